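# ltrfam

`ltrfam` is a headless workbench for the postprocessing stage of *de novo*
LTR-retrotransposon surveys: after a structural detector (e.g.
LTRharvest/LTRdigest) has predicted candidate insertions and annotated their
internal features, `ltrfam` classifies the candidates into putative
families, filters out likely false positives, augments the annotations with
ORFs and reference-library matches, flags putative full-length members, and
exports a per-family reference sequence library — all from the shell or as
a Python library, with no GUI and no external matching tools required.

It is aimed at researchers building species-specific repeat libraries, and
at pipeline authors who need a reproducible, scriptable version of a
classification workflow that is usually spread across glue scripts and
spreadsheets.

## The classification model

Each candidate is a rooted tree of GFF3 features (1-based inclusive
coordinates): an `LTR_retrotransposon` root with `long_terminal_repeat`,
`target_site_duplication`, `primer_binding_site`, `RR_tract` (polypurine
tract) and `protein_match` children. Classification proceeds per *feature
class* c (the two LTRs, the PBS, the PPT, and protein domains split by
name, e.g. `protein_match:RVT_1`):

1. **Matching.** All feature sequences of class c are compared all-vs-all
   with a seed-and-extend local matcher (exact seeds, ungapped X-drop
   extension). A match between sequences x, y with spans s_x, s_y is kept
   iff s_short ≥ 0.8·|shorter| and s_long ≥ 0.3·|longer| (boundary
   inclusive), with identity ≥ 0.8. Precomputed BLAST/LAST 12-column
   tables can be ingested instead.
2. **Single-linkage clustering.** Clusters of class c are the connected
   components of the kept-match graph. Clusters covering fewer than two
   distinct candidates carry no grouping evidence and are dropped.
3. **Signatures and compatibility.** A candidate's *signature* maps each
   class to its set of cluster ids. Candidates i, j are *compatible* iff
   for every class on which both have labels, the label sets intersect —
   so a candidate missing a feature (internal deletion) can still join,
   while candidates whose shared features landed in different clusters
   cannot.
4. **Family joining.** Cluster labels are visited in a deterministic order;
   all groups carrying a label merge iff the merged group is pairwise
   compatible, iterated to a fixed point. Groups of ≥ 2 become families;
   singletons and candidates that could be placed in more than one family
   remain unclassified.

Downstream, a family member is **putatively full-length** when its mean LTR
length and element length deviate from the family medians by at most 50 bp
and 200 bp respectively; the member minimizing the normalized deviation sum
is exported as the family representative.

Filtering applies chains of boolean rules (built-ins such as
`no_protein_domain`, `low_reference_coverage`, `full_domain_set`, or
user-written expression files) with AND/OR combination and per-rule
negation; selected candidates are either withdrawn to the unclassified list
(and deleted from the project if already unclassified) or moved to a new
family.

Because genome-scale inputs are unwieldy for tests and demos, the package
ships a simulator that implants mutated copies of ancestral elements
(TSD–LTR–PBS–domains–PPT–LTR–TSD; copia IN-RT-RH vs gypsy RT-RH-IN domain
order) into a random genome and emits matching GFF3 plus a ground-truth
family table.

## Worked example

Simulate a small genome with two implanted families, classify, and export
a reference library:

```sh
$ ltrfam simulate --out sim --seed 42 --genome-len 80000
simulated 6 candidates into sim
$ ltrfam import --gff3 sim/candidates.gff3 --fasta sim/genome.fasta --project demo.json
imported 6 candidates into demo.json
$ ltrfam match --project demo.json
48 matches kept after span filtering
$ ltrfam classify --project demo.json
2 putative families; 0 candidates unclassified
$ ltrfam stats --project demo.json
candidates      6
families        2
unclassified    0
family_sizes    3,3
run_log_entries 4
$ ltrfam fulllength --project demo.json
fam_0   3 members       3 full-length   rep=famA_0
fam_1   3 members       3 full-length   rep=famB_0
$ ltrfam export --project demo.json --what fasta --scope library --out library.fasta
wrote 1 file(s)
$ head -1 library.fasta
>famA_0 seq0:24-1623(+) family=fam_0
```

The 6 simulated candidates fall into 2 families of 3 (matching the
simulated ground truth); all members sit within the deviation thresholds,
so all are flagged full-length, and the library holds one representative
per family with its genomic provenance in the header. The two `warning:
class ... skipped` messages (not shown) report that the PBS and PPT classes
fall below the 80 nt average-length gate and were excluded from matching.

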