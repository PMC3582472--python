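# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind `ltrfam`, and what the synthetic benchmarks do and do
not demonstrate.

## Data model and coordinates

Annotations are trees of features with GFF3 1-based inclusive coordinates,
kept 1-based internally end to end (no half-open conversion anywhere, so
there is a single place off-by-one errors could enter: the FASTA slice in
`extract_sequence`, which is tested against a reverse-complement involution
property). Two input dialects are accepted: a bare `LTR_retrotransposon`
root, and the LTRharvest-style `repeat_region` wrapper whose TSD children
are re-attached to the element root. Flanking TSDs are exempt from the
child-within-root span check; any other out-of-span child is warned about
and never clipped. Unknown child feature types are preserved verbatim so
filter rules can query them. The `seqX` sequence-identifier convention
(X = 0-based record number) is enforced only in `--strict` mode; otherwise
arbitrary seqids resolve literally against FASTA headers, which lets the
tool consume annotations on named chromosomes.

## Matching

The built-in matcher is deliberately simple: exact seeds of length 10
(one representative seed per pair diagonal), ungapped extension with X-drop
10 under +1/−1 scoring, identity computed over the best-scoring extent.
It has no gapped alignment; for the substitution-dominated divergence
regime of recent retrotransspositions this loses little, and the test suite
pins its kept/removed decisions to full Smith–Waterman local alignment
(Bio.Align) on mixed panels of related and unrelated sequences. Users with
indel-rich data can ingest BLAST/LAST 12-column tables instead; the span
filter is applied identically either way.

Span thresholds default to 80% of the shorter and 30% of the longer
sequence, inclusive at the boundary; identity threshold 0.8. Classes whose
mean sequence length is below 80 nt (typically PBS and PPT) are skipped
with a warning: sub-seed-length sequences cannot be matched meaningfully
by a seeded matcher, and short near-universal motifs would otherwise link
unrelated families. The gate is configurable (`--min-avg-len`).

Matching is strictly intra-class; protein domains are split into separate
classes by their `name` attribute by default (collapsible by flag), since
domain clusters are interpreted per function (RT, IN, …).

## Clustering and classification

Single linkage is realized exactly as connected components of the kept-match
graph — the linkage criterion is the existence of a filtered match, with no
additional distance threshold. Cluster ids are dense per class and ordered
by smallest member uid, making the numbering invariant under permutation of
the match list (property-tested against an independent BFS oracle).
Clusters whose members all come from one candidate (e.g. the candidate's
own two LTRs) are dropped by default (`--keep-private-clusters` retains
them): they cannot join two candidates and would only inflate signatures.

Compatibility uses per-class label-set *intersection*, not equality,
pairwise across a whole merged group. Intersection tolerates candidates
with deleted or unannotated features while still splitting on contradictory
cluster assignments. The merge procedure is pinned to a deterministic
order (labels sorted by class key then cluster id; groups by smallest
member id; all-or-nothing merges per label; iterate to fixed point) so
identical inputs in any order give identical families.

Ambiguity withdrawal: a candidate that both shares a cluster label with and
is pairwise compatible with two or more final families could have been
placed in either, so it is returned to the unclassified list. Mere label
sharing with an incompatible family is *not* treated as ambiguity — when
two families split on their LTR clusters but remain linked by a common
domain cluster, the LTR conflict pins each member to its own side, and
the split is preserved rather than dissolving both families. If withdrawal
empties a family it is removed; a family reduced to one member is kept.

Family maintenance follows workbench conventions: members removed from a
family return to a project-wide unclassified list; candidates deleted from
the unclassified list leave the project entirely; discarding small families
(default minimum 3 members) unclassifies their members unless `--purge`.

## Filtering

Rules are pure predicates over the candidate tree with the convention
true = select/filter out. Chains combine per-rule verdicts (after optional
negation) with ALL or ANY. The user dialect is a restricted expression
grammar (parsed with Python's `ast`, evaluated over a whitelist — no code
execution): `exists(...)`/`count(...)` re-evaluate their argument per node
with `type`, `length`, `start`, `end`, `strand`, `score`, `seqid`,
`attr("k")` bound; top level additionally has `element_length` and
`match_coverage()`. Reference-match coverage uses an inclusive comparison
(coverage exactly at the threshold counts as covered), isolated in one
comparator; the boundary is pinned by test at coverages 0.799/0.800/0.801.

## Augmentation

ORFs are ATG-to-stop (stop codon included), scanned over all six frames of
the whole element — LTRs included, since regulatory ORFs can overlap them;
`--interior-only` restricts to the inter-LTR region. Default minimum 300 bp,
longest ORF per frame reported. Stop-to-stop scanning was considered and
rejected as a default because unanchored frames overstate coding capacity;
the choice is configurable through `mode`.

Reference matching has two engines: `blastn` (external NCBI BLAST+,
E-value threshold 0.01, matched candidate regions become `nucleotide_match`
children with a `Target` attribute) and a built-in engine using the
seed-and-extend matcher (no E-values; gates of span ≥ 50 bp and identity
≥ 0.8). A missing external engine is a hard error, never a silent
fallback. Every matching run is numbered and recorded in the project run
log with its parameters.

## Full-length flagging and export

Per candidate the LTR length is the mean of its LTR lengths (symmetric
under 5'/3' swap); family medians use the midpoint convention for even
counts. Flags: LTR deviation ≤ 50 bp and element deviation ≤ 200 bp (both
configurable). The representative minimizes
ltr_dev/ltr_max + elem_dev/elem_max among full-length members (all members,
with a warning, if none qualify), ties broken by smallest candidate id.
Only length deviations enter the score; feature completeness (domain
counts) does not, to keep the criterion independent of annotation depth.
Exported GFF3 records family membership in an `ltrfam_family` root
attribute so single-file export is lossless; FASTA headers carry
`id seqid:start-end(strand) family=name`.

## Synthetic data

The simulator emulates *detector output*, not detection: it produces the
annotations a structure-based predictor would emit for its own implants.
An ancestral element per family consists of a random LTR (duplicated at
both ends), a PBS complementary to a fixed tRNA 3' terminus (8–18 bp), a
polypurine tract drawn A/G-rich (8–22 bp), and three pol-domain segments
in superfamily order (copia IN-RT-RH, gypsy RT-RH-IN). LTR and domain
segments are rejection-sampled to pairwise identity ≤ 40% so families
cannot merge by chance at the test thresholds. Copies receive i.i.d.
substitutions (Jukes–Cantor-like, default 1%), optionally lose one whole
domain, and are inserted at distinct points of a random background genome
flanked by a copy-specific 4–6 bp TSD (the TSD is generated with the copy
rather than duplicated from the target site; only the identity of the two
flanks matters downstream). All randomness flows from one seeded
generator, so a fixed seed reproduces byte-identical FASTA/GFF3/truth
outputs.

What passing on this generator shows: correct clustering, compatibility
joining, deletion tolerance, threshold boundaries and determinism under
the stated divergence regime. What it does not show: robustness to indels
and alignment gaps, nested insertions, solo LTRs, tandem or fragmented
elements, non-uniform substitution processes, or detector noise
(mis-annotated boundaries); real annotations exercise those and may
fragment families at higher divergence (at 15% substitution the simulated
families visibly fragment, which is reported but not asserted).

## Problem sizes and defaults

Benchmarks in the test suite and the acceptance script use 2–10 families
of 3–10 copies each (elements around 1.3–1.6 kb in genomes of 40–250 kb),
divergence 0–1%, 20-sequence matcher panels (≤ 300 bp), 200 random graphs
of up to 200 nodes for the clustering oracle, and 50 random 2 kb sequences
for the ORF oracle — sizes chosen so every published property is exercised
by exact oracle comparison rather than sampling. Default thresholds
throughout: span fractions 0.8/0.3, identity 0.8, seed length 10, X-drop
10, average-length gate 80 nt, LTR/element deviations 50/200 bp, minimum
family size 3, BLASTN E-value 0.01, ORF minimum 300 bp.

## Known limitations

- The built-in matcher is ungapped; heavily indel-diverged families need
  an external matcher via table ingestion.
- Classification uses one joining strategy (deterministic greedy label
  merging with pairwise compatibility); alternative strategies (stochastic
  flow clustering, phylogeny-based assignment, 80-80-80 thresholding) are
  out of scope, though the stage boundaries make swapping feasible.
- No superfamily-level grouping or multi-level tags; one container per
  candidate.
- The rule dialect covers feature existence/counts, locations, attributes
  and match coverage; arbitrary computation requires registering a Python
  predicate as a plugin rule.
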