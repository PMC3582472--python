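"""Candidate augmentation: ORF detection and reference-library matching.

ORFs are ATG-to-stop open reading frames found in all six frames of the
element sequence and appended as ``reading_frame`` children in genome
coordinates.  Reference matches (``nucleotide_match`` children) come either
from an external ``blastn`` run (tabular output, E-value threshold) or from
the built-in seed-and-extend matcher with span/identity gates.  The maximum
fraction of the element covered by a single reference match backs the
reference-coverage filter rule.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import os
from typing import Optional

from .model import (
    Candidate,
    FeatureNode,
    LtrfamError,
    ORF_TYPE,
    Project,
    REFMATCH_TYPE,
)
from .seqio import extract_sequence, reverse_complement

_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_in_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """All ATG->stop ORFs (stop included) in one forward frame.

    Returns 0-based [start, end) spans on ``seq``.
    """
    out = []
    i = frame
    start = None
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in _STOPS:
            out.append((start, i + 3))
            start = None
        i += 3
    return out


def find_orfs(
    candidate: Candidate,
    seqs,
    min_orf_len: int = 300,
    mode: str = "longest_per_frame",
    interior_only: bool = False,
    attach: bool = True,
) -> list[FeatureNode]:
    """Six-frame ORF scan over the element; coordinates mapped back to the
    genome (1-based).  Per frame either the longest qualifying ORF
    (``longest_per_frame``) or all of them (``all``) are reported.
    """
    root = candidate.root
    span_start, span_end = root.start, root.end
    if interior_only:
        ltrs = sorted(
            (n for n in root.children if n.so_type == "long_terminal_repeat"),
            key=lambda n: n.start,
        )
        if len(ltrs) == 2:
            span_start, span_end = ltrs[0].end + 1, ltrs[1].start - 1
            if span_start > span_end:
                return []
    window = FeatureNode(
        so_type=root.so_type,
        seqid=root.seqid,
        start=span_start,
        end=span_end,
        strand="+",
    )
    forward = extract_sequence(window, seqs)
    if len(forward) < min_orf_len:
        return []
    features: list[FeatureNode] = []
    for strand, seq in (("+", forward), ("-", reverse_complement(forward))):
        for frame in range(3):
            orfs = [
                (s, e)
                for s, e in _orfs_in_frame(seq, frame)
                if e - s >= min_orf_len
            ]
            if not orfs:
                continue
            if mode == "longest_per_frame":
                orfs = [max(orfs, key=lambda se: (se[1] - se[0], -se[0]))]
            for s, e in orfs:
                if strand == "+":
                    g_start = span_start + s
                    g_end = span_start + e - 1
                else:
                    g_start = span_end - e + 1
                    g_end = span_end - s
                features.append(
                    FeatureNode(
                        so_type=ORF_TYPE,
                        seqid=root.seqid,
                        start=g_start,
                        end=g_end,
                        strand=strand,
                        attributes={"frame": str(frame)},
                    )
                )
    features.sort(key=lambda n: (n.start, n.end, n.strand))
    if attach:
        for feat in features:
            root.add_child(feat)
    return features


def match_coverage(candidate: Candidate) -> float:
    """Max fraction of the element covered by one nucleotide_match; 0 if none."""
    best = 0.0
    for node in candidate.root.children:
        if node.so_type == REFMATCH_TYPE:
            best = max(best, node.length / candidate.element_length)
    return min(best, 1.0)


def _best_local_segment(
    a: str, b: str, seed_len: int = 12
) -> Optional[tuple[int, int, int]]:
    """Best ungapped local segment of ``a`` vs ``b`` via seed and extend.

    Returns (start0 on a, length, n_match) or None if no seed is shared.
    """
    from .matching import _extend_ungapped

    best: Optional[tuple[int, int, int]] = None  # keyed by n_match
    seen_diags: set[int] = set()
    index: dict[str, list[int]] = {}
    for pos in range(0, len(b) - seed_len + 1):
        index.setdefault(b[pos : pos + seed_len], []).append(pos)
    for qpos in range(0, len(a) - seed_len + 1):
        seed = a[qpos : qpos + seed_len]
        for spos in index.get(seed, []):
            diag = spos - qpos
            if diag in seen_diags:
                continue
            seen_diags.add(diag)
            start, length, n_match = _extend_ungapped(
                a, b, qpos, spos, seed_len, xdrop=10
            )
            if best is None or n_match > best[2]:
                best = (start, length, n_match)
    return best


def _builtin_reference_hits(
    cand_seq: str, ref_name: str, ref_seq: str, min_span: int, min_identity: float
) -> list[tuple[int, int, float, str]]:
    """Local hits of one candidate against one reference (both orientations).

    Returns (start0, end0_exclusive, identity, orientation) on the candidate.
    """
    hits = []
    for orientation, rseq in (("+", ref_seq), ("-", reverse_complement(ref_seq))):
        segment = _best_local_segment(cand_seq, rseq)
        if segment is None:
            continue
        start, length, n_match = segment
        identity = n_match / length if length else 0.0
        if length >= min_span and identity >= min_identity:
            hits.append((start, start + length, identity, orientation))
    return hits


def reference_match(
    project: Project,
    reference_fasta: str,
    engine: str = "builtin",
    evalue_threshold: float = 0.01,
    min_span: int = 50,
    min_identity: float = 0.8,
) -> int:
    """Annotate candidates with reference-library matches.

    ``builtin`` uses the internal matcher (no E-values; span/identity gates);
    ``blastn`` shells out to NCBI BLAST+ and keeps hits with E-value at or
    below the threshold.  Matched regions become ``nucleotide_match``
    children with a GFF3 ``Target`` attribute naming the reference span.
    Run parameters are appended to the project run log.  Returns the number
    of features added.
    """
    from Bio import SeqIO

    refs = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(reference_fasta, "fasta")
    ]
    if not refs:
        raise LtrfamError(f"reference FASTA {reference_fasta!r} is empty")

    added = 0
    if engine == "builtin":
        for cid in sorted(project.candidates):
            cand = project.candidates[cid]
            window = FeatureNode(
                so_type=cand.root.so_type,
                seqid=cand.root.seqid,
                start=cand.root.start,
                end=cand.root.end,
                strand="+",
            )
            cand_seq = extract_sequence(window, project.sequences)
            for ref_name, ref_seq in refs:
                for start, end, identity, orientation in _builtin_reference_hits(
                    cand_seq, ref_name, ref_seq, min_span, min_identity
                ):
                    cand.root.add_child(
                        FeatureNode(
                            so_type=REFMATCH_TYPE,
                            seqid=cand.seqid,
                            start=cand.root.start + start,
                            end=cand.root.start + end - 1,
                            strand="+",
                            attributes={
                                "Target": f"{ref_name} 1 {end - start} {orientation}",
                                "identity": f"{identity:.3f}",
                            },
                        )
                    )
                    added += 1
    elif engine == "blastn":
        added = _blastn_reference_match(
            project, refs, reference_fasta, evalue_threshold
        )
    else:
        raise LtrfamError(f"unknown reference-matching engine {engine!r}")

    project.log_run(
        "refmatch",
        {
            "engine": engine,
            "reference": reference_fasta,
            "evalue_threshold": evalue_threshold,
            "min_span": min_span,
            "min_identity": min_identity,
        },
    )
    return added


def _blastn_reference_match(
    project: Project, refs, reference_fasta: str, evalue_threshold: float
) -> int:
    from .matching import ingest_match_table

    if shutil.which("blastn") is None:
        raise LtrfamError(
            "external engine 'blastn' selected but the blastn executable "
            "(NCBI BLAST+) is not on PATH"
        )
    added = 0
    with tempfile.TemporaryDirectory() as tmp:
        qpath = os.path.join(tmp, "candidates.fasta")
        with open(qpath, "w") as fh:
            for cid in sorted(project.candidates):
                cand = project.candidates[cid]
                window = FeatureNode(
                    so_type=cand.root.so_type,
                    seqid=cand.root.seqid,
                    start=cand.root.start,
                    end=cand.root.end,
                    strand="+",
                )
                fh.write(f">{cid}\n{extract_sequence(window, project.sequences)}\n")
        out = subprocess.run(
            [
                "blastn",
                "-query",
                qpath,
                "-subject",
                reference_fasta,
                "-outfmt",
                "6",
                "-evalue",
                str(evalue_threshold),
            ],
            capture_output=True,
            text=True,
            check=True,
        )
        import io

        for m in ingest_match_table(io.StringIO(out.stdout)):
            if m.evalue is not None and m.evalue > evalue_threshold:
                continue
            if m.query_uid in project.candidates:
                cid, ref = m.query_uid, m.subject_uid
                c_range, r_range = m.q_range, m.s_range
            elif m.subject_uid in project.candidates:
                cid, ref = m.subject_uid, m.query_uid
                c_range, r_range = m.s_range, m.q_range
            else:
                continue
            cand = project.candidates[cid]
            assert c_range is not None and r_range is not None
            cand.root.add_child(
                FeatureNode(
                    so_type=REFMATCH_TYPE,
                    seqid=cand.seqid,
                    start=cand.root.start + c_range[0] - 1,
                    end=min(cand.root.start + c_range[1] - 1, cand.root.end),
                    strand="+",
                    attributes={
                        "Target": f"{ref} {r_range[0]} {r_range[1]} +",
                        "evalue": f"{m.evalue:g}" if m.evalue is not None else "",
                        "identity": f"{m.identity:.3f}",
                    },
                )
            )
            added += 1
    return added
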