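"""Full-length member detection, representative selection, and export.

A family member is flagged putatively full-length when its mean LTR length
and its whole-element length each deviate from the family medians by at most
the configured thresholds (defaults 50 bp and 200 bp).  The library export
writes one representative per family — the member minimizing the sum of its
normalized deviations — forming a species-specific reference sequence set.
"""

from __future__ import annotations

import os
import re
import statistics
from dataclasses import dataclass, field
from typing import Optional, TextIO

from .model import Candidate, FeatureNode, LtrfamError, Project, UNCLASSIFIED
from .seqio import extract_sequence, write_fasta

#: GFF3 attribute recording family membership on exported roots
FAMILY_ATTR = "ltrfam_family"

DEFAULT_LTR_DEV_MAX = 50
DEFAULT_ELEM_DEV_MAX = 200


@dataclass
class MemberFlags:
    ltr_deviation: float
    elem_deviation: float
    is_full_length: bool


@dataclass
class FullLengthFlags:
    family_name: str
    ltr_dev_max: float
    elem_dev_max: float
    per_candidate: dict[str, MemberFlags] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _mean_ltr_length(candidate: Candidate) -> Optional[float]:
    lengths = candidate.ltr_lengths
    if not lengths:
        return None
    return sum(lengths) / len(lengths)


def flag_fulllength(
    family_name: str,
    members: list[Candidate],
    ltr_dev_max: float = DEFAULT_LTR_DEV_MAX,
    elem_dev_max: float = DEFAULT_ELEM_DEV_MAX,
) -> FullLengthFlags:
    """Deviation-from-median flags for one family.

    The per-candidate LTR length is the mean of its LTR lengths; family
    medians use the midpoint convention for even counts.  Members without
    LTR children are flagged not-full-length with a warning.
    """
    if not members:
        raise LtrfamError("cannot flag an empty family")
    flags = FullLengthFlags(
        family_name=family_name, ltr_dev_max=ltr_dev_max, elem_dev_max=elem_dev_max
    )
    elem_lengths = [c.element_length for c in members]
    ltr_means = [m for m in (_mean_ltr_length(c) for c in members) if m is not None]
    elem_median = statistics.median(elem_lengths)
    ltr_median = statistics.median(ltr_means) if ltr_means else 0.0
    for cand in members:
        elem_dev = abs(cand.element_length - elem_median)
        ltr_mean = _mean_ltr_length(cand)
        if ltr_mean is None:
            flags.warnings.append(
                f"candidate {cand.id} has no LTR children; flagged not full-length"
            )
            flags.per_candidate[cand.id] = MemberFlags(
                ltr_deviation=float("inf"),
                elem_deviation=elem_dev,
                is_full_length=False,
            )
            continue
        ltr_dev = abs(ltr_mean - ltr_median)
        flags.per_candidate[cand.id] = MemberFlags(
            ltr_deviation=ltr_dev,
            elem_deviation=elem_dev,
            is_full_length=ltr_dev <= ltr_dev_max and elem_dev <= elem_dev_max,
        )
    return flags


def select_representative(
    members: list[Candidate], flags: FullLengthFlags
) -> tuple[str, list[str]]:
    """Representative = full-length member with minimal normalized deviation.

    Score = ltr_dev/ltr_dev_max + elem_dev/elem_dev_max; ties broken by
    lexicographically smallest candidate id.  If no member is full-length,
    the global minimizer is chosen with a warning.
    """
    if not members:
        raise LtrfamError("cannot select a representative from an empty family")
    warnings: list[str] = []
    pool = [c for c in members if flags.per_candidate[c.id].is_full_length]
    if not pool:
        warnings.append(
            f"family {flags.family_name!r} has no full-length member; "
            "falling back to the least-deviating member"
        )
        pool = list(members)

    def score(cand: Candidate) -> tuple[float, str]:
        f = flags.per_candidate[cand.id]
        ltr_dev = 0.0 if f.ltr_deviation == float("inf") else f.ltr_deviation
        return (
            ltr_dev / flags.ltr_dev_max + f.elem_deviation / flags.elem_dev_max,
            cand.id,
        )

    return min(pool, key=score).id, warnings


# -- export -------------------------------------------------------------------


def _fasta_header(project: Project, cand: Candidate, family: str) -> str:
    root = cand.root
    return f"{cand.id} {root.seqid}:{root.start}-{root.end}({root.strand}) family={family}"


def _scoped_members(project: Project, scope: str) -> list[tuple[str, str]]:
    """Resolve an export scope to ordered (candidate_id, family_name) pairs.

    Scope is ``all``, ``family:<name>`` or ``library``.
    """
    if scope == "all":
        out = [(cid, name) for name, m in project.families.items() for cid in m]
        out.extend((cid, UNCLASSIFIED) for cid in project.unclassified)
        return out
    if scope.startswith("family:"):
        name = scope.split(":", 1)[1]
        if name not in project.families:
            raise LtrfamError(f"unknown family {name!r}")
        return [(cid, name) for cid in project.families[name]]
    if scope == "library":
        out = []
        for name, member_ids in project.families.items():
            members = [project.candidates[cid] for cid in member_ids]
            flags = flag_fulllength(name, members)
            rep, _ = select_representative(members, flags)
            out.append((rep, name))
        return out
    raise LtrfamError(f"unknown export scope {scope!r}")


def sanitize_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name) or "unnamed"


def export_fasta(
    project: Project,
    out_path: str,
    scope: str = "all",
    per_family: bool = False,
) -> list[str]:
    """Write candidate sequences (strand-adjusted) as FASTA.

    Single-file layout writes ``out_path``; per-family layout treats
    ``out_path`` as a directory and writes one sanitized file per family.
    Returns the list of files written.
    """
    pairs = _scoped_members(project, scope)
    records = [
        (
            _fasta_header(project, project.candidates[cid], family),
            extract_sequence(project.candidates[cid].root, project.sequences),
        )
        for cid, family in pairs
    ]
    if not per_family:
        with open(out_path, "w") as fh:
            write_fasta(records, fh)
        return [out_path]
    os.makedirs(out_path, exist_ok=True)
    by_family: dict[str, list[tuple[str, str]]] = {}
    for (cid, family), rec in zip(pairs, records):
        by_family.setdefault(family, []).append(rec)
    written = []
    for family in by_family:
        path = os.path.join(out_path, sanitize_filename(family) + ".fasta")
        with open(path, "w") as fh:
            write_fasta(by_family[family], fh)
        written.append(path)
    return written


def export_gff3(project: Project, stream: TextIO, scope: str = "all") -> int:
    """Write candidate annotations as GFF3; family membership is recorded in
    an ``ltrfam_family`` attribute on each root.  Returns record count."""
    from .gff3 import write_gff3

    pairs = _scoped_members(project, scope)
    annotated = []
    for cid, family in pairs:
        cand = project.candidates[cid]
        root = cand.root
        # shallow copy of the root so the attribute does not leak back
        new_root = FeatureNode(
            so_type=root.so_type,
            seqid=root.seqid,
            start=root.start,
            end=root.end,
            strand=root.strand,
            score=root.score,
            attributes={**root.attributes, FAMILY_ATTR: family},
            children=root.children,
            source=root.source,
        )
        annotated.append(Candidate(id=cid, root=new_root))
    write_gff3(annotated, stream)
    return len(annotated)
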