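"""Synthetic genomes with implanted LTR-retrotransposon families.

The generator replaces external genome downloads and the upstream de novo
detectors: it writes a random background genome with implanted, mutated
copies of ancestral elements following the canonical element layout
(TSD — LTR — PBS — protein domains — PPT — LTR — TSD), together with
LTRharvest/LTRdigest-style GFF3 annotations (``repeat_region`` root with
target site duplications and a nested ``LTR_retrotransposon``) and a
ground-truth family table.

Copies diverge from their ancestor by i.i.d. substitutions at the family's
mutation rate and may lose one internal protein domain (a deletion), which
is what the compatibility-based classifier must tolerate.  Domain and LTR
segments of different families are kept mutually dissimilar (pairwise
identity <= 40%) so families cannot merge by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, TextIO

import numpy as np

from .gff3 import _format_feature
from .model import (
    FeatureNode,
    LTR_TYPE,
    LtrfamError,
    PBS_TYPE,
    PPT_TYPE,
    DOMAIN_TYPE,
    ROOT_TYPE,
    TSD_TYPE,
)
from .seqio import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: 3' end of an initiator tRNA-Met; the PBS is complementary to its terminus
TRNA_3PRIME = "GGTTCGATCCCGGGCCACCTCCACCA"

#: pHMM-style domain names per pol function
DOMAIN_NAMES = {"AP": "RVP", "RT": "RVT_1", "RH": "RNase_H", "IN": "rve"}

#: domain order distinguishes the two major superfamilies
SUPERFAMILY_ORDER = {
    "COPIA": ("IN", "RT", "RH"),
    "GYPSY": ("RT", "RH", "IN"),
}


@dataclass
class FamilySpec:
    name: str
    n_copies: int = 5
    ltr_len: int = 200
    internal_len: int = 1200
    superfamily: str = "COPIA"
    tsd_len: int = 5
    pbs_len: int = 12
    ppt_len: int = 15
    mutation_rate: float = 0.01
    deletion_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise LtrfamError("n_copies must be >= 1")
        if not 4 <= self.tsd_len <= 6:
            raise LtrfamError("tsd_len must be in [4,6]")
        if not 8 <= self.pbs_len <= 18:
            raise LtrfamError("pbs_len must be in [8,18]")
        if not 8 <= self.ppt_len <= 22:
            raise LtrfamError("ppt_len must be in [8,22]")
        if not 0.0 <= self.mutation_rate <= 0.25:
            raise LtrfamError("mutation_rate must be in [0,0.25]")
        if self.superfamily not in SUPERFAMILY_ORDER:
            raise LtrfamError(f"unknown superfamily {self.superfamily!r}")
        min_internal = self.pbs_len + self.ppt_len + 3 * 60 + 40
        if self.internal_len < min_internal:
            raise LtrfamError(
                f"internal_len {self.internal_len} too short; need >= {min_internal}"
            )


@dataclass
class TruthRow:
    candidate_id: str
    family: str
    is_full_length: bool
    deleted_domain: str = ""


@dataclass
class SimulationResult:
    records: list[tuple[str, str]]  # FASTA records
    gff3: str
    truth: list[TruthRow] = field(default_factory=list)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate`` to a
    uniformly chosen *different* base; length preserved; non-ACGT untouched."""
    if not 0.0 <= rate <= 1.0:
        raise LtrfamError("mutation rate must be in [0,1]")
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    idx = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        idx[arr == b] = i
    hit = (rng.random(arr.shape) < rate) & (idx >= 0)
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx_hit = (idx[hit] + shift) % 4
        arr[hit] = _BASES[idx_hit]
    return arr.tobytes().decode()


def _dissimilar_seq(
    rng: np.random.Generator, n: int, pool: list[str], max_identity: float = 0.4
) -> str:
    """Random sequence whose gapless identity to every pool entry is bounded."""
    for _ in range(200):
        seq = random_seq(rng, n)
        ok = True
        for other in pool:
            m = min(len(seq), len(other))
            ident = sum(seq[i] == other[i] for i in range(m)) / m
            if ident > max_identity:
                ok = False
                break
        if ok:
            pool.append(seq)
            return seq
    raise LtrfamError("could not generate a sufficiently dissimilar segment")


@dataclass
class _Ancestor:
    sequence: str
    # (so_type, name, start0, end0_exclusive) on the element
    features: list[tuple[str, str, int, int]]


def _build_ancestor(
    spec: FamilySpec, rng: np.random.Generator, segment_pool: list[str]
) -> _Ancestor:
    ltr = _dissimilar_seq(rng, spec.ltr_len, segment_pool)
    pbs = reverse_complement(TRNA_3PRIME[-spec.pbs_len :])
    ppt = "".join(rng.choice(["A", "G"], size=spec.ppt_len, p=[0.6, 0.4]))
    order = SUPERFAMILY_ORDER[spec.superfamily]
    n_gaps = len(order) + 1
    budget = spec.internal_len - spec.pbs_len - spec.ppt_len
    domain_len = (budget - 40) // len(order)
    leftover = budget - len(order) * domain_len
    gaps = [leftover // n_gaps] * n_gaps
    gaps[-1] += leftover - sum(gaps)
    domains = {
        func: _dissimilar_seq(rng, domain_len, segment_pool) for func in order
    }

    parts: list[str] = [ltr]
    features: list[tuple[str, str, int, int]] = []
    pos = spec.ltr_len
    features.append((LTR_TYPE, "", 0, spec.ltr_len))

    def push(segment: str, so_type: str = "", name: str = "") -> None:
        nonlocal pos
        parts.append(segment)
        if so_type:
            features.append((so_type, name, pos, pos + len(segment)))
        pos += len(segment)

    push(pbs, PBS_TYPE)
    push(random_seq(rng, gaps[0]))
    for i, func in enumerate(order):
        push(domains[func], DOMAIN_TYPE, DOMAIN_NAMES[func])
        push(random_seq(rng, gaps[i + 1]))
    push(ppt, PPT_TYPE)
    features.append((LTR_TYPE, "", pos, pos + spec.ltr_len))
    push(ltr)
    sequence = "".join(parts)
    assert len(sequence) == 2 * spec.ltr_len + spec.internal_len
    return _Ancestor(sequence=sequence, features=features)


def _make_copy(
    spec: FamilySpec, ancestor: _Ancestor, rng: np.random.Generator
) -> tuple[str, list[tuple[str, str, int, int]], str]:
    """One mutated copy; returns (sequence, features, deleted_domain_name)."""
    seq = ancestor.sequence
    features = list(ancestor.features)
    deleted = ""
    if spec.deletion_prob > 0 and rng.random() < spec.deletion_prob:
        domain_feats = [f for f in features if f[0] == DOMAIN_TYPE]
        victim = domain_feats[int(rng.integers(0, len(domain_feats)))]
        _, name, d_start, d_end = victim
        d_len = d_end - d_start
        seq = seq[:d_start] + seq[d_end:]
        new_features = []
        for so_type, fname, s, e in features:
            if (so_type, fname, s, e) == victim:
                continue
            if s >= d_end:
                s, e = s - d_len, e - d_len
            new_features.append((so_type, fname, s, e))
        features = new_features
        deleted = name
    seq = mutate(seq, spec.mutation_rate, rng)
    return seq, features, deleted


def simulate(
    specs: list[FamilySpec],
    genome_len: int = 100_000,
    seed: int = 42,
    seq_name: str = "seq0",
) -> SimulationResult:
    """Generate (FASTA records, GFF3 text, truth table) for the given specs.

    ``genome_len`` is the final genome length including implants; implants
    are placed at distinct insertion points of the random background, so
    they never overlap.  All randomness flows from one seeded generator:
    a fixed seed reproduces byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    segment_pool: list[str] = []
    implants = []  # (candidate_id, family, seq_with_tsds, features, tsd, deleted)
    for spec in specs:
        ancestor = _build_ancestor(spec, rng, segment_pool)
        for j in range(spec.n_copies):
            seq, features, deleted = _make_copy(spec, ancestor, rng)
            tsd = random_seq(rng, spec.tsd_len)
            implants.append(
                (f"{spec.name}_{j}", spec.name, tsd + seq + tsd, features, tsd, deleted)
            )

    total_implant = sum(len(t[2]) for t in implants)
    background_len = genome_len - total_implant
    min_gap = 20
    if background_len < (len(implants) + 1) * min_gap:
        raise LtrfamError(
            f"genome_len {genome_len} cannot hold {len(implants)} implants "
            f"totalling {total_implant} bp"
        )
    background = random_seq(rng, background_len)
    # distinct insertion offsets into the background, kept apart by min_gap
    usable = background_len - 2 * min_gap
    offsets = sorted(
        min_gap + int(round(x * usable / max(1, len(implants) - 1) if len(implants) > 1 else usable // 2))
        for x in range(len(implants))
    )
    jitter = rng.integers(-min_gap // 2, min_gap // 2 + 1, size=len(offsets))
    offsets = sorted(int(o + d) for o, d in zip(offsets, jitter))

    pieces: list[str] = []
    gff_lines = ["##gff-version 3"]
    truth: list[TruthRow] = []
    cursor = 0
    genome_pos = 0
    for (cid, family, implant_seq, features, tsd, deleted), offset in zip(
        implants, offsets
    ):
        pieces.append(background[cursor:offset])
        genome_pos += offset - cursor
        cursor = offset
        rr_start = genome_pos + 1  # 1-based
        tsd_len = len(tsd)
        elem_len = len(implant_seq) - 2 * tsd_len
        rr_end = genome_pos + len(implant_seq)
        elem_start = rr_start + tsd_len
        elem_end = rr_end - tsd_len
        rr_id = f"rr_{cid}"
        gff_lines.append(
            _gff_line(seq_name, "repeat_region", rr_start, rr_end, {"ID": rr_id})
        )
        gff_lines.append(
            _gff_line(
                seq_name,
                TSD_TYPE,
                rr_start,
                rr_start + tsd_len - 1,
                {"Parent": rr_id},
            )
        )
        gff_lines.append(
            _gff_line(
                seq_name, TSD_TYPE, rr_end - tsd_len + 1, rr_end, {"Parent": rr_id}
            )
        )
        gff_lines.append(
            _gff_line(
                seq_name,
                ROOT_TYPE,
                elem_start,
                elem_end,
                {"ID": cid, "Parent": rr_id},
            )
        )
        for so_type, fname, s, e in features:
            attrs = {"Parent": cid}
            if fname:
                attrs["name"] = fname
            gff_lines.append(
                _gff_line(seq_name, so_type, elem_start + s, elem_start + e - 1, attrs)
            )
        truth.append(
            TruthRow(
                candidate_id=cid,
                family=family,
                is_full_length=not deleted,
                deleted_domain=deleted,
            )
        )
        pieces.append(implant_seq)
        genome_pos += len(implant_seq)
    pieces.append(background[cursor:])
    genome = "".join(pieces)
    assert len(genome) == genome_len
    return SimulationResult(
        records=[(seq_name, genome)],
        gff3="\n".join(gff_lines) + "\n",
        truth=truth,
    )


def _gff_line(seqid, so_type, start, end, attrs) -> str:
    node = FeatureNode(
        so_type=so_type,
        seqid=seqid,
        start=start,
        end=end,
        strand="+",
        attributes={k: v for k, v in attrs.items() if k not in ("ID", "Parent")},
        source="ltrfam-sim",
    )
    return _format_feature(node, attrs.get("ID"), attrs.get("Parent"))


def write_truth_tsv(truth: list[TruthRow], stream: TextIO) -> None:
    stream.write("candidate_id\tfamily\tfull_length\tdeleted_domain\n")
    for row in truth:
        stream.write(
            f"{row.candidate_id}\t{row.family}\t"
            f"{'yes' if row.is_full_length else 'no'}\t{row.deleted_domain}\n"
        )
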