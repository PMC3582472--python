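"""Per-class feature sequence extraction and pairwise local matching.

Classification evidence comes from local similarity between feature sequences
of the same class (both LTRs of every candidate, PBS, PPT, protein domain
regions).  Matches are produced either by the built-in seed-and-extend
matcher (exact seeds, ungapped X-drop extension) or ingested from an external
tool's 12-column tabular output, and are then reduced by the span filter:
a match is kept only if it spans at least ``min_frac_shorter`` of the shorter
and ``min_frac_longer`` of the longer sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, TextIO

from .model import (
    Candidate,
    DOMAIN_TYPE,
    LTR_TYPE,
    LtrfamError,
    PBS_TYPE,
    PPT_TYPE,
    ParseError,
)
from .seqio import extract_sequence

#: shorthand accepted on the CLI for feature-class selection
CLASS_ALIASES = {
    "ltr": LTR_TYPE,
    "ppt": PPT_TYPE,
    "pbs": PBS_TYPE,
    "domains": DOMAIN_TYPE,
    LTR_TYPE: LTR_TYPE,
    PPT_TYPE: PPT_TYPE,
    PBS_TYPE: PBS_TYPE,
    DOMAIN_TYPE: DOMAIN_TYPE,
}


@dataclass(frozen=True)
class FeatureSequence:
    uid: str
    candidate_id: str
    class_key: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Match:
    query_uid: str
    subject_uid: str
    q_span: int
    s_span: int
    identity: float
    score: float
    evalue: Optional[float] = None
    # 1-based coordinate ranges of the matched regions, when known
    q_range: Optional[tuple[int, int]] = None
    s_range: Optional[tuple[int, int]] = None


def resolve_classes(names: Iterable[str]) -> list[str]:
    out = []
    for name in names:
        key = CLASS_ALIASES.get(name.strip())
        if key is None:
            raise LtrfamError(f"unknown feature class {name!r}")
        if key not in out:
            out.append(key)
    return out


def class_key_of(node, split_domains: bool = True) -> str:
    if node.so_type == DOMAIN_TYPE and split_domains:
        return f"{DOMAIN_TYPE}:{node.attributes.get('name', 'unknown')}"
    return node.so_type


def collect_feature_sequences(
    project,
    classes: Iterable[str],
    split_domains: bool = True,
) -> list[FeatureSequence]:
    """One strand-adjusted FeatureSequence per matching feature node.

    Both LTRs of a candidate are emitted as separate entries.  Protein domain
    matches are subdivided by their ``name`` attribute (``protein_match:RVT_1``
    etc.) unless ``split_domains`` is false.
    """
    wanted = set(resolve_classes(classes))
    out: list[FeatureSequence] = []
    for cid in sorted(project.candidates):
        cand: Candidate = project.candidates[cid]
        ordinals: dict[str, int] = {}
        for node in cand.root.traverse():
            if node is cand.root or node.so_type not in wanted:
                continue
            key = class_key_of(node, split_domains)
            ordinal = ordinals.get(key, 0)
            ordinals[key] = ordinal + 1
            seq = extract_sequence(node, project.sequences)
            if not seq:
                continue
            out.append(
                FeatureSequence(
                    uid=f"{cid}:{key}:{ordinal}",
                    candidate_id=cid,
                    class_key=key,
                    sequence=seq,
                )
            )
    return out


# -- built-in seed-and-extend matcher ----------------------------------------


def _extend_ungapped(
    a: str, b: str, qpos: int, spos: int, seed_len: int, xdrop: int
) -> tuple[int, int, int]:
    """Extend an exact seed along its diagonal with X-drop termination.

    Returns (q_start, length, n_matches) of the best-scoring ungapped segment
    containing the seed (match +1, mismatch -1).
    """
    # rightward from seed end
    score = seed_len
    best = score
    best_right = qpos + seed_len  # exclusive
    i, j = qpos + seed_len, spos + seed_len
    while i < len(a) and j < len(b):
        score += 1 if a[i] == b[j] else -1
        i += 1
        j += 1
        if score > best:
            best, best_right = score, i
        elif score < best - xdrop:
            break
    # leftward from seed start
    score = best
    best_left = qpos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += 1 if a[i] == b[j] else -1
        if score > best:
            best, best_left = score, i
        elif score < best - xdrop:
            break
        i -= 1
        j -= 1
    length = best_right - best_left
    offset = spos - qpos
    n_match = sum(
        1 for k in range(best_left, best_right) if a[k] == b[k + offset]
    )
    return best_left, length, n_match


def match_all(
    seqs: list[FeatureSequence],
    seed_len: int = 10,
    min_identity: float = 0.8,
    xdrop: int = 10,
    min_avg_len: Optional[float] = None,
) -> tuple[list[Match], list[str]]:
    """All-vs-all local matching within each feature class.

    Output is symmetric (one canonical entry per unordered pair, query uid
    lexicographically smaller), excludes self-matches, and is deterministic
    under permutation of the input because sequences are processed in uid
    order.  Classes whose average sequence length is below ``min_avg_len``
    are skipped with a warning.
    """
    warnings: list[str] = []
    by_class: dict[str, list[FeatureSequence]] = {}
    for fs in sorted(seqs, key=lambda f: f.uid):
        by_class.setdefault(fs.class_key, []).append(fs)

    matches: list[Match] = []
    for class_key in sorted(by_class):
        group = by_class[class_key]
        if len(group) < 2:
            continue
        if min_avg_len is not None:
            avg = sum(f.length for f in group) / len(group)
            if avg < min_avg_len:
                warnings.append(
                    f"class {class_key!r} skipped: average length "
                    f"{avg:.1f} < {min_avg_len}"
                )
                continue
        # k-mer index: seed -> [(seq index, position)]
        index: dict[str, list[tuple[int, int]]] = {}
        for si, fs in enumerate(group):
            s = fs.sequence
            for pos in range(0, len(s) - seed_len + 1):
                index.setdefault(s[pos : pos + seed_len], []).append((si, pos))
        # per pair: one representative seed per diagonal
        pair_diags: dict[tuple[int, int], dict[int, tuple[int, int]]] = {}
        for seed in index:
            hits = index[seed]
            if len(hits) < 2:
                continue
            for ai in range(len(hits)):
                for bi in range(ai + 1, len(hits)):
                    (x, xpos), (y, ypos) = hits[ai], hits[bi]
                    if x == y:
                        continue
                    diags = pair_diags.setdefault((x, y), {})
                    diag = ypos - xpos
                    if diag not in diags or (xpos, ypos) < diags[diag]:
                        diags[diag] = (xpos, ypos)
        for (x, y) in sorted(pair_diags):
            a, b = group[x].sequence, group[y].sequence
            best = None  # (score, length, identity)
            for diag in sorted(pair_diags[(x, y)]):
                qpos, spos = pair_diags[(x, y)][diag]
                _, length, n_match = _extend_ungapped(
                    a, b, qpos, spos, seed_len, xdrop
                )
                score = 2 * n_match - length  # matches - mismatches
                if best is None or (score, length) > (best[0], best[1]):
                    best = (score, length, n_match / length)
            assert best is not None
            score, length, identity = best
            if identity >= min_identity:
                matches.append(
                    Match(
                        query_uid=group[x].uid,
                        subject_uid=group[y].uid,
                        q_span=length,
                        s_span=length,
                        identity=identity,
                        score=float(score),
                    )
                )
    return matches, warnings


def span_filter(
    matches: Iterable[Match],
    lengths: dict[str, int],
    min_frac_shorter: float = 0.8,
    min_frac_longer: float = 0.3,
) -> list[Match]:
    """Keep matches spanning >= 80%/30% (defaults) of shorter/longer sequence.

    Boundary inclusive on both thresholds.
    """
    kept = []
    for m in matches:
        for uid in (m.query_uid, m.subject_uid):
            if uid not in lengths:
                raise LtrfamError(f"no length known for uid {uid!r}")
        lq, ls = lengths[m.query_uid], lengths[m.subject_uid]
        if lq <= ls:
            span_shorter, len_shorter = m.q_span, lq
            span_longer, len_longer = m.s_span, ls
        else:
            span_shorter, len_shorter = m.s_span, ls
            span_longer, len_longer = m.q_span, lq
        if (
            span_shorter >= min_frac_shorter * len_shorter
            and span_longer >= min_frac_longer * len_longer
        ):
            kept.append(m)
    return kept


def ingest_match_table(stream: TextIO) -> list[Match]:
    """Parse BLAST-style 12-column tabular output (outfmt 6) into matches.

    Self-matches (qseqid == sseqid) are skipped; pident is rescaled to [0,1].
    """
    matches: list[Match] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ParseError(
                f"match table line {lineno}: expected 12 columns, got {len(cols)}"
            )
        q, s = cols[0], cols[1]
        if q == s:
            continue
        try:
            pident = float(cols[2])
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            evalue = float(cols[10])
            bitscore = float(cols[11])
        except ValueError as exc:
            raise ParseError(f"match table line {lineno}: {exc}") from exc
        query_uid, subject_uid = sorted((q, s))
        q_span = abs(qend - qstart) + 1
        s_span = abs(send - sstart) + 1
        q_range = (min(qstart, qend), max(qstart, qend))
        s_range = (min(sstart, send), max(sstart, send))
        if query_uid != q:
            q_span, s_span = s_span, q_span
            q_range, s_range = s_range, q_range
        matches.append(
            Match(
                query_uid=query_uid,
                subject_uid=subject_uid,
                q_span=q_span,
                s_span=s_span,
                identity=pident / 100.0,
                score=bitscore,
                evalue=evalue,
                q_range=q_range,
                s_range=s_range,
            )
        )
    return matches
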