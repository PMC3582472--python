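"""GFF3 reading/writing of candidate annotation trees.

Accepts both GFF3 dialects seen in de novo LTR retrotransposon predictions:
a bare ``LTR_retrotransposon`` root, and the LTRharvest/LTRdigest layout in
which the element is nested under a ``repeat_region`` together with its
target site duplications.  In both cases the candidate root is the
``LTR_retrotransposon`` node; siblings under a ``repeat_region`` (TSDs) are
re-attached as children of the candidate root.
"""

from __future__ import annotations

import re
from typing import TextIO

from gffutils.feature import Feature, feature_from_line

from .model import Candidate, FeatureNode, LtrfamError, ParseError, ROOT_TYPE

_SEQID_RE = re.compile(r"^seq\d+$")


def _node_from_feature(feat: Feature) -> tuple[FeatureNode, str | None, str | None]:
    """Convert a parsed GFF3 feature to a FeatureNode.

    Returns (node, id, parent_id); ID/Parent are kept out of node.attributes
    so that written files round-trip to structurally equal trees.
    """
    attrs: dict[str, str] = {}
    fid = parent = None
    for key in feat.attributes:
        values = ",".join(feat.attributes[key])
        if key == "ID":
            fid = values
        elif key == "Parent":
            parent = values
        else:
            attrs[key] = values
    score = None if feat.score in (".", "", None) else float(feat.score)
    node = FeatureNode(
        so_type=feat.featuretype,
        seqid=feat.seqid,
        start=feat.start,
        end=feat.end,
        strand=feat.strand if feat.strand else ".",
        score=score,
        attributes=attrs,
        source=feat.source or "ltrfam",
    )
    return node, fid, parent


def read_gff3(stream: TextIO, strict: bool = False) -> tuple[list[Candidate], list[str]]:
    """Parse GFF3 into candidates.

    One :class:`Candidate` per ``LTR_retrotransposon`` feature; root features
    of other types with no such descendant are ignored with a warning.
    """
    warnings: list[str] = []
    nodes: list[tuple[FeatureNode, str | None, str | None]] = []
    by_id: dict[str, FeatureNode] = {}
    bad_seqids: set[str] = set()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            if line.startswith("##FASTA"):
                break
            continue
        try:
            feat = feature_from_line(line)
            node, fid, parent = _node_from_feature(feat)
        except Exception as exc:
            raise ParseError(f"malformed GFF3 at line {lineno}: {exc}") from exc
        if not _SEQID_RE.match(node.seqid) and node.seqid not in bad_seqids:
            bad_seqids.add(node.seqid)
            msg = f"seqid {node.seqid!r} does not follow the seq<N> convention"
            if strict:
                raise ParseError(msg + " (strict mode)")
            warnings.append(msg)
        if fid is not None and fid in by_id:
            # multi-line (discontinuous) feature: join by extending the span
            first = by_id[fid]
            first.start = min(first.start, node.start)
            first.end = max(first.end, node.end)
            warnings.append(f"joined multi-line feature {fid!r}")
            continue
        if fid is not None:
            by_id[fid] = node
        nodes.append((node, fid, parent))

    roots: list[FeatureNode] = []
    for node, _fid, parent in nodes:
        if parent is None:
            roots.append(node)
            continue
        if parent not in by_id:
            raise ParseError(f"Parent {parent!r} references an unknown feature")
        try:
            by_id[parent].add_child(node)
        except LtrfamError as exc:
            raise ParseError(str(exc)) from exc

    candidates: list[Candidate] = []
    used_ids: set[str] = set()
    counter = 0
    id_of = {id(n): fid for n, fid, _ in nodes if fid is not None}

    def fresh_id() -> str:
        nonlocal counter
        while True:
            cid = f"cand_{counter}"
            counter += 1
            if cid not in used_ids:
                return cid

    for root in roots:
        elements = [n for n in root.traverse() if n.so_type == ROOT_TYPE]
        if not elements:
            warnings.append(f"ignored root feature of type {root.so_type!r}")
            continue
        adopted: set[int] = set()
        if root.so_type != ROOT_TYPE:
            # repeat_region dialect: re-root on the element, adopt siblings
            # (TSDs legitimately flank the element, so they are exempt from
            # the out-of-span check below)
            siblings = [c for c in root.children if c.so_type != ROOT_TYPE]
            if len(elements) > 1:
                warnings.append(
                    f"{len(elements)} elements under one {root.so_type!r}; "
                    "siblings attached to the first"
                )
            for sib in siblings:
                elements[0].add_child(sib)
                adopted.add(id(sib))
        for element in elements:
            cid = id_of.get(id(element))
            if cid is None or cid in used_ids:
                cid = fresh_id()
            used_ids.add(cid)
            for child in element.children:
                if id(child) in adopted:
                    continue
                if child.start < element.start or child.end > element.end:
                    warnings.append(
                        f"child {child.so_type} [{child.start},{child.end}] outside "
                        f"candidate {cid} span [{element.start},{element.end}]"
                    )
            cand = Candidate(id=cid, root=element)
            if len(cand.ltr_lengths) != 2:
                warnings.append(
                    f"candidate {cid} has {len(cand.ltr_lengths)} LTR children "
                    "(expected 2)"
                )
            candidates.append(cand)
    return candidates, warnings


def _format_feature(node: FeatureNode, fid: str | None, parent: str | None) -> str:
    attrs: dict[str, list[str]] = {}
    if fid is not None:
        attrs["ID"] = [fid]
    if parent is not None:
        attrs["Parent"] = [parent]
    for key, value in node.attributes.items():
        attrs[key] = [value]
    feat = Feature(
        seqid=node.seqid,
        source=node.source,
        featuretype=node.so_type,
        start=node.start,
        end=node.end,
        score="." if node.score is None else f"{node.score:g}",
        strand=node.strand,
        frame=".",
        attributes=attrs,
    )
    return str(feat)


def write_gff3(candidates: list[Candidate], stream: TextIO) -> None:
    """Serialize candidate trees; output begins with ``##gff-version 3``.

    Interior nodes receive generated IDs for Parent linkage; leaves are
    written without IDs so that reading the output back yields structurally
    identical trees.
    """
    stream.write("##gff-version 3\n")
    serial = 0
    for cand in candidates:
        stream.write(_format_feature(cand.root, cand.id, None) + "\n")

        def emit(node: FeatureNode, parent_id: str) -> None:
            nonlocal serial
            fid = None
            if node.children:
                fid = f"{parent_id}_f{serial}"
                serial += 1
            stream.write(_format_feature(node, fid, parent_id) + "\n")
            for child in sorted(node.children, key=lambda n: (n.start, n.end, n.so_type)):
                emit(child, fid)  # type: ignore[arg-type]

        for child in sorted(cand.root.children, key=lambda n: (n.start, n.end, n.so_type)):
            emit(child, cand.id)
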