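"""Project persistence: a single human-readable JSON file.

The genome is referenced by FASTA path plus SHA-256 checksum rather than
embedded (genomes are large; annotations are moderate).  A checksum
mismatch on load is a hard error: every coordinate in the project is
meaningless against a different sequence.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

from .matching import Match
from .model import Candidate, FeatureNode, LtrfamError, Project, RunLogEntry
from .seqio import read_fasta

FORMAT_VERSION = 1


def _node_to_dict(node: FeatureNode) -> dict:
    return {
        "type": node.so_type,
        "seqid": node.seqid,
        "start": node.start,
        "end": node.end,
        "strand": node.strand,
        "score": node.score,
        "attributes": node.attributes,
        "source": node.source,
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(data: dict) -> FeatureNode:
    node = FeatureNode(
        so_type=data["type"],
        seqid=data["seqid"],
        start=data["start"],
        end=data["end"],
        strand=data["strand"],
        score=data["score"],
        attributes=dict(data["attributes"]),
        source=data.get("source", "ltrfam"),
    )
    for child in data["children"]:
        node.add_child(_node_from_dict(child))
    return node


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_project(project: Project, path: str) -> None:
    data = {
        "format_version": FORMAT_VERSION,
        "fasta_path": project.fasta_path,
        "fasta_sha256": project.fasta_sha256,
        "candidates": {
            cid: _node_to_dict(c.root) for cid, c in sorted(project.candidates.items())
        },
        "families": project.families,
        "unclassified": project.unclassified,
        "run_log": [asdict(e) for e in project.run_log],
        "matches": [asdict(m) for m in project.matches],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_project(path: str) -> Project:
    with open(path) as fh:
        data = json.load(fh)
    project = Project()
    project.fasta_path = data.get("fasta_path")
    project.fasta_sha256 = data.get("fasta_sha256")
    if project.fasta_path:
        fasta = project.fasta_path
        if not os.path.isabs(fasta):
            fasta = os.path.join(os.path.dirname(os.path.abspath(path)), fasta)
        if not os.path.exists(fasta):
            raise LtrfamError(f"referenced FASTA {fasta!r} not found")
        digest = sha256_of(fasta)
        if project.fasta_sha256 and digest != project.fasta_sha256:
            raise LtrfamError(
                f"FASTA checksum mismatch for {fasta!r}: the sequence file "
                "changed since the project was saved"
            )
        with open(fasta) as fh:
            project.sequences, _ = read_fasta(fh)
    for cid, tree in data["candidates"].items():
        project.candidates[cid] = Candidate(id=cid, root=_node_from_dict(tree))
    project.families = {k: list(v) for k, v in data["families"].items()}
    project.unclassified = list(data["unclassified"])
    project.run_log = [RunLogEntry(**e) for e in data["run_log"]]
    project.matches = [
        Match(
            **{
                **m,
                "q_range": tuple(m["q_range"]) if m.get("q_range") else None,
                "s_range": tuple(m["s_range"]) if m.get("s_range") else None,
            }
        )
        for m in data.get("matches", [])
    ]
    return project


def attach_fasta(project: Project, fasta_path: str) -> list[str]:
    """Load sequences from a FASTA file and record its path + checksum."""
    with open(fasta_path) as fh:
        project.sequences, warnings = read_fasta(fh)
    project.fasta_path = fasta_path
    project.fasta_sha256 = sha256_of(fasta_path)
    return warnings
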