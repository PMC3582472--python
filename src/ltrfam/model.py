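"""Core data model: annotation feature trees, candidates, sequences, projects.

An LTR-retrotransposon candidate is represented as a rooted tree of GFF3-style
features (coordinates 1-based inclusive throughout).  The root is always a
feature of Sequence Ontology type ``LTR_retrotransposon``; internal features
(LTRs, target site duplications, primer binding site, polypurine tract,
protein domain matches, reading frames, reference matches) are its children.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

ROOT_TYPE = "LTR_retrotransposon"
LTR_TYPE = "long_terminal_repeat"
TSD_TYPE = "target_site_duplication"
PBS_TYPE = "primer_binding_site"
PPT_TYPE = "RR_tract"
DOMAIN_TYPE = "protein_match"
ORF_TYPE = "reading_frame"
REFMATCH_TYPE = "nucleotide_match"

#: sentinel family name for the project-wide unclassified list
UNCLASSIFIED = "__unclassified__"

VALID_STRANDS = ("+", "-", ".", "?")


class LtrfamError(Exception):
    """Base class for data errors raised by this package."""


class ParseError(LtrfamError):
    pass


@dataclass
class FeatureNode:
    """One annotation feature; a node of the candidate tree.

    ``start``/``end`` are 1-based inclusive genome coordinates on ``seqid``.
    """

    so_type: str
    seqid: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None
    attributes: dict[str, str] = field(default_factory=dict)
    children: list["FeatureNode"] = field(default_factory=list)
    source: str = "ltrfam"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise LtrfamError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise LtrfamError(f"end < start ({self.end} < {self.start})")
        if self.strand not in VALID_STRANDS:
            raise LtrfamError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def add_child(self, node: "FeatureNode") -> None:
        if node.seqid != self.seqid:
            raise LtrfamError(
                f"child seqid {node.seqid!r} differs from parent {self.seqid!r}"
            )
        self.children.append(node)

    def traverse(self) -> Iterator["FeatureNode"]:
        """Pre-order traversal of the subtree rooted here (self included)."""
        yield self
        for child in self.children:
            yield from child.traverse()

    def find(self, so_type: str) -> list["FeatureNode"]:
        return [n for n in self.traverse() if n.so_type == so_type]

    def equal_tree(self, other: "FeatureNode") -> bool:
        """Structural equality on (type, coords, strand, score, attributes)."""
        if (
            self.so_type != other.so_type
            or self.seqid != other.seqid
            or self.start != other.start
            or self.end != other.end
            or self.strand != other.strand
            or self.score != other.score
            or self.attributes != other.attributes
            or len(self.children) != len(other.children)
        ):
            return False
        mine = sorted(self.children, key=_child_sort_key)
        theirs = sorted(other.children, key=_child_sort_key)
        return all(a.equal_tree(b) for a, b in zip(mine, theirs))


def _child_sort_key(node: FeatureNode):
    return (node.start, node.end, node.so_type)


@dataclass
class Candidate:
    """A rooted ``LTR_retrotransposon`` feature tree with derived metrics."""

    id: str
    root: FeatureNode

    def __post_init__(self) -> None:
        if self.root.so_type != ROOT_TYPE:
            raise LtrfamError(
                f"candidate root must be {ROOT_TYPE}, got {self.root.so_type}"
            )

    @property
    def element_length(self) -> int:
        return self.root.length

    @property
    def ltr_lengths(self) -> list[int]:
        return [n.length for n in self.root.children if n.so_type == LTR_TYPE]

    @property
    def seqid(self) -> str:
        return self.root.seqid


class SequenceCollection:
    """Ordered nucleotide records addressable by the ``seqX`` convention.

    ``seqX`` resolves to record number X (0-based); any other seqid is looked
    up literally against record names.
    """

    def __init__(self, records: list[tuple[str, str]]):
        self.records = [(name, seq.upper()) for name, seq in records]
        self._by_name = {name: i for i, (name, _) in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, seqid: str) -> int:
        """Return the record index for a seqid; raise on failure."""
        if seqid.startswith("seq") and seqid[3:].isdigit():
            idx = int(seqid[3:])
            if idx >= len(self.records):
                raise LtrfamError(
                    f"seqid {seqid!r} references record {idx} but only "
                    f"{len(self.records)} records are loaded"
                )
            return idx
        if seqid in self._by_name:
            return self._by_name[seqid]
        raise LtrfamError(f"seqid {seqid!r} matches no loaded sequence")

    def get(self, seqid: str) -> str:
        return self.records[self.resolve(seqid)][1]


@dataclass
class RunLogEntry:
    number: int
    tool: str
    parameters: dict
    timestamp: str


class Project:
    """Sequences + candidates + families + unclassified list + run log.

    Every candidate id lives in exactly one container: a named family or the
    unclassified list.  Matching/clustering byproducts are cached on the
    project so the pipeline stages can be run as separate CLI invocations.
    """

    def __init__(self, sequences: Optional[SequenceCollection] = None):
        self.sequences = sequences or SequenceCollection([])
        self.candidates: dict[str, Candidate] = {}
        self.families: dict[str, list[str]] = {}
        self.unclassified: list[str] = []
        self.run_log: list[RunLogEntry] = []
        self.matches: list = []  # list[Match], populated by the match stage
        self.assignments: list = []  # list[ClusterAssignment]
        self.fasta_path: Optional[str] = None
        self.fasta_sha256: Optional[str] = None
        self._id_counter = itertools.count()

    # -- candidate containers -------------------------------------------------

    def add_candidate(self, candidate: Candidate) -> None:
        if candidate.id in self.candidates:
            raise LtrfamError(f"duplicate candidate id {candidate.id!r}")
        self.candidates[candidate.id] = candidate
        self.unclassified.append(candidate.id)

    def container_of(self, candidate_id: str) -> str:
        """Family name holding the candidate, or UNCLASSIFIED."""
        if candidate_id in self.unclassified:
            return UNCLASSIFIED
        for name, members in self.families.items():
            if candidate_id in members:
                return name
        raise LtrfamError(f"candidate {candidate_id!r} is in no container")

    def live_ids(self) -> list[str]:
        out = list(self.unclassified)
        for members in self.families.values():
            out.extend(members)
        return out

    def log_run(self, tool: str, parameters: dict) -> RunLogEntry:
        import datetime

        entry = RunLogEntry(
            number=len(self.run_log) + 1,
            tool=tool,
            parameters=dict(parameters),
            timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
        )
        self.run_log.append(entry)
        return entry

    def next_generated_id(self) -> str:
        while True:
            cid = f"cand_{next(self._id_counter)}"
            if cid not in self.candidates:
                return cid
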