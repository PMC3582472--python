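"""Convenience drivers chaining the pipeline stages.

The classification pipeline is: collect per-class feature sequences →
all-vs-all matching within classes → span filter → single-linkage
clustering → candidate signatures → cluster-compatibility joining.
Each stage is also exposed as its own CLI subcommand; this module simply
chains them with shared defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classification import apply_classification, classify
from .clustering import Signature, build_signatures, single_linkage
from .matching import collect_feature_sequences, match_all, span_filter
from .model import Project

DEFAULT_CLASSES = ("ltr", "pbs", "ppt", "domains")


@dataclass
class PipelineParams:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    seed_len: int = 10
    min_identity: float = 0.8
    min_frac_shorter: float = 0.8
    min_frac_longer: float = 0.3
    min_avg_len: float | None = 80.0
    split_domains: bool = True
    keep_private_clusters: bool = False
    prefix: str = "fam_"


@dataclass
class PipelineResult:
    signatures: list[Signature] = field(default_factory=list)
    n_matches: int = 0
    n_kept: int = 0
    warnings: list[str] = field(default_factory=list)


def run_match(project: Project, params: PipelineParams) -> PipelineResult:
    """Feature extraction + matching + span filtering; matches cached on
    the project."""
    result = PipelineResult()
    seqs = collect_feature_sequences(
        project, params.classes, split_domains=params.split_domains
    )
    matches, warnings = match_all(
        seqs,
        seed_len=params.seed_len,
        min_identity=params.min_identity,
        min_avg_len=params.min_avg_len,
    )
    result.warnings.extend(warnings)
    result.n_matches = len(matches)
    lengths = {fs.uid: fs.length for fs in seqs}
    kept = span_filter(
        matches,
        lengths,
        min_frac_shorter=params.min_frac_shorter,
        min_frac_longer=params.min_frac_longer,
    )
    result.n_kept = len(kept)
    project.matches = kept
    project.log_run(
        "match",
        {
            "classes": list(params.classes),
            "seed_len": params.seed_len,
            "min_identity": params.min_identity,
            "min_frac_shorter": params.min_frac_shorter,
            "min_frac_longer": params.min_frac_longer,
            "min_avg_len": params.min_avg_len,
        },
    )
    return result


def run_cluster(project: Project, params: PipelineParams) -> list[Signature]:
    """Single-linkage clustering of the cached matches + signatures."""
    seqs = collect_feature_sequences(
        project, params.classes, split_domains=params.split_domains
    )
    known = {fs.uid for fs in seqs}
    matches = [
        m for m in project.matches if m.query_uid in known and m.subject_uid in known
    ]
    assignments = single_linkage(
        seqs, matches, keep_private_clusters=params.keep_private_clusters
    )
    project.assignments = assignments
    signatures = build_signatures(assignments, sorted(project.candidates), seqs)
    project.log_run("cluster", {"classes": list(params.classes)})
    return signatures


def run_classify(
    project: Project, params: PipelineParams, signatures: list[Signature]
) -> dict[str, list[str]]:
    families, unclassified = classify(signatures, prefix=params.prefix)
    apply_classification(project, families, unclassified)
    project.log_run("classify", {"prefix": params.prefix})
    return families


def run_full(project: Project, params: PipelineParams | None = None) -> PipelineResult:
    """match → cluster → classify in one call."""
    params = params or PipelineParams()
    result = run_match(project, params)
    signatures = run_cluster(project, params)
    run_classify(project, params, signatures)
    result.signatures = signatures
    return result


def project_from_simulation(result) -> Project:
    """Build an in-memory project from a :func:`ltrfam.simulate.simulate`
    result (no files touched)."""
    import io

    from .gff3 import read_gff3
    from .seqio import read_fasta, write_fasta

    project = Project()
    buf = io.StringIO()
    write_fasta(result.records, buf)
    buf.seek(0)
    project.sequences, _ = read_fasta(buf)
    candidates, _ = read_gff3(io.StringIO(result.gff3))
    for cand in candidates:
        project.add_candidate(cand)
    return project
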