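"""Family assignment by cluster compatibility, and family maintenance.

Two candidates are *compatible* when, for every feature class on which both
carry cluster labels, their label sets intersect.  Compatibility tolerates
missing features (internal deletions leave a class empty on one side) while
still splitting candidates whose shared classes landed in different clusters.
Groups of pairwise-compatible candidates joined through shared cluster
labels become putative families; everything else stays unclassified.

Deletion semantics follow the workbench convention: removing a candidate
from a family returns it to the project-wide unclassified list; deleting it
from the unclassified list removes it from the project entirely.
"""

from __future__ import annotations

from typing import Iterable

from .clustering import Signature
from .model import LtrfamError, Project, UNCLASSIFIED


def compatible(a: Signature, b: Signature) -> bool:
    """Per-class label-set intersection on every class present in both."""
    for class_key, labels_a in a.entries.items():
        labels_b = b.entries.get(class_key)
        if labels_b is not None and not (labels_a & labels_b):
            return False
    return True


def classify(
    signatures: list[Signature], prefix: str = "fam_"
) -> tuple[dict[str, list[str]], list[str]]:
    """Join candidates into putative families by cluster compatibility.

    Greedy label-driven merging, pinned to a deterministic order for
    reproducibility: cluster labels are visited sorted by (class key,
    cluster id); for each label all groups containing a carrier of that
    label are merged iff every candidate pair across the union is
    compatible; this repeats to a fixed point.  Groups of >= 2 become
    families named ``prefix + index`` (index by smallest member id); the
    rest are unclassified.  A candidate sharing a cluster label with two or
    more distinct final families cannot be placed unambiguously and is
    withdrawn to the unclassified list.

    Returns (families: name -> ordered member ids, unclassified ids).
    """
    sigs = {s.candidate_id: s for s in signatures}
    order = sorted(sigs)
    groups: list[set[str]] = [{cid} for cid in order]
    all_labels = sorted({lab for s in signatures for lab in s.labels})

    def carriers(label) -> set[str]:
        return {cid for cid in order if label in sigs[cid].labels}

    changed = True
    while changed:
        changed = False
        for label in all_labels:
            holder_idxs = [
                i for i, g in enumerate(groups) if g & carriers(label)
            ]
            if len(holder_idxs) < 2:
                continue
            union: set[str] = set()
            for i in holder_idxs:
                union |= groups[i]
            members = sorted(union)
            ok = all(
                compatible(sigs[a], sigs[b])
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
            if ok:
                groups = [
                    g for i, g in enumerate(groups) if i not in holder_idxs[1:]
                ]
                groups[holder_idxs[0]] = union
                changed = True

    final = sorted((g for g in groups if len(g) >= 2), key=min)
    families = {f"{prefix}{i}": sorted(g) for i, g in enumerate(final)}
    unclassified = sorted(
        cid for g in groups if len(g) < 2 for cid in g
    )

    # ambiguity withdrawal: a candidate that shares labels with and is
    # compatible with >= 2 distinct families could have been placed in
    # either, so its assignment is arbitrary; it goes back to unclassified.
    # Mere label sharing with an *incompatible* family (e.g. two families
    # split on their LTR clusters but linked by a common domain cluster)
    # is not ambiguity: the conflict pins the candidate to its own family.
    family_labels = {
        name: set().union(*(sigs[cid].labels for cid in members))
        for name, members in families.items()
    }
    withdrawn: list[str] = []
    for name, members in families.items():
        for cid in list(members):
            placeable = sum(
                1
                for fname, labels in family_labels.items()
                if (labels & sigs[cid].labels)
                and all(
                    compatible(sigs[cid], sigs[other])
                    for other in families[fname]
                    if other != cid
                )
            )
            if placeable >= 2:
                withdrawn.append(cid)
    for cid in withdrawn:
        for members in families.values():
            if cid in members:
                members.remove(cid)
        unclassified.append(cid)
    families = {name: m for name, m in families.items() if m}
    return families, sorted(unclassified)


def apply_classification(
    project: Project, families: dict[str, list[str]], unclassified: Iterable[str]
) -> None:
    """Install a classification result on a project (replaces any previous)."""
    live = set(project.live_ids())
    project.families = {name: list(m) for name, m in families.items()}
    assigned = {cid for m in families.values() for cid in m}
    project.unclassified = sorted(
        (set(unclassified) | (live - assigned)) - assigned
    )


def discard_small_families(
    project: Project, min_members: int = 3, purge: bool = False
) -> int:
    """Remove families below the size threshold; members go to unclassified
    (or are deleted outright with ``purge``).  Returns number discarded."""
    doomed = [
        name for name, m in project.families.items() if len(m) < min_members
    ]
    for name in doomed:
        members = project.families.pop(name)
        if not purge:
            project.unclassified.extend(members)
        else:
            for cid in members:
                project.candidates.pop(cid, None)
    return len(doomed)


def move_candidate(project: Project, candidate_id: str, target: str) -> None:
    """Move a candidate to a family (created on the fly if new) or back to
    the unclassified list."""
    if candidate_id not in project.candidates:
        raise LtrfamError(f"unknown candidate {candidate_id!r}")
    source = project.container_of(candidate_id)
    if source == UNCLASSIFIED:
        project.unclassified.remove(candidate_id)
    else:
        project.families[source].remove(candidate_id)
        if not project.families[source]:
            del project.families[source]
    if target == UNCLASSIFIED:
        project.unclassified.append(candidate_id)
    else:
        project.families.setdefault(target, []).append(candidate_id)


def delete_candidate(project: Project, candidate_id: str) -> None:
    """Delete semantics: from a family -> unclassified; from the
    unclassified list -> removed from the project entirely."""
    if candidate_id not in project.candidates:
        raise LtrfamError(f"unknown candidate {candidate_id!r}")
    container = project.container_of(candidate_id)
    if container == UNCLASSIFIED:
        project.unclassified.remove(candidate_id)
        del project.candidates[candidate_id]
    else:
        move_candidate(project, candidate_id, UNCLASSIFIED)


def rename_family(project: Project, old: str, new: str) -> None:
    if old not in project.families:
        raise LtrfamError(f"unknown family {old!r}")
    if new in project.families and new != old:
        raise LtrfamError(f"family name {new!r} already in use")
    project.families = {
        (new if name == old else name): members
        for name, members in project.families.items()
    }
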