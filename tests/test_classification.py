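"""Cluster-compatibility family joining and family maintenance semantics."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ltrfam.classification import (
    apply_classification,
    classify,
    compatible,
    delete_candidate,
    discard_small_families,
    move_candidate,
    rename_family,
)
from ltrfam.clustering import Signature
from ltrfam.model import LtrfamError, Project, UNCLASSIFIED
from ltrfam.pipeline import PipelineParams, project_from_simulation, run_full
from ltrfam.simulate import FamilySpec, simulate


def _sig(cid, **entries):
    return Signature(
        candidate_id=cid,
        entries={k: frozenset(v) for k, v in entries.items()},
    )


class TestCompatibility:
    def test_identical_signatures_compatible(self):
        a = _sig("A", ltr={0}, rt={1})
        b = _sig("B", ltr={0}, rt={1})
        assert compatible(a, b)

    def test_disjoint_shared_class_incompatible(self):
        a = _sig("A", ltr={0}, rt={1})
        b = _sig("B", ltr={0}, rt={2})
        assert not compatible(a, b)

    def test_missing_class_tolerated(self):
        # internal deletion: one candidate has no RT labels at all
        a = _sig("A", ltr={0}, rt={1})
        b = _sig("B", ltr={0})
        assert compatible(a, b)


class TestClassify:
    def test_identical_signatures_one_family(self):
        families, unclassified = classify(
            [_sig("A", ltr={0}, rt={1}), _sig("B", ltr={0}, rt={1})]
        )
        assert families == {"fam_0": ["A", "B"]}
        assert unclassified == []

    def test_conflicting_rt_clusters_not_joined(self):
        families, unclassified = classify(
            [_sig("A", ltr={0}, rt={1}), _sig("B", ltr={0}, rt={2})]
        )
        assert families == {}
        assert unclassified == ["A", "B"]

    def test_singletons_stay_unclassified(self):
        families, unclassified = classify([_sig("A"), _sig("B", ltr={0})])
        assert families == {}
        assert set(unclassified) == {"A", "B"}

    def test_ltr_variant_split_with_shared_domain_cluster(self):
        """Two LTR variants inside one nominal family break compatibility
        and yield two families, even though all copies share the RT
        cluster."""
        sigs = [
            _sig("A1", ltr={0}, rt={0}),
            _sig("A2", ltr={0}, rt={0}),
            _sig("B1", ltr={1}, rt={0}),
            _sig("B2", ltr={1}, rt={0}),
        ]
        families, unclassified = classify(sigs)
        assert len(families) == 2
        partitions = sorted(tuple(m) for m in families.values())
        assert partitions == [("A1", "A2"), ("B1", "B2")]
        assert unclassified == []

    def test_ambiguous_candidate_withdrawn(self):
        # X is compatible with, and label-linked to, both families
        sigs = [
            _sig("A1", ltr={0}, rt={0}),
            _sig("A2", ltr={0}, rt={0}),
            _sig("B1", ltr={1}, ppt={5}),
            _sig("B2", ltr={1}, ppt={5}),
            _sig("X", rt={0}, ppt={5}),
        ]
        families, unclassified = classify(sigs)
        assert "X" in unclassified
        assert all("X" not in m for m in families.values())

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(5)
        sigs = [
            _sig(f"c{i:02d}", ltr={i % 3}, rt={i % 3}) for i in range(12)
        ]
        ref = classify(sigs)
        for _ in range(5):
            perm = list(sigs)
            rng.shuffle(perm)
            assert classify(perm) == ref

    def test_all_pairs_in_a_family_are_compatible(self):
        rng = np.random.default_rng(17)
        sigs = []
        for i in range(30):
            entries = {}
            for cls in ("ltr", "rt", "rh"):
                if rng.random() < 0.8:
                    entries[cls] = {int(rng.integers(0, 5))}
            sigs.append(_sig(f"c{i:02d}", **entries))
        families, _ = classify(sigs)
        by_id = {s.candidate_id: s for s in sigs}
        for members in families.values():
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert compatible(by_id[a], by_id[b])

    def test_matches_bruteforce_merge_oracle_conflict_free(self):
        """On conflict-free signatures the final partition equals the
        connected components of the share-a-label graph (computed by an
        independent exhaustive pairwise merge)."""
        rng = np.random.default_rng(23)
        sigs = []
        for i in range(30):
            group = int(rng.integers(0, 5))
            entries = {}
            for cls in ("ltr", "rt", "rh"):
                if rng.random() < 0.7:
                    entries[cls] = {group}
            sigs.append(_sig(f"c{i:02d}", **entries))
        by_id = {s.candidate_id: s for s in sigs}

        # oracle: exhaustive merging of any two label-sharing compatible groups
        groups = [{s.candidate_id} for s in sigs]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    share = any(
                        by_id[a].labels & by_id[b].labels
                        for a in groups[i]
                        for b in groups[j]
                    )
                    comp = all(
                        compatible(by_id[a], by_id[b])
                        for a in groups[i]
                        for b in groups[j]
                    )
                    if share and comp:
                        groups[i] |= groups[j]
                        del groups[j]
                        changed = True
                        break
                if changed:
                    break
        oracle = sorted(
            tuple(sorted(g)) for g in groups if len(g) >= 2
        )
        families, _ = classify(sigs)
        assert sorted(tuple(m) for m in families.values()) == oracle

    def test_recovers_simulated_partition_exactly(self):
        specs = [
            FamilySpec(name=f"f{k}", n_copies=4, mutation_rate=0.005,
                       superfamily="COPIA" if k % 2 else "GYPSY")
            for k in range(3)
        ]
        result = simulate(specs, genome_len=80_000, seed=31)
        project = project_from_simulation(result)
        run_full(project, PipelineParams())
        truth = {row.candidate_id: row.family for row in result.truth}
        predicted = {}
        for name, members in project.families.items():
            for cid in members:
                predicted[cid] = name
        for i, cid in enumerate(project.unclassified):
            predicted[cid] = f"__single_{i}"
        ids = sorted(truth)
        ari = adjusted_rand_score(
            [truth[c] for c in ids], [predicted[c] for c in ids]
        )
        assert ari == 1.0


class TestFamilyMaintenance:
    def _project_with_sizes(self, sizes):
        project = Project()
        from ltrfam.model import Candidate, FeatureNode

        n = 0
        families = {}
        for fi, size in enumerate(sizes):
            name = f"fam_{fi}"
            families[name] = []
            for _ in range(size):
                cid = f"c{n:03d}"
                n += 1
                root = FeatureNode("LTR_retrotransposon", "seq0", 1, 100)
                project.candidates[cid] = Candidate(id=cid, root=root)
                families[name].append(cid)
        project.families = families
        return project

    def test_discard_small_families(self):
        project = self._project_with_sizes([5, 2, 3, 1])
        n = discard_small_families(project, min_members=3)
        assert n == 2
        assert sorted(len(m) for m in project.families.values()) == [3, 5]
        assert len(project.unclassified) == 3

    def test_discard_none_when_all_large(self):
        project = self._project_with_sizes([3, 4, 5])
        assert discard_small_families(project, min_members=3) == 0

    def test_two_member_family_purge_profile(self):
        # size profile mirroring a mammalian-genome survey: 171 putative
        # families of which 76 have exactly two members
        sizes = [2] * 76 + [3] * 95
        project = self._project_with_sizes(sizes)
        n = discard_small_families(project, min_members=3)
        assert n == 76
        assert len(project.families) == 95

    def test_move_family_member_to_unclassified(self):
        project = self._project_with_sizes([3])
        cid = project.families["fam_0"][0]
        move_candidate(project, cid, UNCLASSIFIED)
        assert cid in project.unclassified
        assert cid not in project.families["fam_0"]

    def test_delete_from_unclassified_removes_entirely(self):
        project = self._project_with_sizes([2])
        cid = project.families["fam_0"][0]
        move_candidate(project, cid, UNCLASSIFIED)
        delete_candidate(project, cid)
        assert cid not in project.candidates
        assert cid not in project.live_ids()

    def test_delete_from_family_goes_to_unclassified(self):
        project = self._project_with_sizes([2])
        cid = project.families["fam_0"][0]
        delete_candidate(project, cid)
        assert cid in project.unclassified
        assert cid in project.candidates

    def test_move_to_new_family_created_on_the_fly(self):
        project = self._project_with_sizes([2])
        cid = project.families["fam_0"][0]
        before = len(project.families)
        move_candidate(project, cid, "manual_1")
        assert len(project.families) == before + 1
        assert project.families["manual_1"] == [cid]

    def test_rename_preserves_members_and_round_trips(self):
        project = self._project_with_sizes([3, 2])
        members = list(project.families["fam_0"])
        rename_family(project, "fam_0", "fam_0 (mdg3)")
        assert project.families["fam_0 (mdg3)"] == members
        rename_family(project, "fam_0 (mdg3)", "fam_0")
        assert project.families["fam_0"] == members

    def test_rename_collision_errors(self):
        project = self._project_with_sizes([2, 2])
        with pytest.raises(LtrfamError):
            rename_family(project, "fam_0", "fam_1")

    def test_conservation_every_live_candidate_in_one_container(self):
        project = self._project_with_sizes([4, 2, 1])
        total = len(project.candidates)
        move_candidate(project, "c000", UNCLASSIFIED)
        discard_small_families(project, min_members=3)
        delete_candidate(project, "c000")
        live = project.live_ids()
        assert len(live) == len(set(live)) == len(project.candidates) == total - 1

    def test_apply_classification_covers_all_live(self):
        project = self._project_with_sizes([3])
        ids = sorted(project.candidates)
        apply_classification(project, {"f": ids[:2]}, [])
        assert set(project.live_ids()) == set(ids)
        assert project.unclassified == [ids[2]]
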