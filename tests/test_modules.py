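"""Profiles, uncentered-Pearson distances, clustering, rescue, network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.cluster.hierarchy import fcluster

from apmskit import (
    DataError,
    Edge,
    InteractionNetwork,
    PipelineConfig,
    compute_nsaf,
    enumerate_family_dimers,
    gene_distance_matrix,
    hierarchical_modules,
    recall_vs_reference,
    relative_abundance,
    rescue_subthreshold,
    uncentered_correlation,
)

from oracles import average_linkage_three


def gdm_from(profiles: dict):
    return gene_distance_matrix(pd.DataFrame(profiles).T)


class TestRelativeAbundance:
    def test_prey_equal_to_bait_gives_one(self, tiny_dataset):
        nsaf = compute_nsaf(tiny_dataset)
        rel = relative_abundance(nsaf, tiny_dataset)
        assert rel.loc["BAIT1", "BAIT1"] == pytest.approx(1.0)
        assert rel.loc["BAIT2", "BAIT2"] == pytest.approx(1.0)

    def test_zero_included_in_replicate_mean(self):
        from apmskit import Dataset, ProteinRecord
        from conftest import make_run

        proteins = {"B": ProteinRecord("B", 100, True), "P": ProteinRecord("P", 100)}
        runs = [make_run("r1", "B", {"B": 10, "P": 2}, replicate=1),
                make_run("r2", "B", {"B": 10}, replicate=2)]
        ds = Dataset(proteins=proteins, runs=runs)
        rel = relative_abundance(compute_nsaf(ds), ds)
        # ratios are {0.2, 0.0} -> mean 0.1
        assert rel.loc["P", "B"] == pytest.approx(0.1)

    def test_bait_missing_from_own_run_is_error(self, tiny_dataset):
        nsaf = compute_nsaf(tiny_dataset)
        nsaf.loc["b1r1", "BAIT1"] = 0.0
        with pytest.raises(DataError, match="b1r1"):
            relative_abundance(nsaf, tiny_dataset)


class TestGeneDistanceMatrix:
    def test_identical_profiles_distance_zero(self):
        gdm = gdm_from({"x": [1, 2, 3], "y": [1, 2, 3]})
        assert gdm.distance("x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_distance_one(self):
        gdm = gdm_from({"x": [1, 0, 0], "y": [0, 1, 0]})
        assert gdm.distance("x", "y") == pytest.approx(1.0)

    def test_hand_computed_uncentered_correlation(self):
        # x=(1,2), y=(2,1): r_u = 4/5, d = 0.2
        assert uncentered_correlation(np.array([1.0, 2.0]),
                                      np.array([2.0, 1.0])) == pytest.approx(0.8)
        gdm = gdm_from({"x": [1, 2], "y": [2, 1]})
        assert gdm.distance("x", "y") == pytest.approx(0.2)

    def test_all_zero_profile_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            gdm = gdm_from({"x": [1, 0], "y": [0, 1], "z": [0, 0]})
        assert "z" not in gdm
        assert "all-zero" in caplog.text

    def test_single_profile_rejected(self):
        with pytest.raises(DataError):
            gdm_from({"x": [1, 0], "z": [0, 0]})

    @given(arrays(float, (4, 3), elements=st.floats(0, 10, allow_nan=False)))
    def test_symmetry_and_range_on_nonnegative_profiles(self, mat):
        mat = mat + 1e-6  # keep profiles non-zero
        gdm = gdm_from({f"p{i}": row for i, row in enumerate(mat)})
        d = gdm.values.to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d), 0.0)


class TestHierarchicalModules:
    def test_two_identical_blocks_recovered_exactly(self):
        profiles = {f"a{i}": [1.0, 1.0, 0.0] for i in range(3)}
        profiles.update({f"b{i}": [0.0, 0.0, 1.0] for i in range(3)})
        modules = hierarchical_modules(gdm_from(profiles), 2)
        labels_a = {modules.labels[f"a{i}"] for i in range(3)}
        labels_b = {modules.labels[f"b{i}"] for i in range(3)}
        assert labels_a == {1} and labels_b == {2}

    def test_three_profile_merge_order_matches_brute_force(self):
        profiles = {"a": [1.0, 0.2, 0.0], "b": [0.9, 0.3, 0.1], "c": [0.0, 0.1, 1.0]}
        gdm = gdm_from(profiles)
        modules = hierarchical_modules(gdm, 1)
        ids = modules.ids  # lexicographic: a, b, c
        oracle = average_linkage_three(gdm.values.loc[ids, ids].to_numpy())
        z = modules.linkage_matrix
        first_pair = frozenset(int(v) for v in z[0, :2])
        assert first_pair == oracle[0][0]
        assert z[0, 2] == pytest.approx(oracle[0][1])
        assert z[1, 2] == pytest.approx(oracle[1][1])

    def test_cut_to_singletons(self):
        profiles = {"a": [1.0, 0.0], "b": [0.5, 0.5], "c": [0.0, 1.0]}
        modules = hierarchical_modules(gdm_from(profiles), 3)
        assert sorted(modules.labels.values()) == [1, 2, 3]

    def test_deterministic_across_repeats(self):
        rng = np.random.default_rng(2)
        profiles = {f"p{i}": rng.random(5) for i in range(12)}
        a = hierarchical_modules(gdm_from(profiles), 3)
        b = hierarchical_modules(gdm_from(profiles), 3)
        assert a.labels == b.labels
        assert np.array_equal(a.linkage_matrix, b.linkage_matrix)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        profiles = {f"p{i}": rng.random(4) for i in range(10)}
        z = hierarchical_modules(gdm_from(profiles), 2).linkage_matrix
        heights = z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestRescue:
    def _candidates(self):
        return pd.DataFrame([
            {"bait": "B1", "prey": "H1", "is_hcip": True, "passed_enrichment": True},
            {"bait": "B1", "prey": "S1", "is_hcip": False, "passed_enrichment": True},
            {"bait": "B1", "prey": "S2", "is_hcip": False, "passed_enrichment": True},
            {"bait": "B1", "prey": "S3", "is_hcip": False, "passed_enrichment": False},
        ])

    def _gdm(self):
        # S1 correlates with H1; S2 orthogonal to H1; S3 correlates with H1
        return gdm_from({"H1": [1.0, 0.5, 0.0], "S1": [0.8, 0.6, 0.0],
                         "S2": [0.0, 0.0, 1.0], "S3": [1.0, 0.4, 0.0]})

    def test_correlated_subthreshold_prey_rescued(self):
        rescued = rescue_subthreshold(self._candidates(), self._gdm())
        assert ("B1", "S1") in rescued

    def test_orthogonal_prey_not_rescued(self):
        rescued = rescue_subthreshold(self._candidates(), self._gdm())
        assert ("B1", "S2") not in rescued

    def test_enrichment_failing_prey_not_eligible(self):
        rescued = rescue_subthreshold(self._candidates(), self._gdm())
        assert ("B1", "S3") not in rescued

    def test_passing_pair_untouched(self):
        rescued = rescue_subthreshold(self._candidates(), self._gdm())
        assert ("B1", "H1") not in rescued

    def test_prey_absent_from_gdm_not_rescued(self):
        cands = self._candidates()
        cands.loc[len(cands)] = {"bait": "B1", "prey": "UNSEEN", "is_hcip": False,
                                 "passed_enrichment": True}
        rescued = rescue_subthreshold(cands, self._gdm())
        assert ("B1", "UNSEEN") not in rescued


class TestAssembleAndRecall:
    def test_union_of_passing_and_rescued(self):
        from apmskit import assemble_network

        scores = pd.DataFrame([
            {"bait": "B1", "prey": "P1", "is_hcip": True, "wdn": 2.0, "enrichment": 20.0},
            {"bait": "B1", "prey": "P2", "is_hcip": True, "wdn": 1.5, "enrichment": 15.0},
            {"bait": "B1", "prey": "P3", "is_hcip": False, "wdn": 0.5, "enrichment": 30.0},
            {"bait": "B1", "prey": "P4", "is_hcip": False, "wdn": 0.1, "enrichment": 2.0},
        ])
        net = assemble_network(scores, rescued={("B1", "P3")})
        assert net.pairs == {("B1", "P1"), ("B1", "P2"), ("B1", "P3")}
        assert net.get("B1", "P3").attrs["rescued"]
        assert not net.get("B1", "P1").attrs["rescued"]
        # rescue only ever adds edges
        assert net.pairs >= {("B1", "P1"), ("B1", "P2")}

    def test_empty_network_allowed_with_warning(self, caplog):
        from apmskit import assemble_network

        scores = pd.DataFrame([{"bait": "B1", "prey": "P1", "is_hcip": False}])
        with caplog.at_level("WARNING"):
            net = assemble_network(scores)
        assert len(net) == 0
        assert "empty" in caplog.text

    def test_recall_toy(self):
        net = InteractionNetwork([Edge("A", "B"), Edge("C", "D"), Edge("E", "F"),
                                  Edge("G", "H")])
        reference = {("A", "B"): 1, ("C", "D"): 2, ("E", "F"): 1, ("X", "Y"): 3,
                     ("U", "V"): 1, ("M", "N"): 1, ("O", "P"): 1, ("Q", "R"): 1,
                     ("S", "T"): 1, ("I", "J"): 1}
        assert recall_vs_reference(net, reference, 1) == pytest.approx(0.3)
        # stratum with >1 publication: {CD, XY}; only CD found
        assert recall_vs_reference(net, reference, 2) == pytest.approx(0.5)

    def test_recall_superset_is_one_and_empty_zero(self):
        reference = {("A", "B"): 1}
        assert recall_vs_reference(InteractionNetwork([Edge("A", "B"), Edge("A", "C")]),
                                   reference) == 1.0
        assert recall_vs_reference(InteractionNetwork(), reference) == 0.0

    def test_recall_empty_stratum_is_error(self):
        with pytest.raises(DataError):
            recall_vs_reference(InteractionNetwork([Edge("A", "B")]),
                                {("A", "B"): 1}, min_publications=5)


class TestFamilyDimers:
    def test_triangle_toy(self):
        net = InteractionNetwork([Edge("a", "b"), Edge("a", "c")])
        assert enumerate_family_dimers(net, {"a", "b", "c"}) == 2

    def test_empty_network(self):
        assert enumerate_family_dimers(InteractionNetwork(), {"a", "b"}) == 0

    def test_out_of_family_edges_ignored(self):
        net = InteractionNetwork([Edge("a", "b"), Edge("a", "z")])
        assert enumerate_family_dimers(net, {"a", "b"}) == 1
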