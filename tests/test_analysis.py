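import numpy as np
import pandas as pd
import pytest

from npcbasket.analysis import (
    cluster,
    localization_density,
    model_precision,
    pairwise_rmsd_matrix,
    rmsd,
    sampling_precision,
    satisfaction_report,
    select_good_scoring,
)
from npcbasket.restraints import RestraintBundle
from npcbasket.sampling import ModelEnsemble
from .conftest import two_copy_state


def make_ensemble(topology, frames, scores):
    frames = np.asarray(frames)
    n = len(frames)
    return ModelEnsemble(
        topology=topology,
        frames=frames,
        scores=np.asarray(scores, dtype=float),
        breakdowns=pd.DataFrame({"crosslink": np.zeros(n)}),
        provenance=pd.DataFrame({"run": np.zeros(n, int),
                                 "replica": np.zeros(n, int),
                                 "step": np.arange(n)}),
    )


class TestSelection:
    def make(self, toy_state):
        frames = np.repeat(toy_state.coords[None], 5, axis=0)
        return make_ensemble(toy_state, frames, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_percentile_100_keeps_everything(self, toy_state):
        sel, report = select_good_scoring(self.make(toy_state), percentile=100)
        assert len(sel) == 5 and report["n_selected"] == 5

    def test_known_cutoff_keeps_expected_survivors(self, toy_state):
        ens = self.make(toy_state)
        sel, _ = select_good_scoring(ens, percentile=60)
        assert len(sel) == 3
        assert sel.scores.tolist() == [1.0, 2.0, 3.0]

    def test_impossible_threshold_warns_empty(self, toy_state):
        ens = self.make(toy_state)
        with pytest.warns(UserWarning, match="no good-scoring"):
            sel, report = select_good_scoring(
                ens, per_term_thresholds={"crosslink": -1.0}
            )
        assert len(sel) == 0 and report["n_selected"] == 0


class TestRmsd:
    def test_identical_states_zero(self):
        a = two_copy_state()
        assert rmsd(a, a) == 0.0

    def test_uniform_shift_equals_shift_norm(self):
        a, b = two_copy_state(), two_copy_state(shift=(2.0, 0, 0))
        assert rmsd(a, b) == pytest.approx(2.0)

    def test_swapped_copies_recovered_by_permutation(self):
        a = two_copy_state()
        b = two_copy_state()
        # exchange the two copies in space
        ia = a.get_chain("X", 0).coarse
        ib = a.get_chain("X", 1).coarse
        b.coords[ia] = a.coords[ib]
        b.coords[ib] = a.coords[ia]
        assert rmsd(a, b) > 10.0
        assert rmsd(a, b, allow_copy_permutation=True) == pytest.approx(0.0)

    def test_topology_mismatch_rejected(self, toy_state):
        with pytest.raises(ValueError, match="topology"):
            rmsd(toy_state, two_copy_state())

    def test_matrix_agrees_with_pairwise_calls(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(4, 6, 3))
        mat = pairwise_rmsd_matrix(frames)
        for i in range(4):
            for j in range(4):
                expect = np.sqrt(((frames[i] - frames[j]) ** 2).sum() / 6)
                assert mat[i, j] == pytest.approx(expect, abs=1e-6)


class TestClustering:
    def test_identical_frames_one_cluster(self):
        frames = np.zeros((6, 3, 3))
        cr = cluster(frames, threshold=1.0)
        assert len(cr.clusters) == 1 and len(cr.clusters[0]) == 6

    def test_two_blobs_split_at_small_threshold(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(scale=1.0, size=(10, 4, 3))
        blob2 = blob1 + 100.0
        cr = cluster(np.vstack([blob1, blob2]), threshold=10.0)
        assert len(cr.clusters) == 2
        assert sorted(len(c) for c in cr.clusters) == [10, 10]

    def test_infinite_threshold_one_cluster(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(scale=50, size=(12, 4, 3))
        cr = cluster(frames, threshold=np.inf)
        assert len(cr.clusters) == 1

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(scale=5, size=(20, 4, 3))
        cr = cluster(frames, threshold=8.0)
        all_members = np.sort(np.concatenate(cr.clusters))
        np.testing.assert_array_equal(all_members, np.arange(20))


class TestModelPrecision:
    def test_identical_members_zero(self):
        assert model_precision(np.zeros((4, 3, 3)))["pairwise"] == 0.0

    def test_two_members_equals_their_rmsd(self):
        a = np.zeros((2, 3))
        b = np.full((2, 3), 4.0 / np.sqrt(3))  # rmsd 4
        mp = model_precision(np.stack([a, b]))
        assert mp["pairwise"] == pytest.approx(4.0)

    def test_three_members_mean_of_pairs(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(size=(3, 5, 3))
        mat = pairwise_rmsd_matrix(frames)
        expect = (mat[0, 1] + mat[0, 2] + mat[1, 2]) / 3
        assert model_precision(frames)["pairwise"] == pytest.approx(expect)

    def test_singleton_notes_it(self):
        mp = model_precision(np.zeros((1, 3, 3)))
        assert mp["pairwise"] == 0.0 and "note" in mp


class TestSamplingPrecision:
    grid = np.arange(1.0, 30.0, 1.0)

    def test_duplicated_half_passes_at_smallest_threshold(self):
        rng = np.random.default_rng(0)
        half = rng.normal(scale=5.0, size=(40, 4, 3))
        frames = np.vstack([half, half])
        halves = np.r_[np.zeros(40, int), np.ones(40, int)]
        scores = np.tile(rng.normal(size=40), 2)
        rep = sampling_precision(frames, halves, self.grid, scores=scores)
        assert rep.precision == self.grid[0]
        assert rep.score_pvalue > 0.05

    def test_gaussian_cloud_precision_below_3_sigma(self):
        rng = np.random.default_rng(1)
        sigma = 5.0
        frames = rng.normal(scale=sigma, size=(120, 4, 3))
        halves = (np.arange(120) % 2).astype(int)
        rep = sampling_precision(frames, halves, self.grid,
                                 scores=rng.normal(size=120))
        assert rep.precision is not None
        assert rep.precision <= 3 * sigma

    def test_unbalanced_bimodal_fails_population_test_at_small_thresholds(self):
        rng = np.random.default_rng(2)
        mode_a = rng.normal(scale=1.0, size=(100, 4, 3))
        mode_b = rng.normal(scale=1.0, size=(100, 4, 3)) + 100.0
        # half 0: 90/10, half 1: 10/90
        frames = np.vstack([mode_a[:90], mode_b[:10], mode_a[90:], mode_b[10:]])
        halves = np.r_[np.zeros(100, int), np.ones(100, int)]
        rep = sampling_precision(frames, halves, np.array([2.0, 5.0, 10.0]))
        small = rep.table[rep.table.threshold <= 10.0]
        assert not small.passes.any()
        assert (small.cramers_v >= 0.10).all()

    def test_unimodal_precision_bounded_by_cluster_spread(self):
        # on a single-mode ensemble the sampling precision cannot exceed the
        # merged cluster's model precision (up to one grid step)
        rng = np.random.default_rng(5)
        frames = rng.normal(scale=5.0, size=(120, 4, 3))
        halves = (np.arange(120) % 2).astype(int)
        rep = sampling_precision(frames, halves, self.grid)
        spread = model_precision(frames)["pairwise"]
        assert rep.precision is not None
        assert rep.precision <= spread + (self.grid[1] - self.grid[0])

    def test_single_run_demands_independent_runs(self):
        with pytest.raises(ValueError, match="independent"):
            sampling_precision(np.zeros((10, 2, 3)), np.zeros(10, int), self.grid)


class TestLocalizationDensity:
    def test_single_model_support_is_its_envelope(self, yeast_truth):
        values, origin, voxel = localization_density([yeast_truth], "Strut",
                                                     voxel_size=20.0)
        assert values.max() == 1.0
        assert set(np.unique(values)) <= {0.0, 1.0}

    def test_disjoint_models_peak_at_half(self, yeast_truth):
        moved = yeast_truth.copy()
        moved.coords = yeast_truth.coords + np.array([500.0, 0.0, 0.0])
        values, _, _ = localization_density([yeast_truth, moved], "Strut",
                                            voxel_size=20.0)
        assert values.max() == pytest.approx(0.5)

    def test_identical_members_binary_map(self, yeast_truth):
        values, _, _ = localization_density([yeast_truth] * 4, "Strut",
                                            voxel_size=25.0)
        assert set(np.unique(values)) <= {0.0, 1.0}
        assert values.max() == 1.0

    def test_integral_matches_mean_envelope_volume(self, yeast_truth):
        # map integral = mean of member envelope volumes (indicator average)
        moved = yeast_truth.copy()
        moved.coords = yeast_truth.coords + np.array([300.0, 0.0, 0.0])
        members = [yeast_truth, moved]
        values, _, voxel = localization_density(members, "Strut", voxel_size=20.0)
        total = values.sum() * voxel**3
        vols = []
        for m in members:
            v, _, vox = localization_density([m], "Strut", voxel_size=20.0)
            vols.append(v.sum() * vox**3)
        assert total == pytest.approx(np.mean(vols), rel=0.05)

    def test_unknown_selector_rejected(self, yeast_truth):
        with pytest.raises(ValueError, match="selector"):
            localization_density([yeast_truth], "Nothing")


class TestSatisfactionReport:
    def test_truth_ensemble_on_noiseless_bundle(self, yeast_bundle):
        rb = RestraintBundle(
            crosslinks=yeast_bundle.crosslinks,
            map_gmm=yeast_bundle.density,
            positional=yeast_bundle.terminal_localizations,
        )
        rep = satisfaction_report([yeast_bundle.truth_state], rb)
        assert rep["crosslink_satisfaction_ensemble"] == 1.0
        assert rep["centroid_em_cc"] == pytest.approx(1.0, abs=1e-9)
        assert rep["positional_violations"] == []

    def test_three_of_four_links_is_75_percent(self):
        from npcbasket.assembly import AssemblyState
        from npcbasket.restraints import CrosslinkRecord

        st = AssemblyState.from_chains([
            {"subunit": "A", "copy_index": 0,
             "centers": np.array([[0.0, 0, 0], [20.0, 0, 0], [40.0, 0, 0]]),
             "radii": np.full(3, 3.0),
             "resranges": np.array([[1, 10], [11, 20], [21, 30]])},
        ])
        links = [
            CrosslinkRecord("A", 5, "A", 15),   # 20 A, satisfied
            CrosslinkRecord("A", 15, "A", 25),  # 20 A, satisfied
            CrosslinkRecord("A", 6, "A", 16),   # 20 A, satisfied
            CrosslinkRecord("A", 5, "A", 25),   # 40 A, violated at 35 A
        ]
        rep = satisfaction_report([st], RestraintBundle(crosslinks=links))
        assert rep["crosslink_satisfaction_ensemble"] == pytest.approx(0.75)

    def test_ensemble_level_at_least_per_model(self, yeast_bundle):
        rng = np.random.default_rng(0)
        rb = RestraintBundle(crosslinks=yeast_bundle.crosslinks)
        members = []
        for _ in range(3):
            st = yeast_bundle.truth_state.copy()
            st.coords = yeast_bundle.truth_state.coords + rng.normal(
                scale=15.0, size=st.coords.shape
            )
            members.append(st)
        rep = satisfaction_report(members, rb)
        assert (rep["crosslink_satisfaction_ensemble"]
                >= rep["crosslink_satisfaction_per_model"] - 1e-12)
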