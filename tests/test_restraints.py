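import numpy as np
import pytest

from npcbasket.assembly import AssemblyState
from npcbasket.gmm import GaussianMixture, cross_correlation, model_to_gmm
from npcbasket.restraints import (
    CrosslinkRecord,
    PositionalSpec,
    ProximityPair,
    RestraintBundle,
    RestraintSetupError,
    RestraintWeights,
    ScoringFunction,
    score_connectivity,
    score_crosslinks,
    score_em,
    score_equivalence,
    score_excluded_volume,
    score_positional,
    score_proximity,
    total_score,
)


def chain(subunit, centers, radii, resranges, copy_index=0):
    return {
        "subunit": subunit, "copy_index": copy_index,
        "centers": np.asarray(centers, dtype=float),
        "radii": np.asarray(radii, dtype=float),
        "resranges": np.asarray(resranges),
    }


class TestCrosslinkScore:
    def state_with_copies(self, d_copy0, d_copy1):
        return AssemblyState.from_chains([
            chain("A", [[0, 0, 0]], [3], [[1, 10]]),
            chain("B", [[d_copy0, 0, 0]], [3], [[1, 10]], copy_index=0),
            chain("B", [[d_copy1, 0, 0]], [3], [[1, 10]], copy_index=1),
        ])

    def test_within_cutoff_is_free(self):
        st = self.state_with_copies(10.0, 10.0)
        total, details = score_crosslinks(st, [CrosslinkRecord("A", 5, "B", 5)],
                                          cutoff=35.0, k=1.0)
        assert total == 0.0
        assert details[0]["satisfied"]

    def test_harmonic_beyond_cutoff(self):
        st = self.state_with_copies(45.0, 45.0)
        total, _ = score_crosslinks(st, [CrosslinkRecord("A", 5, "B", 5)],
                                    cutoff=35.0, k=1.0)
        assert total == pytest.approx(50.0)  # 0.5 * 1 * 10^2

    def test_ambiguity_takes_minimum_over_copies(self):
        st = self.state_with_copies(50.0, 20.0)
        total, details = score_crosslinks(st, [CrosslinkRecord("A", 5, "B", 5)],
                                          cutoff=35.0)
        assert total == 0.0
        assert details[0]["distance"] == pytest.approx(20.0)

    def test_adding_a_copy_never_raises_penalty(self):
        rec = CrosslinkRecord("A", 5, "B", 5)
        one_copy = AssemblyState.from_chains([
            chain("A", [[0, 0, 0]], [3], [[1, 10]]),
            chain("B", [[60.0, 0, 0]], [3], [[1, 10]]),
        ])
        p1, _ = score_crosslinks(one_copy, [rec])
        for extra in (10.0, 45.0, 200.0):
            st = self.state_with_copies(60.0, extra)
            p2, _ = score_crosslinks(st, [rec])
            assert p2 <= p1 + 1e-12

    def test_scaffold_contacts_may_cross_the_symmetry_interface(self):
        # fixed scaffold bead at azimuth +20 deg; mobile bead at -25 deg:
        # 45 deg apart within the unit, but adjacent to the scaffold bead's
        # C8 image at -25 deg
        r = 300.0
        def on_ring(az):
            a = np.deg2rad(az)
            return [r * np.cos(a), r * np.sin(a), 0.0]

        st = AssemblyState.from_chains(
            [
                chain("Scaf", [on_ring(20.0)], [5], [[1, 10]]),
                chain("Mob", [on_ring(-24.0)], [5], [[1, 10]]),
            ],
            rigid_groups=[([0], True)],
        )
        rec = CrosslinkRecord("Scaf", 5, "Mob", 5)
        in_unit, _ = score_crosslinks(st, [rec], cutoff=35.0)
        with_images, details = score_crosslinks(st, [rec], cutoff=35.0, n_symmetry=8)
        assert in_unit > 0.0
        assert with_images == 0.0  # image at 20 - 45 = -25 deg is 5 deg away
        assert details[0]["satisfied"]

    def test_unmappable_record_names_it(self, toy_state):
        with pytest.raises(RestraintSetupError, match="Missing"):
            score_crosslinks(toy_state, [CrosslinkRecord("Missing", 1, "A", 1)])


class TestFineLevelMapping:
    def test_crosslinks_map_to_fine_beads_of_rigid_segments(self):
        from npcbasket.representation import Segment, SubunitSpec, build_representation
        from npcbasket.restraints import crosslink_candidates

        rng = np.random.default_rng(0)
        coords = np.cumsum(rng.normal(scale=1.5, size=(40, 3)), axis=0)
        spec = SubunitSpec(
            "R", 40,
            segments=[Segment(1, 20, "rigid"), Segment(21, 40, "disordered")],
            source_model=coords,
        )
        st = build_representation([spec])
        rec = CrosslinkRecord("R", 7, "R", 35)
        (pair,) = crosslink_candidates(st, rec)
        ch = st.chains[0]
        # residue 7 sits in the rigid segment: finest (1-residue) bead
        assert pair[0] in ch.fine
        assert st.resrange[pair[0]].tolist() == [7, 7]
        # residue 35 is flexible: coarse 10-residue bead
        assert pair[1] in ch.coarse
        assert st.resrange[pair[1]].tolist() == [31, 40]


class TestGmmGridFit:
    def test_em_fit_recovers_a_rasterized_mixture(self):
        from npcbasket.gmm import fit_gmm_to_grid

        truth = GaussianMixture(
            [1.0, 1.5, 0.8],
            [[-30.0, 0, 0], [25.0, 10, 0], [0.0, -20, 15]],
            [8.0, 10.0, 9.0],
        )
        voxel, origin = 4.0, np.array([-60.0, -60.0, -60.0])
        axes = [origin[d] + (np.arange(30) + 0.5) * voxel for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        grid = truth.density(pts).reshape(30, 30, 30)
        fit = fit_gmm_to_grid(grid, origin, voxel, n_components=3, seed=0)
        assert cross_correlation(fit, truth) > 0.95
        refit = fit_gmm_to_grid(grid, origin, voxel, n_components=3, seed=0)
        np.testing.assert_allclose(refit.means, fit.means)


class TestDensityScore:
    def test_identical_mixtures_correlate_perfectly(self):
        g = GaussianMixture([1.0, 2.0], [[0, 0, 0], [10, 0, 0]], [4.0, 6.0])
        assert abs(cross_correlation(g, g) - 1.0) < 1e-9

    def test_two_gaussians_20A_apart_analytic_value(self):
        a = GaussianMixture([1.0], [[0, 0, 0]], [10.0])
        b = GaussianMixture([1.0], [[20.0, 0, 0]], [10.0])
        cc, pen = score_em(a, b, weight=2.0)
        assert cc == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert pen == pytest.approx(2.0 * (1 - np.exp(-1.0)))

    def test_analytic_overlap_matches_numeric_integration(self):
        # independent oracle: brute-force 3-D Riemann sum of f*g
        a = GaussianMixture([1.0], [[0, 0, 0]], [10.0])
        b = GaussianMixture([1.0], [[20.0, 0, 0]], [10.0])
        h = 2.0
        axis = np.arange(-60.0, 80.0, h)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        fa, fb = a.density(pts), b.density(pts)
        num = (fa * fb).sum() * h**3
        den = np.sqrt((fa * fa).sum() * (fb * fb).sum()) * h**3
        assert cross_correlation(a, b) == pytest.approx(num / den, rel=1e-6)

    def test_symmetry_and_weight_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = GaussianMixture(rng.uniform(0.5, 2, 4), rng.normal(scale=15, size=(4, 3)),
                            rng.uniform(3, 8, 4))
        b = GaussianMixture(rng.uniform(0.5, 2, 5), rng.normal(scale=15, size=(5, 3)),
                            rng.uniform(3, 8, 5))
        cc = cross_correlation(a, b)
        assert cc == pytest.approx(cross_correlation(b, a), abs=1e-12)
        b7 = GaussianMixture(7.0 * b.weights, b.means, b.sigmas)
        assert cc == pytest.approx(cross_correlation(a, b7), abs=1e-12)
        assert 0.0 <= cc <= 1.0

    def test_model_to_gmm_component_per_bead(self, yeast_truth):
        g = model_to_gmm(yeast_truth, sigma_scale=1.0)
        assert len(g) == len(yeast_truth.coarse_idx)

    def test_broader_model_sigma_lowers_cc_against_sharp_map(self, yeast_truth):
        sharp = model_to_gmm(yeast_truth, sigma_scale=0.5)
        cc1 = cross_correlation(model_to_gmm(yeast_truth, 1.0), sharp)
        cc2 = cross_correlation(model_to_gmm(yeast_truth, 2.0), sharp)
        assert cc2 < cc1


class TestPositionalScore:
    def state_at(self, xyz):
        return AssemblyState.from_chains([chain("A", [xyz], [3], [[1, 10]])])

    def test_bead_at_target_is_free(self):
        spec = PositionalSpec("terminal-localization", "A", 1, 10, (0.0, 0, 0),
                              tolerance=10.0)
        total, _ = score_positional(self.state_at([0, 0, 0]), [spec])
        assert total == 0.0

    def test_harmonic_beyond_tolerance(self):
        spec = PositionalSpec("terminal-localization", "A", 1, 10, (0.0, 0, 0),
                              tolerance=10.0)
        total, _ = score_positional(self.state_at([12.0, 0, 0]), [spec], k=1.0)
        assert total == pytest.approx(2.0)  # 0.5 * 2^2

    def test_bead_inside_slab_is_free(self):
        spec = PositionalSpec("membrane-slab", "A", 1, 10, (-50.0, 50.0))
        total, _ = score_positional(self.state_at([500.0, 0, 20.0]), [spec])
        assert total == 0.0

    def test_slab_excursion_penalized(self):
        spec = PositionalSpec("membrane-slab", "A", 1, 10, (-50.0, 50.0))
        total, _ = score_positional(self.state_at([0.0, 0, 53.0]), [spec], k=1.0)
        assert total == pytest.approx(4.5)


class TestProximityScore:
    def two_domains(self, gap):
        return AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [10, 0, 0]], [3, 3], [[1, 10], [11, 20]]),
            chain("B", [[10.0 + gap, 0, 0]], [3], [[1, 10]]),
        ])

    def test_touching_domains_free(self):
        st = self.two_domains(gap=5.0)
        total, _ = score_proximity(st, [ProximityPair(("A", 1, 20), ("B", 1, 10), 10.0)])
        assert total == 0.0

    def test_harmonic_on_min_interset_distance(self):
        st = self.two_domains(gap=14.0)
        total, _ = score_proximity(st, [ProximityPair(("A", 1, 20), ("B", 1, 10), 10.0)],
                                   k=1.0)
        assert total == pytest.approx(8.0)  # min distance = bound + 4

    def test_argument_order_irrelevant(self):
        st = self.two_domains(gap=20.0)
        t1, _ = score_proximity(st, [ProximityPair(("A", 1, 20), ("B", 1, 10), 10.0)])
        t2, _ = score_proximity(st, [ProximityPair(("B", 1, 10), ("A", 1, 20), 10.0)])
        assert t1 == pytest.approx(t2)

    def test_empty_domain_errors(self, toy_state):
        with pytest.raises(RestraintSetupError):
            score_proximity(toy_state, [ProximityPair(("A", 100, 200), ("B", 1, 10), 5.0)])


class TestConnectivityScore:
    def test_contact_distance_chain_is_free(self):
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [10, 0, 0], [20, 0, 0]], [5, 5, 5],
                  [[1, 10], [11, 20], [21, 30]]),
        ])
        assert score_connectivity(st, c=1.2) == 0.0

    def test_gap_penalized_harmonically(self):
        # threshold 1.2*(5+5)=12; gap of threshold+3 -> 0.5*9 = 4.5
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [15.0, 0, 0]], [5, 5], [[1, 10], [11, 20]]),
        ])
        assert score_connectivity(st, c=1.2, k=1.0) == pytest.approx(4.5)

    def test_no_interchain_term(self):
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0]], [5], [[1, 10]]),
            chain("B", [[500.0, 0, 0]], [5], [[1, 10]]),
        ])
        assert score_connectivity(st) == 0.0


class TestExcludedVolume:
    def test_separated_beads_free(self, toy_state):
        assert score_excluded_volume(toy_state) == 0.0

    def test_overlap_penalized(self):
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0]], [10], [[1, 10]]),
            chain("B", [[15.0, 0, 0]], [10], [[1, 10]]),
        ])
        assert score_excluded_volume(st, k=1.0) == pytest.approx(12.5)  # 0.5*5^2

    def test_same_rigid_body_overlap_excluded(self):
        st = AssemblyState.from_chains(
            [
                chain("A", [[0, 0, 0]], [10], [[1, 10]]),
                chain("B", [[15.0, 0, 0]], [10], [[1, 10]]),
            ],
            rigid_groups=[([0, 1], False)],
        )
        assert score_excluded_volume(st) == 0.0

    def test_consecutive_chain_beads_excluded(self):
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [5.0, 0, 0]], [10, 10], [[1, 10], [11, 20]]),
        ])
        assert score_excluded_volume(st) == 0.0

    def test_symmetry_images_detect_interface_clash(self):
        # bead on the wedge boundary overlaps its C8 neighbor image
        r = 50.0
        st = AssemblyState.from_chains([
            chain("A", [[r * np.cos(np.pi / 8), r * np.sin(np.pi / 8), 0]],
                  [30.0], [[1, 10]]),
        ])
        assert score_excluded_volume(st) == 0.0
        assert score_excluded_volume(st, include_symmetry_images=True,
                                     n_symmetry=8) > 0.0


class TestEquivalenceScore:
    def pair_state(self, d):
        return AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [d, 0, 0]], [3, 3], [[1, 10], [11, 20]]),
        ])

    def alignment(self):
        return [(("A", 0, 5), ("A", 0, 5)), (("A", 0, 15), ("A", 0, 15))]

    def test_identical_states_score_zero(self):
        st = self.pair_state(20.0)
        assert score_equivalence(st, st, self.alignment()) == 0.0

    def test_distance_difference_penalized(self):
        a, b = self.pair_state(20.0), self.pair_state(23.0)
        assert score_equivalence(a, b, self.alignment(), k=1.0) == pytest.approx(4.5)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        a, b = self.pair_state(20.0), self.pair_state(26.0)
        base = score_equivalence(a, b, self.alignment())
        from npcbasket.assembly import random_rotation_matrix

        moved = a.transformed(random_rotation_matrix(rng), rng.normal(size=3) * 50)
        assert score_equivalence(moved, b, self.alignment()) == pytest.approx(base)

    def test_empty_alignment_warns_and_returns_zero(self):
        st = self.pair_state(20.0)
        with pytest.warns(UserWarning):
            assert score_equivalence(st, st, []) == 0.0


class TestTotalScore:
    def test_truth_on_noiseless_bundle_all_data_terms_zero(self, yeast_bundle):
        rb = RestraintBundle(
            crosslinks=yeast_bundle.crosslinks,
            map_gmm=yeast_bundle.density,
            positional=yeast_bundle.terminal_localizations,
        )
        total, breakdown, info = total_score(yeast_bundle.truth_state, rb)
        assert total == pytest.approx(0.0, abs=1e-9)
        assert info["em_cc"] == pytest.approx(1.0, abs=1e-9)

    def test_breakdown_sums_to_total(self, yeast_bundle, toy_state):
        rb = RestraintBundle(crosslinks=[CrosslinkRecord("A", 5, "B", 5)])
        st = toy_state
        total, breakdown, _ = total_score(st, rb)
        assert total == pytest.approx(sum(breakdown.values()), abs=1e-9)

    def test_zero_weight_removes_term(self, toy_state):
        rb = RestraintBundle(crosslinks=[CrosslinkRecord("A", 5, "B", 5)])
        w = RestraintWeights(crosslink=0.0)
        _, breakdown, _ = total_score(toy_state, rb, w)
        assert breakdown["crosslink"] == 0.0

    def test_hand_built_toy_matches_hand_sum(self):
        # two beads 45 apart, radii 3: one crosslink (cutoff 35, k=1) -> 50;
        # connectivity threshold 1.2*6=7.2 -> 0.5*(45-7.2)^2 = 714.42
        st = AssemblyState.from_chains([
            chain("A", [[0, 0, 0], [45.0, 0, 0]], [3, 3], [[1, 10], [11, 20]]),
        ])
        rb = RestraintBundle(crosslinks=[CrosslinkRecord("A", 5, "A", 15)])
        total, breakdown, _ = total_score(st, rb)
        assert breakdown["crosslink"] == pytest.approx(50.0)
        assert breakdown["connectivity"] == pytest.approx(0.5 * (45 - 7.2) ** 2)
        assert total == pytest.approx(50.0 + 0.5 * (45 - 7.2) ** 2)


class TestCompiledScorer:
    def test_matches_reference_on_random_states(self, yeast_bundle):
        rb = RestraintBundle(
            crosslinks=yeast_bundle.crosslinks,
            map_gmm=yeast_bundle.density,
            positional=(list(yeast_bundle.terminal_localizations)
                        + list(yeast_bundle.membrane_anchors)),
        )
        template = yeast_bundle.truth_state
        scorer = ScoringFunction(template, rb)
        rng = np.random.default_rng(8)
        for scale in (0.0, 5.0, 50.0, 400.0):
            st = template.copy()
            st.coords = template.coords + rng.normal(scale=scale,
                                                     size=template.coords.shape)
            ref_total, ref_terms, ref_info = total_score(st, rb)
            fast_total, fast_terms, fast_info = scorer.breakdown(st.coords)
            assert fast_total == pytest.approx(ref_total, rel=1e-9, abs=1e-9)
            for key, val in ref_terms.items():
                assert fast_terms[key] == pytest.approx(val, rel=1e-9, abs=1e-9)

    def test_all_penalties_nonnegative(self, yeast_bundle):
        rb = RestraintBundle(crosslinks=yeast_bundle.crosslinks,
                             map_gmm=yeast_bundle.density)
        scorer = ScoringFunction(yeast_bundle.truth_state, rb)
        rng = np.random.default_rng(1)
        st = yeast_bundle.truth_state.copy()
        st.coords = st.coords + rng.normal(scale=80, size=st.coords.shape)
        _, terms, _ = scorer.breakdown(st.coords)
        assert all(v >= 0 for v in terms.values())
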