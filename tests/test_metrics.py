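"""Series-level metrics: event segmentation, residence times, distributions,
g(r) and hydrogen bonds, checked against run-length/enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosar.geometry import CylinderModel
from nanosar.metrics import (
    BindingEvent,
    ContactSeries,
    DistanceDistribution,
    auc_below,
    bound_fraction,
    class_auc_sum,
    count_hbonds,
    polar_distance_distribution,
    radial_distribution,
    residence_time,
    segment_binding_events,
    stacking_distance,
)
from nanosar.trajectory import AnalyteMolecule, PolarGroup, TrajectoryBundle


def series_from_trace(trace: str, target="conjugate", dt=1.0) -> ContactSeries:
    """Boolean trace -> contact series with areas 40 (bound) / 0 (unbound)."""
    areas = np.array([40.0 if c == "1" else 0.0 for c in trace])[:, None]
    return ContactSeries(areas=areas, target=target, dt=dt)


def bare_bundle(coords, analytes=(), swcnt=(), dna=(), box=(50.0, 50.0, 50.0), dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    return TrajectoryBundle(
        coords=coords,
        elements=np.array(["C"] * n),
        swcnt=np.asarray(swcnt, dtype=np.int64),
        dna=np.asarray(dna, dtype=np.int64),
        analytes=list(analytes),
        box=np.asarray(box, dtype=float),
        dt=dt,
    )


ZCYL = CylinderModel(np.zeros(3), np.array([0.0, 0.0, 1.0]), 4.5)


class TestBoundFraction:
    def test_all_and_none(self):
        per, pooled = bound_fraction(series_from_trace("1111"))
        assert pooled == 100.0 and per[0] == 100.0
        per, pooled = bound_fraction(series_from_trace("0000"))
        assert pooled == 0.0

    def test_threshold_is_strict(self):
        s = ContactSeries(areas=np.array([[1.0], [1.01]]), target="swcnt", dt=1.0)
        per, pooled = bound_fraction(s, threshold=1.0)
        assert pooled == 50.0


class TestSegmentation:
    def test_run_lengths(self):
        events = segment_binding_events(series_from_trace("000111100110"))
        assert sorted(e.duration for e in events) == [2.0, 4.0]
        starts = sorted(e.start_frame for e in events)
        assert starts == [3, 9]

    def test_all_bound_single_event(self):
        events = segment_binding_events(series_from_trace("1111111"))
        assert len(events) == 1 and events[0].duration == 7.0

    def test_amine_criterion_splits_event(self):
        s = series_from_trace("1111111111")
        amine = np.full((10, 1), 5.0)
        amine[4:6, 0] = 12.0  # two interior frames beyond 10.5 A
        events = segment_binding_events(s, amine_distance=amine)
        assert sorted(e.duration for e in events) == [4.0, 4.0]

    def test_nan_amine_column_not_applied(self):
        s = series_from_trace("111111")
        amine = np.full((6, 1), np.nan)  # molecule without amine groups
        events = segment_binding_events(s, amine_distance=amine)
        assert len(events) == 1 and events[0].duration == 6.0

    def test_misaligned_series_rejected(self):
        s = series_from_trace("111")
        with pytest.raises(ValueError, match="misaligned"):
            segment_binding_events(s, amine_distance=np.zeros((5, 1)))

    def test_gap_tolerance_bridges_short_gaps(self):
        s = series_from_trace("1110111")
        assert len(segment_binding_events(s)) == 2
        assert len(segment_binding_events(s, gap_tolerance=1)) == 1

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 5000), n=st.integers(1, 60))
    def test_total_bound_time_identity(self, seed, n):
        """Sum of event durations equals dt * number of bound frames."""
        rng = np.random.default_rng(seed)
        trace = "".join(rng.choice(["0", "1"], size=n))
        s = series_from_trace(trace, dt=0.5)
        events = segment_binding_events(s)
        assert sum(e.duration for e in events) == pytest.approx(
            0.5 * trace.count("1")
        )
        if events:
            res = residence_time(events)
            assert res.tau_R == pytest.approx(
                0.5 * trace.count("1") / res.n_events
            )


class TestResidenceTime:
    def test_single_event(self):
        e = [BindingEvent(0, "swcnt", 0, 9, 10.0)]
        assert residence_time(e).tau_R == 10.0

    def test_pooled_mean(self):
        events = [
            BindingEvent(0, "swcnt", 0, 1, 2.0),
            BindingEvent(1, "swcnt", 4, 5, 2.0),
            BindingEvent(2, "swcnt", 0, 5, 6.0),
        ]
        res = residence_time(events)
        assert res.tau_R == pytest.approx(10.0 / 3.0)
        assert res.n_events == 3

    def test_never_bound_distinct_error(self):
        with pytest.raises(ValueError, match="never bound"):
            residence_time([])

    def test_exponential_dwell_recovery(self):
        """Mean of >= 1e3 exponential dwells with mean 25 recovered within 10%."""
        rng = np.random.default_rng(1)
        durations = np.ceil(rng.exponential(25.0, size=2000))
        events = [
            BindingEvent(0, "swcnt", 0, int(d) - 1, float(d)) for d in durations
        ]
        res = residence_time(events)
        assert res.tau_R == pytest.approx(25.0, rel=0.10)


class TestStacking:
    def _bundle_with_aryl_at(self, dists):
        """One single-atom 'ring' at the given surface distances per frame."""
        coords = np.array([[[4.5 + d, 0.0, 0.0]] for d in dists])
        mol = AnalyteMolecule(indices=[0], aryl_ring=[0])
        return bare_bundle(coords, analytes=[mol])

    def test_constant_distance(self):
        b = self._bundle_with_aryl_at([3.5, 3.5, 3.5])
        per, pooled = stacking_distance(b, ZCYL)
        assert pooled == pytest.approx(3.5)

    def test_conditional_mean_excludes_beyond_cutoff(self):
        b = self._bundle_with_aryl_at([3.0, 5.0, 12.0])
        per, pooled = stacking_distance(b, ZCYL, cutoff=10.0)
        assert pooled == pytest.approx(4.0)

    def test_never_within_cutoff_is_nan(self):
        b = self._bundle_with_aryl_at([15.0, 20.0])
        per, pooled = stacking_distance(b, ZCYL)
        assert np.isnan(pooled) and np.isnan(per[0])


class TestDistanceDistribution:
    def _bundle_with_group_at(self, dists, group_class="hydroxy"):
        coords = np.array([[[4.5 + d, 0.0, 0.0]] for d in dists])
        mol = AnalyteMolecule(
            indices=[0],
            aryl_ring=[0],
            polar_groups=[PolarGroup("G", [0], group_class)],
        )
        return bare_bundle(coords, analytes=[mol])

    def test_single_occupied_bin_integrates_to_one(self):
        b = self._bundle_with_group_at([3.0, 3.0, 3.0])
        dist = polar_distance_distribution(b, "hydroxy", ZCYL)
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0, abs=1e-6)
        assert np.count_nonzero(dist.density) == 1

    def test_uniform_samples_give_flat_density(self):
        d = np.linspace(0.005, 9.995, 2000)
        dist = polar_distance_distribution(self._bundle_with_group_at(d), "hydroxy", ZCYL)
        np.testing.assert_allclose(dist.density, 0.1, atol=1e-9)

    def test_closed_upper_bound_and_exclusions(self):
        dist = polar_distance_distribution(
            self._bundle_with_group_at([10.0, 10.4, 5.0]), "hydroxy", ZCYL
        )
        assert dist.n_samples == 2  # 10.0 included, 10.4 excluded

    def test_no_qualifying_sample_flagged_empty(self):
        dist = polar_distance_distribution(
            self._bundle_with_group_at([20.0]), "hydroxy", ZCYL
        )
        assert dist.empty and np.all(dist.density == 0)

    def test_gaussian_mixture_ks_consistent(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        comp = rng.random(4000) < 0.6
        d = np.where(
            comp,
            rng.normal(3.4, 0.2, 4000),
            rng.normal(6.5, 0.4, 4000),
        )
        d = d[(d >= 0) & (d <= 10)]
        dist = polar_distance_distribution(self._bundle_with_group_at(d), "hydroxy", ZCYL)
        # draw from the histogram and KS-compare against the raw samples
        widths = np.diff(dist.bin_edges)
        probs = dist.density * widths
        resampled = rng.choice(
            dist.bin_edges[:-1] + widths / 2, size=2000, p=probs / probs.sum()
        ) + rng.uniform(-0.05, 0.05, 2000)
        ks = stats.ks_2samp(resampled, d)
        assert ks.pvalue > 0.01


class TestAuc:
    def _uniform(self):
        edges = np.arange(0.0, 10.05, 0.1)
        return DistanceDistribution(edges, np.full(100, 0.1), n_samples=1000)

    def test_uniform_auc(self):
        assert auc_below(self._uniform(), 4.0) == pytest.approx(0.4, abs=1e-12)

    def test_entirely_below_threshold(self):
        edges = np.arange(0.0, 10.05, 0.1)
        density = np.zeros(100)
        density[:20] = 0.5  # all mass below 2 A
        dist = DistanceDistribution(edges, density, n_samples=10)
        assert auc_below(dist, 4.0) == pytest.approx(1.0)

    def test_partial_bin(self):
        assert auc_below(self._uniform(), 4.05) == pytest.approx(0.405, abs=1e-12)

    def test_monotone_in_x(self):
        dist = self._uniform()
        vals = [auc_below(dist, x) for x in np.linspace(0, 10, 41)]
        assert np.all(np.diff(vals) >= 0)

    def test_out_of_support(self):
        with pytest.raises(ValueError, match="support"):
            auc_below(self._uniform(), 12.0)

    def test_class_sum_for_two_hydroxy_groups(self):
        edges = np.arange(0.0, 10.05, 0.1)
        density = np.zeros(100)
        density[:40] = 0.3 / 4.0 / 0.1 * 0.1  # AUC below 4 = 0.3
        density[40:] = (1 - 0.3) / 6.0
        d = DistanceDistribution(edges, density, n_samples=50)
        assert auc_below(d, 4.0) == pytest.approx(0.3)
        assert class_auc_sum([d, d], 4.0) == pytest.approx(0.6)


class TestGofR:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(2)
        box = 20.0
        coords = rng.uniform(0, box, size=(40, 300, 3))
        b = bare_bundle(coords, dna=np.arange(300), box=(box, box, box))
        g = radial_distribution(b, np.arange(150), np.arange(150, 300), r_max=8.0,
                                bin_width=0.25)
        assert np.abs(g.g[g.r_grid > 1.0].mean() - 1.0) < 0.05
        assert np.all(g.g >= 0)

    def test_hard_exclusion_zero_below_cutoff(self):
        # simple cubic lattice, spacing 4 A: no pair closer than 4
        ax = np.arange(0, 20, 4.0)
        pts = np.array([[x, y, z] for x in ax for y in ax for z in ax])
        b = bare_bundle(pts[None], dna=np.arange(len(pts)), box=(20, 20, 20))
        g = radial_distribution(b, np.arange(len(pts)), np.arange(len(pts)), r_max=9.0)
        assert np.all(g.g[g.r_grid < 3.9] == 0)
        # nearest-neighbor distance 4.0 falls in the [4.0, 4.1) bin
        assert g.g[(g.r_grid > 3.95) & (g.r_grid < 4.15)].sum() > 0

    def test_single_pair_single_bin(self):
        coords = np.array([[[1.0, 1, 1], [1.0, 1, 4.25]]])
        b = bare_bundle(coords, dna=[0, 1], box=(30, 30, 30))
        g = radial_distribution(b, [0], [1], r_max=10.0)
        assert np.count_nonzero(g.g) == 1
        assert g.r_grid[np.nonzero(g.g)[0][0]] == pytest.approx(3.25)

    def test_r_max_vs_box_guard(self):
        b = bare_bundle(np.zeros((1, 2, 3)), dna=[0, 1], box=(10, 10, 10))
        with pytest.raises(ValueError, match="half"):
            radial_distribution(b, [0], [1], r_max=6.0)


class TestHbonds:
    def _frame(self, atoms):
        return bare_bundle(np.asarray(atoms, dtype=float)[None])

    def test_ideal_linear_bond_counted(self):
        # O-H...O, D...A = 2.8 A, perfectly linear
        b = self._frame([[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0]])
        counts = count_hbonds(b, donors=[(0, 1)], acceptors=[2])
        assert counts[0] == 1

    def test_distance_cutoff(self):
        b = self._frame([[0, 0, 0], [0.96, 0, 0], [4.5, 0, 0]])
        assert count_hbonds(b, [(0, 1)], [2], d_cut=3.5)[0] == 0

    def test_angle_cutoff(self):
        # acceptor at 90 degrees off the O-H axis, within distance
        b = self._frame([[0, 0, 0], [0.96, 0, 0], [0, 2.5, 0]])
        assert count_hbonds(b, [(0, 1)], [2], d_cut=3.5, angle_cut=30)[0] == 0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        atoms = rng.uniform(0, 6, size=(12, 3))
        donors = [(0, 1), (2, 3), (4, 5)]
        acceptors = [6, 7]
        b = self._frame(atoms)
        got = count_hbonds(b, donors, acceptors, d_cut=3.5, angle_cut=30)[0]
        expected = 0
        for d, h in donors:
            for a in acceptors:
                if np.linalg.norm(atoms[a] - atoms[d]) > 3.5:
                    continue
                v1 = atoms[d] - atoms[h]
                v2 = atoms[a] - atoms[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                dha = np.arccos(np.clip(cosang, -1, 1))
                if np.rad2deg(dha) >= 150:
                    expected += 1
        assert got == expected

    def test_missing_hydrogen_rejected(self):
        b = self._frame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="hydrogen"):
            count_hbonds(b, donors=[(0,)], acceptors=[2])
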