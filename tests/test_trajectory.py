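"""End-to-end trajectory pipeline: ground-truth round trips and estimator
recovery on simulated binding kinetics."""

import numpy as np
import pytest

from nanosar import metrics as M
from nanosar.synthetic import KineticParams, build_world, simulate_trajectory
from nanosar.trajectory import TrajectoryBundle, load_trajectory, write_trajectory


@pytest.fixture(scope="module")
def conj_series(two_state_traj):
    bundle, truth, kin = two_state_traj
    return M.contact_series(bundle, "conjugate")


class TestContactSeriesRoundTrip:
    def test_crosses_threshold_only_in_bound_intervals(self, two_state_traj, conj_series):
        bundle, truth, kin = two_state_traj
        bound_state = truth.states.index("stack_swcnt")
        truth_bound = (truth.state_sequence == bound_state).T
        np.testing.assert_array_equal(conj_series.areas > 30.0, truth_bound)

    def test_far_molecules_have_zero_contact(self, two_state_traj, conj_series):
        bundle, truth, kin = two_state_traj
        free = (truth.state_sequence == truth.states.index("free")).T
        assert np.all(conj_series.areas[free] == 0.0)

    def test_single_frame_series_equals_direct_call(self, two_state_traj):
        bundle, truth, kin = two_state_traj
        sub = TrajectoryBundle(
            coords=bundle.coords[:1],
            elements=bundle.elements,
            swcnt=bundle.swcnt,
            dna=bundle.dna,
            analytes=bundle.analytes,
            box=bundle.box,
            dt=bundle.dt,
        )
        series = M.contact_series(sub, "conjugate")
        for m in range(3):
            direct = M.contact_area(
                sub, sub.analytes[m].indices, sub.conjugate, frame=0
            )
            assert series.areas[0, m] == pytest.approx(direct, abs=1e-9)


class TestKineticRecovery:
    def test_bound_fraction_recovers_stationary_occupancy(
        self, two_state_traj, conj_series
    ):
        bundle, truth, kin = two_state_traj
        _, pooled = M.bound_fraction(conj_series)
        events = M.segment_binding_events(conj_series)
        p = truth.bound_fraction_true() / 100.0
        se = 100.0 * np.sqrt(p * (1 - p) / len(events))
        assert pooled == pytest.approx(truth.bound_fraction_true(), abs=3 * se)

    def test_residence_time_recovers_mean_dwell(self, two_state_traj, conj_series):
        bundle, truth, kin = two_state_traj
        amine = M.amine_distance_series(bundle, M.swcnt_cylinder(bundle))
        events = M.segment_binding_events(conj_series, amine_distance=amine)
        res = M.residence_time(events)
        true_tau = truth.residence_true_ns()
        se = true_tau / np.sqrt(res.n_events)
        assert res.tau_R == pytest.approx(true_tau, abs=3 * se)

    def test_amine_criterion_inactive_when_group_is_close(
        self, two_state_traj, conj_series
    ):
        """The simulated analyte keeps its ammonium within 10.5 A while bound,
        so the amine gate leaves the segmentation unchanged."""
        bundle, truth, kin = two_state_traj
        amine = M.amine_distance_series(bundle, M.swcnt_cylinder(bundle))
        with_gate = M.segment_binding_events(conj_series, amine_distance=amine)
        without = M.segment_binding_events(conj_series)
        assert len(with_gate) == len(without)

    @pytest.mark.parametrize("k_on,k_off", [(0.02, 0.04), (0.08, 0.04), (0.04, 0.08)])
    def test_rate_grid_recovery(self, world, k_on, k_off):
        """Across (k_on, k_off) combinations the pipeline recovers the
        stationary occupancy and 1/k_off from the contact series."""
        kin = KineticParams.two_state(k_on, k_off, dt=1.0, n_frames=700, seed=31)
        bundle, truth = simulate_trajectory(world, kin)
        series = M.contact_series(bundle, "conjugate", n_sphere_points=128)
        events = M.segment_binding_events(series)
        res = M.residence_time(events)
        p_true = k_on / (k_on + k_off)
        se_p = np.sqrt(p_true * (1 - p_true) / res.n_events)
        _, pooled = M.bound_fraction(series)
        assert pooled / 100.0 == pytest.approx(p_true, abs=3 * se_p)
        tau_true = 1.0 / k_off
        se_tau = tau_true / np.sqrt(res.n_events)
        assert res.tau_R == pytest.approx(tau_true, abs=3 * se_tau)

    def test_frame_stride_consistency(self, two_state_traj):
        bundle, truth, kin = two_state_traj
        strided = bundle.with_stride(2)
        assert strided.dt == 2 * bundle.dt
        s1 = M.contact_series(bundle, "conjugate", n_sphere_points=128)
        s2 = M.contact_series(strided, "conjugate", n_sphere_points=128)
        _, bf1 = M.bound_fraction(s1)
        _, bf2 = M.bound_fraction(s2)
        assert bf2 == pytest.approx(bf1, abs=5.0)
        # event durations quantize to multiples of the strided dt
        for e in M.segment_binding_events(s2):
            assert e.duration % strided.dt == pytest.approx(0.0)


class TestStackingRecovery:
    def test_stacking_offset_recovered(self, two_state_traj):
        bundle, truth, kin = two_state_traj
        cyl = M.swcnt_cylinder(bundle)
        per, pooled = M.stacking_distance(bundle, cyl)
        n_stack = (truth.state_sequence != truth.states.index("free")).sum()
        se = truth.stacking_offset_sd / np.sqrt(n_stack)
        assert pooled == pytest.approx(truth.stacking_offset_mean, abs=max(3 * se, 0.02))

    def test_polar_distribution_integrates_to_one(self, two_state_traj):
        bundle, truth, kin = two_state_traj
        cyl = M.swcnt_cylinder(bundle)
        dist = M.polar_distance_distribution(bundle, "hydroxy", cyl)
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0, abs=1e-6)
        assert dist.n_samples > 0


class TestBindingModes:
    def test_pure_swcnt_stacking(self, two_state_traj):
        bundle, truth, kin = two_state_traj
        cyl = M.swcnt_cylinder(bundle)
        sc = M.contact_series(bundle.with_stride(10), "swcnt", n_sphere_points=128)
        dc = M.contact_series(bundle.with_stride(10), "dna", n_sphere_points=128)
        strided = bundle.with_stride(10)
        for m in range(3):
            mode = M.classify_binding_mode(
                strided, m, cyl, swcnt_series=sc, dna_series=dc
            )
            assert mode == "stack_swcnt"

    def test_alternating_dna_swcnt_is_both(self, three_state_traj):
        bundle, truth, kin = three_state_traj
        cyl = M.swcnt_cylinder(bundle)
        sc = M.contact_series(bundle, "swcnt", n_sphere_points=128)
        dc = M.contact_series(bundle, "dna", n_sphere_points=128)
        seq = truth.state_sequence
        i_dna = truth.states.index("stack_dna")
        i_sw = truth.states.index("stack_swcnt")
        for m in range(6):
            n_dna = (seq[m] == i_dna).sum()
            n_sw = (seq[m] == i_sw).sum()
            n_bound = n_dna + n_sw
            if n_bound == 0:
                continue
            mode = M.classify_binding_mode(
                bundle, m, cyl, swcnt_series=sc, dna_series=dc
            )
            if n_dna / n_bound > 0.5:
                assert mode == "stack_dna"
            elif n_sw / n_bound > 0.5:
                assert mode == "stack_swcnt"
            else:
                assert mode == "both"

    def test_never_bound_is_unbound(self, world):
        kin = KineticParams.two_state(0.0, 0.05, dt=1.0, n_frames=50, seed=3)
        bundle, truth = simulate_trajectory(world, kin)
        cyl = M.swcnt_cylinder(bundle)
        sc = M.contact_series(bundle, "swcnt", n_sphere_points=128)
        dc = M.contact_series(bundle, "dna", n_sphere_points=128)
        assert (
            M.classify_binding_mode(bundle, 0, cyl, swcnt_series=sc, dna_series=dc)
            == "unbound"
        )

    def test_insertion_mode(self, world):
        kin = KineticParams(
            states=("free", "inserted"),
            rates={("free", "inserted"): 0.05, ("inserted", "free"): 0.03},
            dt=1.0,
            n_frames=300,
            seed=17,
        )
        bundle, truth = simulate_trajectory(world, kin)
        cyl = M.swcnt_cylinder(bundle)
        sc = M.contact_series(bundle, "swcnt", n_sphere_points=128)
        dc = M.contact_series(bundle, "dna", n_sphere_points=128)
        modes = [
            M.classify_binding_mode(bundle, m, cyl, swcnt_series=sc, dna_series=dc)
            for m in range(6)
        ]
        assert modes.count("insertion") >= 5


class TestIO:
    def test_pdb_dcd_json_round_trip(self, tmp_path, world):
        kin = KineticParams.two_state(0.04, 0.04, dt=0.5, n_frames=25, seed=6)
        bundle, _ = simulate_trajectory(world, kin)
        pdb, dcd, gjson = write_trajectory(bundle, tmp_path)
        loaded = load_trajectory(pdb, dcd, gjson)
        assert loaded.n_frames == bundle.n_frames
        assert loaded.dt == pytest.approx(bundle.dt)
        np.testing.assert_allclose(loaded.coords, bundle.coords, atol=1e-3)
        np.testing.assert_array_equal(loaded.swcnt, bundle.swcnt)
        assert len(loaded.analytes) == len(bundle.analytes)
        np.testing.assert_array_equal(
            loaded.analytes[2].aryl_ring, bundle.analytes[2].aryl_ring
        )
        assert set(loaded.dna_backbone) == set(bundle.dna_backbone)
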