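"""Integration accuracy, observables and flux integrals."""

import numpy as np
import pytest

from doxcycle import (
    Reaction,
    ReactionNetwork,
    ScenarioConfig,
    build_invivo_model,
    compute_observables,
    integrate,
    integrated_flux,
    total_doxorubicin,
)
from doxcycle.models import KineticModel
from doxcycle.timecourse import TimeCourseError


@pytest.fixture(scope="module")
def eu1_tc(eu1_model):
    return integrate(eu1_model, np.arange(0.0, 61.0, 10.0))


class TestIntegrate:
    def test_initial_grid_point_equals_initial_conditions(self, eu1_model,
                                                          eu1_tc):
        for s in eu1_model.species:
            assert eu1_tc[s][0] == pytest.approx(
                eu1_model.initial_state[s], rel=1e-12)

    def test_cpr_moiety_conserved_over_one_hour(self, eu1_model, eu1_tc):
        total0 = eu1_tc["CPR_red"][0] + eu1_tc["CPR_ox"][0]
        total = eu1_tc["CPR_red"][-1] + eu1_tc["CPR_ox"][-1]
        assert total == pytest.approx(total0, rel=1e-7)

    def test_total_doxorubicin_conserved(self, eu1_model, eu1_tc):
        state0 = {s: eu1_tc[s][0] for s in eu1_model.species}
        state1 = {s: eu1_tc[s][-1] for s in eu1_model.species}
        assert total_doxorubicin(eu1_model, state1) == pytest.approx(
            total_doxorubicin(eu1_model, state0), rel=1e-7)

    def test_agreement_with_fixed_step_rk4_reference(self, invitro_model):
        """Stiff solver vs a brute-force fixed-step 4th-order reference.

        The reference pairs the independently hand-coded derivative with a
        classic RK4 loop.  The fastest in vitro relaxation (semiquinone
        reoxidation, k3*[O2] ~ 8e4 s^-1) forces the explicit step below
        ~2e-5 s, so the reference uses h = 1e-5 s over the first second.
        """
        from oracles import invitro_rhs

        model = invitro_model
        net = model.network
        species = net.species
        h, t_end = 1e-5, 1.0

        def f(state):
            return invitro_rhs(state, model.parameters)

        def step(state):
            k1 = f(state)
            s2 = {s: state[s] + 0.5 * h * k1[s] for s in species}
            k2 = f(s2)
            s3 = {s: state[s] + 0.5 * h * k2[s] for s in species}
            k3 = f(s3)
            s4 = {s: state[s] + h * k3[s] for s in species}
            k4 = f(s4)
            return {s: state[s] + (h / 6.0) *
                    (k1[s] + 2 * k2[s] + 2 * k3[s] + k4[s]) for s in species}

        state = dict(model.initial_state)
        for _ in range(int(round(t_end / h))):
            state = step(state)
        tc = integrate(model, np.array([0.0, t_end / 60.0]))
        for s in species:
            if abs(state[s]) > 1e-12:  # skip species at numerical zero
                assert tc[s][-1] == pytest.approx(state[s], rel=1e-4), s

    def test_tolerance_refinement_stability(self, eu1_model):
        grid = np.arange(0.0, 61.0, 10.0)
        a = integrate(eu1_model, grid, rtol=1e-8, atol=1e-14)
        b = integrate(eu1_model, grid, rtol=5e-9, atol=5e-15)
        for s in ("In_Dox_q", "NADPH", "Ex_Dox_q"):
            np.testing.assert_allclose(a[s][1:], b[s][1:], rtol=1e-3)

    def test_non_monotone_grid_rejected(self, eu1_model):
        with pytest.raises(TimeCourseError):
            integrate(eu1_model, [0.0, 10.0, 10.0])


class TestObservables:
    def test_nadph_fraction_starts_at_one(self, eu1_model, eu1_tc):
        obs = compute_observables(eu1_model, eu1_tc)
        assert obs["nadph"][0] == pytest.approx(1.0)

    def test_superoxide_signal_is_cumulative_and_nondecreasing(
            self, eu1_model, eu1_tc):
        obs = compute_observables(eu1_model, eu1_tc)
        sig = obs["superoxide_signal"]
        assert sig[0] == 0.0
        assert np.all(np.diff(sig) >= 0.0)

    def test_max_normalized_series_peaks_at_one(self, eu1_model, eu1_tc):
        obs = compute_observables(eu1_model, eu1_tc,
                                  ("quinone_dox",), normalize=True)
        assert obs["quinone_dox"].max() == pytest.approx(1.0)

    def test_extracellular_requires_cellular_trajectory(self, invitro_model):
        tc = integrate(invitro_model, [0.0, 20.0])
        with pytest.raises(TimeCourseError):
            compute_observables(invitro_model, tc, ("extracellular_dox",))


def first_order_toy(k: float) -> KineticModel:
    """Single first-order decay X -> Y, rate k (s^-1), closed form known."""
    net = ReactionNetwork(
        ("X", "Y"),
        (Reaction("R1", "permeation", ("X",), {"X": -1, "Y": 1},
                  {"k": k, "area": 1.0}),),
    )
    scenario = ScenarioConfig(kind="invitro")
    return KineticModel(net, {"X": 1.0, "Y": 0.0}, {"k": k}, scenario)


class TestIntegratedFlux:
    def test_zero_length_window_gives_zero(self, eu1_model, eu1_tc):
        assert integrated_flux(eu1_model, eu1_tc, "R1", (10.0, 10.0)) == 0.0

    def test_window_outside_grid_rejected(self, eu1_model, eu1_tc):
        with pytest.raises(TimeCourseError):
            integrated_flux(eu1_model, eu1_tc, "R1", (0.0, 90.0))

    def test_early_semiquinone_flux_vanishes(self, eu1_model):
        # In_Dox_q(0) = 0, so the R1 integral vanishes quadratically as
        # the window shrinks to 0+
        grid = np.linspace(0.0, 0.1, 101)
        tc = integrate(eu1_model, grid)
        small = integrated_flux(eu1_model, tc, "R1", (0.0, 0.01))
        full = integrated_flux(eu1_model, tc, "R1", (0.0, 0.1))
        assert 0.0 <= small < 1e-9
        assert small < full / 50.0

    def test_rate_time_rescaling_leaves_integral_invariant(self):
        """Halving k and doubling time: closed-form check on a toy decay.

        The integral of the rate over [0, T] is 1 - exp(-kT), identical
        for (k, T) and (k/2, 2T).
        """
        grid_a = np.linspace(0.0, 2.0, 1201)   # minutes
        grid_b = np.linspace(0.0, 4.0, 2401)
        ma, mb = first_order_toy(0.05), first_order_toy(0.025)
        fa = integrated_flux(ma, integrate(ma, grid_a), "R1")
        fb = integrated_flux(mb, integrate(mb, grid_b), "R1")
        expected = 1.0 - np.exp(-0.05 * 120.0)
        assert fa == pytest.approx(expected, rel=1e-5)
        assert fa == pytest.approx(fb, rel=1e-5)


class TestCellularNarrative:
    """Directional behaviour of the cellular models (default options)."""

    def test_low_dose_quinone_ordering_eu1_below_eu3(self):
        grid = np.linspace(0.0, 60.0, 61)
        q = {}
        for cell in ("EU1-Res", "EU3-Sens"):
            m = build_invivo_model(ScenarioConfig(
                kind="invivo", cell_line=cell, dose="low"))
            q[cell] = compute_observables(m, integrate(m, grid))["quinone_dox"]
        assert q["EU1-Res"][-1] < q["EU3-Sens"][-1]

    @pytest.mark.parametrize("cell", ["EU1-Res", "EU3-Sens"])
    def test_low_dose_early_peak_then_decline_to_plateau(self, cell):
        grid = np.linspace(0.0, 60.0, 61)
        m = build_invivo_model(ScenarioConfig(
            kind="invivo", cell_line=cell, dose="low"))
        q = compute_observables(m, integrate(m, grid))["quinone_dox"]
        i_peak = int(np.argmax(q))
        assert 0 < i_peak < len(q) - 1      # interior early peak
        assert grid[i_peak] < 30.0
        assert q[-1] < 0.95 * q[i_peak]     # declines after the peak
        late = q[grid >= 40.0]
        assert np.ptp(late) < 0.2 * q[i_peak]   # settles toward a plateau
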