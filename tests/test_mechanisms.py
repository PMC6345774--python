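"""Two-state, conformational-selection and induced-fit simulators."""

import numpy as np
import pytest

from p53mdm2.mechanisms import (MechanismParams, Scheme,
                                apparent_kd_equilibrium, extract_kobs,
                                relaxation_rates, simulate)

WT = dict(kon=1.6e6, koff=9.0)


def equilibrium_kd_from_trajectory(params, t_end=2000.0):
    """Numerical oracle: run to equilibrium, form Kd from the endpoint."""
    traj = simulate(params, t_end=t_end, n_points=50)
    c = {k: v[-1] for k, v in traj.concentrations.items()}
    free_p = c.get("P", 0.0) + c.get("Pu", 0.0) + c.get("Ph", 0.0)
    complexes = c.get("C", 0.0) + c.get("Cstar", 0.0)
    return free_p * c["M"] / complexes


class TestParams:
    def test_scheme_irrelevant_rates_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams("two_state", kon=1e6, koff=1.0, kf=10.0)
        with pytest.raises(ValueError):
            MechanismParams("induced_fit", kon=1e6, koff=1.0, kf=10.0,
                            ku=1.0, kon_star=1.0, koff_star=1.0)

    def test_missing_required_rates_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams("conformational_selection", kon=1e6, koff=1.0)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            MechanismParams("two_state", kon=1e6, koff=1.0,
                            initial={"Ph": 1e-6})


class TestSimulate:
    def test_two_state_relaxation_rate(self):
        # WT rates at 2 uM MDM2: kobs = kon*[M] + koff = 12.2 /s. The
        # exact relaxation rate is kon*([M]eq+[P]eq)+koff; with a probe
        # peptide at 1/32 of [M] both agree within 1%.
        p = MechanismParams("two_state", **WT,
                            initial={"P": 0.0625e-6, "M": 2e-6})
        traj = simulate(p, t_end=0.5, n_points=1500)
        kobs, single = extract_kobs(traj)
        assert single
        assert kobs == pytest.approx(12.2, rel=0.01)

    def test_all_rates_zero_is_constant(self):
        p = MechanismParams("two_state", kon=0.0, koff=0.0,
                            initial={"P": 1e-6, "M": 2e-6})
        traj = simulate(p, t_end=1.0)
        for series in traj.concentrations.values():
            assert np.allclose(series, series[0])

    def test_mass_conservation(self):
        p = MechanismParams("induced_fit", **WT, kon_star=50.0,
                            koff_star=20.0,
                            initial={"P": 0.5e-6, "M": 2e-6})
        traj = simulate(p, t_end=1.0)
        ptot = traj.peptide_total()
        mtot = traj.mdm2_total()
        assert np.max(np.abs(ptot - ptot[0])) / ptot[0] < 1e-9
        assert np.max(np.abs(mtot - mtot[0])) / mtot[0] < 1e-9

    def test_cs_rapid_preequilibrium_rate(self):
        # kf, ku >> kon[M]: kobs ~ kon*[M]*kf/(kf+ku) + koff
        kf, ku, m = 5000.0, 5000.0, 2e-6
        p = MechanismParams("conformational_selection", **WT, kf=kf, ku=ku,
                            initial={"Pu": 0.05e-6, "M": m})
        traj = simulate(p, t_end=1.0, n_points=2000)
        kobs, single = extract_kobs(traj)
        expected = WT["kon"] * m * kf / (kf + ku) + WT["koff"]
        assert single
        assert kobs == pytest.approx(expected, rel=0.02)

    def test_cs_slow_folding_is_biphasic(self):
        # kf + ku << kon[M]: folding limits binding; relaxation of the
        # bound signal is no longer single-exponential
        p = MechanismParams("conformational_selection", **WT, kf=0.5,
                            ku=0.5, initial={"Pu": 0.05e-6, "M": 2e-6})
        traj = simulate(p, t_end=10.0, n_points=2000)
        _, single = extract_kobs(traj)
        assert not single
        rates = relaxation_rates(p, 2e-6)
        assert rates.size >= 2
        assert rates[-1] / rates[0] > 5.0

    def test_if_silent_fast_step_looks_single_exponential(self):
        # a fast bound-state isomerisation leaves the trace single-
        # exponential while shifting the equilibrium Kd off koff/kon
        p = MechanismParams("induced_fit", **WT, kon_star=2000.0,
                            koff_star=952.0,
                            initial={"P": 0.0625e-6, "M": 2e-6})
        traj = simulate(p, t_end=0.5, n_points=1500)
        _, single = extract_kobs(traj)
        assert single
        kd_app = apparent_kd_equilibrium(p)
        assert kd_app < 0.5 * (p.koff / p.kon)


class TestApparentKd:
    def test_two_state_is_rate_ratio(self):
        p = MechanismParams("two_state", **WT, initial={"P": 1e-6,
                                                        "M": 1e-6})
        assert apparent_kd_equilibrium(p) == pytest.approx(5.625e-6)

    def test_cs_equal_partition_doubles_kd(self):
        p = MechanismParams("conformational_selection", **WT, kf=100.0,
                            ku=100.0, initial={"Pu": 1e-6, "M": 1e-6})
        assert apparent_kd_equilibrium(p) == pytest.approx(2 * 5.625e-6)

    def test_if_step_reconciles_kinetic_and_itc_kd(self):
        # K* = kon*/koff* = 2.1 turns the kinetic ratio 5.6 uM into an
        # equilibrium Kd of 1.8 uM
        p = MechanismParams("induced_fit", **WT, kon_star=210.0,
                            koff_star=100.0,
                            initial={"P": 1e-6, "M": 1e-6})
        assert apparent_kd_equilibrium(p) * 1e6 == pytest.approx(1.81,
                                                                 abs=0.01)

    @pytest.mark.parametrize("scheme, extra, initial", [
        ("two_state", {}, {"P": 1e-6, "M": 2e-6}),
        ("conformational_selection", {"kf": 40.0, "ku": 90.0},
         {"Pu": 1e-6, "M": 2e-6}),
        ("induced_fit", {"kon_star": 35.0, "koff_star": 12.0},
         {"P": 1e-6, "M": 2e-6}),
    ])
    def test_simulator_endpoint_matches_analytic_kd(self, scheme, extra,
                                                    initial):
        p = MechanismParams(scheme, **WT, **extra, initial=initial)
        num = equilibrium_kd_from_trajectory(p)
        assert num == pytest.approx(apparent_kd_equilibrium(p), rel=1e-3)

    def test_random_parameter_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            kon = 10.0 ** rng.uniform(5.5, 7.0)
            koff = 10.0 ** rng.uniform(0.0, 1.5)
            k1 = 10.0 ** rng.uniform(0.5, 2.5)
            k2 = 10.0 ** rng.uniform(0.5, 2.5)
            cs = MechanismParams("conformational_selection", kon=kon,
                                 koff=koff, kf=k1, ku=k2,
                                 initial={"Pu": 1e-6, "M": 3e-6})
            assert (equilibrium_kd_from_trajectory(cs)
                    == pytest.approx(apparent_kd_equilibrium(cs), rel=1e-3))
            if_ = MechanismParams("induced_fit", kon=kon, koff=koff,
                                  kon_star=k1, koff_star=k2,
                                  initial={"P": 1e-6, "M": 3e-6})
            assert (equilibrium_kd_from_trajectory(if_)
                    == pytest.approx(apparent_kd_equilibrium(if_),
                                     rel=1e-3))

    def test_detailed_balance_at_equilibrium(self):
        p = MechanismParams("induced_fit", **WT, kon_star=35.0,
                            koff_star=12.0, initial={"P": 1e-6, "M": 2e-6})
        traj = simulate(p, t_end=2000.0, n_points=50)
        c = {k: v[-1] for k, v in traj.concentrations.items()}
        assert (c["P"] * c["M"] / c["Cstar"]
                == pytest.approx(p.koff / p.kon, rel=1e-4))
        assert (c["C"] / c["Cstar"]
                == pytest.approx(p.kon_star / p.koff_star, rel=1e-4))


class TestTwoStateLimits:
    def test_cs_with_frozen_unfolding_matches_two_state(self):
        two = MechanismParams("two_state", **WT,
                              initial={"P": 0.125e-6, "M": 2e-6})
        cs = MechanismParams("conformational_selection", **WT, kf=1e5,
                             ku=0.0, initial={"Ph": 0.125e-6, "M": 2e-6})
        t2 = simulate(two, t_end=0.5, n_points=300)
        tcs = simulate(cs, t_end=0.5, n_points=300)
        scale = t2.bound_signal[-1]
        assert np.max(np.abs(tcs.bound_signal - t2.bound_signal)) / scale \
            < 5e-3

    def test_if_without_isomerisation_matches_two_state(self):
        two = MechanismParams("two_state", **WT,
                              initial={"P": 0.125e-6, "M": 2e-6})
        if_ = MechanismParams("induced_fit", **WT, kon_star=0.0,
                              koff_star=1e-9,
                              initial={"P": 0.125e-6, "M": 2e-6})
        t2 = simulate(two, t_end=0.5, n_points=300)
        tif = simulate(if_, t_end=0.5, n_points=300)
        scale = t2.bound_signal[-1]
        assert np.max(np.abs(tif.bound_signal - t2.bound_signal)) / scale \
            < 5e-3
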