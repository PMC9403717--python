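"""Progress-curve integration against closed-form and mass-action oracles."""

import numpy as np
import pytest

import akrkin as ak


GRID = np.linspace(0.0, 10800.0, 181)


class TestBeerLambert:
    @pytest.mark.parametrize(
        "nadh,eps,path,expected",
        [
            (0.0, 6220.0, 1.0, 0.0),
            (100e-6, 6220.0, 1.0, 0.622),
            (90e-6, 6220.0, 0.9, 0.50382),
        ],
    )
    def test_values(self, nadh, eps, path, expected):
        assert ak.absorbance_from_concentration(nadh, eps, path) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ak.absorbance_from_concentration(-1e-6, 6220.0, 1.0)


class TestClosedForm:
    def test_boundary_values(self, params_c1, cond_c1):
        curve = ak.closed_form_no_inhibitor(params_c1, cond_c1, GRID)
        assert curve.nadh[0] == 0.0
        late = ak.closed_form_no_inhibitor(params_c1, cond_c1,
                                           np.array([0.0, 1e9]))
        assert late.nadh[-1] == pytest.approx(cond_c1.A0 + cond_c1.B0, rel=1e-9)

    def test_fast_phase_half_time(self, shared_c1, cond_c1):
        # with the slow enantiomer inert, NADH(ln2/lambda1) = A0/2
        p = ak.MechanismParams(**{**shared_c1, "k_spec2": 0.0})
        f = (cond_c1.NAD0 / p.K_NAD) / (1.0 + cond_c1.NAD0 / p.K_NAD)
        lam1 = p.k_spec1 * cond_c1.E_total * f
        t_half = np.log(2.0) / lam1
        curve = ak.closed_form_no_inhibitor(p, cond_c1, np.array([0.0, t_half]))
        assert curve.nadh[-1] == pytest.approx(cond_c1.A0 / 2.0, rel=1e-12)

    def test_rejects_inhibitor(self, params_c1, cond_c1):
        with pytest.raises(ValueError):
            ak.closed_form_no_inhibitor(params_c1, cond_c1.evolve(I_conc=1e-6), GRID)

    def test_simulator_matches_closed_form_in_frozen_regime(self, params_c1, cond_c1):
        sim = ak.simulate_progress_curve(params_c1, cond_c1, GRID,
                                         frozen_coenzyme=True)
        ref = ak.closed_form_no_inhibitor(params_c1, cond_c1, GRID)
        rel = np.abs(sim.nadh[1:] - ref.nadh[1:]) / ref.nadh[1:]
        assert np.max(rel) < 1e-6


class TestSimulator:
    def test_no_enzyme_no_signal(self, params_c1, cond_c1):
        curve = ak.simulate_progress_curve(params_c1, cond_c1.evolve(E_total=0.0), GRID)
        assert np.all(curve.absorbance == 0.0)

    def test_nadh_monotone_and_bounded(self, shared_c1):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = ak.MechanismParams(
                **shared_c1,
                K2=10 ** rng.uniform(-7, -4), k_plus2=10 ** rng.uniform(0, 3),
                K3=10 ** rng.uniform(-8, -5), k_plus3=10 ** rng.uniform(-1, 2),
            )
            cond = ak.AssayConditions(E_total=0.11e-6, NAD0=2.3e-3, S_total=90e-6,
                                      I_conc=10 ** rng.uniform(-6, -3.7))
            nadh = ak.simulate_nadh(p, [cond], GRID)[0]
            assert np.all(np.diff(nadh) >= -1e-12)
            assert nadh[-1] <= cond.S_total * (1 + 1e-9)

    def test_curve_dominance_in_inhibitor(self, shared_c1, design_c1):
        p = ak.MechanismParams(**shared_c1, K2=2e-6, k_plus2=50.0)
        concs = [0.0, 1e-6, 1e-5, 1e-4]
        nadh = ak.simulate_nadh(p, [design_c1.conditions(c) for c in concs], GRID)
        for lo, hi in zip(nadh[:-1], nadh[1:]):
            assert np.all(hi <= lo + 1e-12)

    def test_irreversible_rate_dies_reversible_rate_persists(self, shared_c1, design_c1):
        cond = design_c1.conditions(50e-6)
        irrev = ak.MechanismParams(**shared_c1, K3=50e-9, k_plus3=20.0)
        rev = ak.MechanismParams(**shared_c1, K3=50e-9, variant="reversible_only")
        long_grid = np.linspace(0, 4 * 10800.0, 241)
        n_irrev = ak.simulate_nadh(irrev, [cond], long_grid)[0]
        n_rev = ak.simulate_nadh(rev, [cond], long_grid)[0]
        assert n_irrev[-1] < cond.S_total * 0.9  # substrate remains
        rate_late_irrev = n_irrev[-1] - n_irrev[-2]
        rate_late_rev = n_rev[-1] - n_rev[-2]
        assert rate_late_irrev < 1e-3 * rate_late_rev

    def test_bad_grid_rejected(self, params_c1, cond_c1):
        with pytest.raises(ValueError):
            ak.simulate_nadh(params_c1, [cond_c1], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            ak.simulate_nadh(params_c1, [cond_c1], np.array([0.0, 2.0, 2.0]))


class TestMassActionOracle:
    def test_reduced_model_matches_oracle(self, shared_c1, design_c1):
        p = ak.MechanismParams(**shared_c1, K3=21.4e-9, k_plus3=9.4)
        cond = design_c1.conditions(10e-6)
        red = ak.simulate_progress_curve(p, cond, GRID)
        ora = ak.mass_action_reference(p, cond, GRID)
        assert abs(red.nadh[-1] - ora.nadh[-1]) / ora.nadh[-1] < 0.005

    @pytest.mark.parametrize("routing", ["direct", "via_enadh"])
    def test_agreement_improves_with_off_rate(self, shared_c1, design_c1, routing):
        p = ak.MechanismParams(**shared_c1, K3=21.4e-9, k_plus3=9.4)
        cond = design_c1.conditions(10e-6)
        red = ak.simulate_progress_curve(p, cond, GRID)
        errs = []
        for k_off in (1e1, 1e2, 1e3):
            ora = ak.mass_action_reference(p, cond, GRID, k_off=k_off,
                                           product_release=routing)
            errs.append(abs(red.nadh[-1] - ora.nadh[-1]) / ora.nadh[-1])
        assert errs[0] > errs[1] > errs[2]

    def test_sequestration_correction_tracks_oracle_at_strong_inhibition(
            self, shared_c1, design_c1):
        # enzyme-bound NADH matters when final product is only a few uM
        p = ak.MechanismParams(**shared_c1, K3=21.4e-9, k_plus3=9.4)
        cond = design_c1.conditions(200e-6)
        ora = ak.mass_action_reference(p, cond, GRID, k_off=1e5)
        on = ak.simulate_progress_curve(p, cond, GRID, sequestration=True)
        off = ak.simulate_progress_curve(p, cond, GRID, sequestration=False)
        err_on = abs(on.nadh[-1] - ora.nadh[-1]) / ora.nadh[-1]
        err_off = abs(off.nadh[-1] - ora.nadh[-1]) / ora.nadh[-1]
        assert err_on < 1e-3 < err_off
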