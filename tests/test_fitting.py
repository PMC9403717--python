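"""Parameter recovery, identifiability and optimiser invariances."""

import numpy as np
import pytest

import akrkin as ak
from akrkin.fitting import NonIdentifiableError


def gen(params, design, sd=0.0, seed=1):
    return ak.generate_curveset(params, design, ak.NoiseModel(sd=sd, seed=seed))


class TestSubstrateConstants:
    def test_noiseless_round_trip(self, shared_c1, params_c1, design_c1, fast_opts):
        cs = gen(params_c1, design_c1)
        fr = ak.fit_substrate_constants(cs.controls(), options=fast_opts)
        assert fr.converged
        assert fr.params["k_spec1"] == pytest.approx(shared_c1["k_spec1"], rel=1e-3)
        assert fr.params["k_spec2"] == pytest.approx(shared_c1["k_spec2"], rel=1e-3)
        assert fr.params["k_spec1"] >= fr.params["k_spec2"]

    def test_symmetric_racemate_degenerates(self, shared_c1, coarse_design_c1, fast_opts):
        p = ak.MechanismParams(**{**shared_c1, "k_spec2": shared_c1["k_spec1"]})
        cs = gen(p, coarse_design_c1, sd=0.001, seed=4)
        fr = ak.fit_substrate_constants(cs.controls(), options=fast_opts)
        diff = abs(fr.params["k_spec1"] - fr.params["k_spec2"])
        pooled_se = np.hypot(fr.se["k_spec1"], fr.se["k_spec2"])
        assert diff <= max(3 * pooled_se, 0.05 * fr.params["k_spec1"])

    def test_no_controls_is_an_error(self, shared_c1, params_c1, design_c1):
        cs = gen(params_c1, design_c1)
        no_ctrl = cs.subset(lambda c: c.meta.inhibitor_conc_M > 0)
        with pytest.raises(ValueError, match="control"):
            ak.fit_substrate_constants(no_ctrl, design=design_c1)

    def test_flat_curve_is_diagnosed(self, params_c1, design_c1):
        dead = design_c1.evolve(E_total=1e-30)
        cs = gen(params_c1, dead)
        with pytest.raises(NonIdentifiableError, match="flat"):
            ak.fit_substrate_constants(cs.controls())


class TestInhibitionFit:
    def test_noiseless_full_round_trip(self, shared_c1, design_c1):
        truth = ak.MechanismParams(**shared_c1, K3=21.4e-9, k_plus3=9.4)
        cs = gen(truth, design_c1.evolve(replicates=1))
        fr = ak.fit_inhibition(cs, shared_c1, {"K3": None, "k_plus3": None},
                               variant="full", options=ak.FitOptions(n_starts=4))
        assert fr.converged
        assert fr.params["K3"] == pytest.approx(21.4e-9, rel=1e-3)
        assert fr.params["k_plus3"] == pytest.approx(9.4, rel=1e-3)

    def test_noiseless_reversible_round_trip(self, shared_c1, coarse_design_c1):
        truth = ak.MechanismParams(**shared_c1, K2=49.7e-6, variant="reversible_only")
        cs = gen(truth, coarse_design_c1.evolve(replicates=1))
        fr = ak.fit_inhibition(cs, shared_c1, {"K2": None},
                               variant="reversible_only",
                               options=ak.FitOptions(n_starts=2))
        assert fr.params["K2"] == pytest.approx(49.7e-6, rel=1e-3)

    def test_control_only_set_is_unidentifiable(self, shared_c1, params_c1, design_c1):
        cs = gen(params_c1, design_c1).controls()
        with pytest.raises(ValueError, match="concentration"):
            ak.fit_inhibition(cs, shared_c1, {"K3": None, "k_plus3": None},
                              design=design_c1)

    def test_variant_free_parameter_mismatch(self, shared_c1, params_c1, design_c1):
        cs = gen(params_c1, design_c1)
        with pytest.raises(ValueError):
            ak.fit_inhibition(cs, shared_c1, {"composite3": None}, variant="full")
        with pytest.raises(ValueError):
            ak.fit_inhibition(cs, shared_c1, {"k_plus3": None},
                              variant="reversible_only")

    def test_nested_model_residuals(self, shared_c1, coarse_design_c1, fast_opts):
        truth = ak.MechanismParams(**shared_c1, K3=100e-9, k_plus3=2.0)
        cs = gen(truth, coarse_design_c1, sd=0.002, seed=6)
        full = ak.fit_inhibition(cs, shared_c1, {"K3": None, "k_plus3": None},
                                 variant="full", options=fast_opts)
        rev = ak.fit_inhibition(cs, shared_c1, {"K3": None},
                                variant="reversible_only", options=fast_opts)
        assert full.rss <= rev.rss * (1 + 1e-9)

    def test_permutation_invariance(self, shared_c1, coarse_design_c1):
        truth = ak.MechanismParams(**shared_c1, K3=100e-9, k_plus3=2.0)
        cs = gen(truth, coarse_design_c1, sd=0.002, seed=2)
        opts = ak.FitOptions(n_starts=1)
        fr1 = ak.fit_inhibition(cs, shared_c1, {"K3": None, "k_plus3": None},
                                variant="full", options=opts)
        rng = np.random.default_rng(0)
        shuffled = list(cs.curves)
        rng.shuffle(shuffled)
        cs2 = ak.CurveSet(shuffled, dict(cs.attrs))
        fr2 = ak.fit_inhibition(cs2, shared_c1, {"K3": None, "k_plus3": None},
                                variant="full", options=opts)
        for k in fr1.free_names:
            assert fr2.params[k] == pytest.approx(fr1.params[k], rel=1e-9)

    def test_estimator_calibration(self, shared_c1, coarse_design_c1, fast_opts):
        """Empirical spread over noisy replicate fits is within a factor of
        two of the reported asymptotic standard errors."""
        truth = ak.MechanismParams(**shared_c1, K3=100e-9, k_plus3=2.0)
        ests, ses = [], []
        for seed in range(20):
            cs = gen(truth, coarse_design_c1, sd=0.002, seed=100 + seed)
            fr = ak.fit_inhibition(cs, shared_c1, {"K3": None, "k_plus3": None},
                                   variant="full",
                                   options=ak.FitOptions(n_starts=1))
            ests.append([fr.params["K3"], fr.params["k_plus3"]])
            ses.append([fr.se["K3"], fr.se["k_plus3"]])
        emp = np.std(np.log(ests), axis=0)
        asym = np.median(np.array(ses) / np.array(ests), axis=0)
        for e, a in zip(emp, asym):
            assert a / 2 <= e <= a * 2


class TestVariantSelection:
    def test_reversible_truth_recommended(self, shared_c1, coarse_design_c1, fast_opts):
        truth = ak.MechanismParams(**shared_c1, K2=227e-6, variant="reversible_only")
        cs = gen(truth, coarse_design_c1, sd=0.002, seed=7)
        sel = ak.select_variant(cs, shared_c1, branches=("nad",), options=fast_opts)
        assert sel["recommendation"] == "reversible_only"

    def test_full_truth_recommended(self, shared_c1, coarse_design_c1, fast_opts):
        truth = ak.MechanismParams(**shared_c1, K3=21.4e-9, k_plus3=9.4)
        cs = gen(truth, coarse_design_c1, sd=0.002, seed=8)
        sel = ak.select_variant(cs, shared_c1, branches=("nadh",), options=fast_opts)
        assert sel["recommendation"] == "full"

    def test_parabolic_truth_recommended_and_recovered(self, coarse_design_c1):
        shared_c3 = dict(ak.constants.SHARED_CONSTANTS["AKR1C3"])
        design = ak.default_assay_design("AKR1C3").evolve(interval=300.0, replicates=2)
        truth = ak.MechanismParams(**shared_c3, composite3=1.97e6, variant="parabolic")
        cs = gen(truth, design, sd=0.002, seed=9)
        sel = ak.select_variant(cs, shared_c3, branches=("nadh",),
                                options=ak.FitOptions(n_starts=2))
        assert sel["recommendation"] == "parabolic"
        assert sel["fits"]["parabolic"].params["composite3"] == pytest.approx(
            1.97e6, rel=0.2)
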