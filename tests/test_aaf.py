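import numpy as np
import pytest

from aafburden import (
    ConfigurationError,
    RiskFunction,
    aaf_chronic,
    aaf_hiv,
    aaf_ihd,
    aaf_injury,
    aaf_wholly_attributable,
    compute_aafs,
)
from aafburden.aaf import aaf_categorical
from aafburden.risk import CauseGroup
from aafburden.strata import StratumKey

from conftest import make_profile, mc_chronic_numerator

CONST2 = RiskFunction("c", "men", "constant", (2.0,))
NULL = RiskFunction("c", "men", "constant", (1.0,))


class TestChronic:
    def test_all_lifetime_abstainers(self):
        prof = make_profile(p_abstainer=1.0, p_former=0.0, mean_gpd=0.0)
        assert aaf_chronic(prof, CONST2).aaf == 0.0

    def test_constant_rr_closed_form(self):
        prof = make_profile(p_abstainer=0.5, p_former=0.0, binge_prevalence=0.0)
        res = aaf_chronic(prof, CONST2)
        assert res.aaf == pytest.approx(0.5 / 1.5, abs=1e-9)

    def test_null_risk_gives_zero(self):
        prof = make_profile(p_abstainer=0.3, p_former=0.2)
        assert aaf_chronic(prof, NULL).aaf == 0.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(11)
        prof = make_profile(p_abstainer=0.3, p_former=0.1, mean_gpd=20.0)
        rf = RiskFunction("c", "men", "log_linear", (0.01,), rr_former=1.2)
        got = aaf_chronic(prof, rf).aaf
        num = mc_chronic_numerator(rng, prof, lambda x: np.exp(0.01 * x), 1.2)
        assert got == pytest.approx(num / (num + 1), abs=0.002)

    def test_sex_mismatch_rejected(self):
        prof = make_profile(sex="women", mean_gpd=10.0)
        with pytest.raises(ConfigurationError):
            aaf_chronic(prof, CONST2)

    def test_former_only(self):
        prof = make_profile(p_abstainer=0.5, p_former=0.5, mean_gpd=0.0)
        rf = RiskFunction("c", "men", "constant", (1.0,), rr_former=1.4)
        # N = 0.5 * 0.4
        assert aaf_chronic(prof, rf).aaf == pytest.approx(0.2 / 1.2, abs=1e-12)


class TestIHD:
    PROT = RiskFunction("ihd", "men", "constant", (0.8,), rr_former=1.0,
                        role="protective")
    DET = RiskFunction("ihd", "men", "constant", (1.5,), role="detrimental")

    def test_no_binge_protective_gives_negative(self):
        prof = make_profile(p_abstainer=0.5, p_former=0.0, binge_prevalence=0.0)
        assert aaf_ihd(prof, self.PROT, self.DET).aaf < 0

    def test_all_binge_floored_nonnegative(self):
        prot_below_one = RiskFunction("ihd", "men", "constant", (0.5,),
                                      role="protective")
        det_below_one = RiskFunction("ihd", "men", "constant", (0.7,),
                                     role="detrimental")
        prof = make_profile(p_abstainer=0.5, p_former=0.0, binge_prevalence=1.0)
        assert aaf_ihd(prof, prot_below_one, det_below_one).aaf >= 0

    def test_fifty_fifty_constant_closed_form(self):
        prof = make_profile(p_abstainer=0.5, p_former=0.0, binge_prevalence=0.5)
        res = aaf_ihd(prof, self.PROT, self.DET)
        # N = 0.5 * (0.5*(-0.2) + 0.5*0.5) = 0.075
        assert res.aaf == pytest.approx(0.075 / 1.075, abs=1e-9)

    def test_missing_binge_prevalence_rejected(self):
        prof = make_profile(binge_prevalence=None)
        with pytest.raises(ConfigurationError):
            aaf_ihd(prof, self.PROT, self.DET)


class TestInjury:
    CELLS_NULL = {"nonbinge": [1.0] * 4, "binge": [1.0] * 4}

    def test_all_rr_one_gives_zero(self):
        prof = make_profile(p_abstainer=0.3, p_former=0.1)
        assert aaf_injury(prof, self.CELLS_NULL, "inj").aaf == 0.0

    def test_single_cell_closed_form(self):
        res = aaf_categorical(StratumKey("White", "35-44", "men"), "inj",
                              "injury", [0.3], [3.0])
        assert res.aaf == pytest.approx(0.6 / 1.6, abs=1e-12)

    def test_collapses_to_chronic_under_constant_rr(self):
        prof = make_profile(p_abstainer=0.3, p_former=0.0, binge_prevalence=0.4)
        cells = {"nonbinge": [1.7] * 4, "binge": [1.7] * 4}
        got = aaf_injury(prof, cells, "inj").aaf
        ref = aaf_chronic(prof, RiskFunction("inj", "men", "constant", (1.7,))).aaf
        assert got == pytest.approx(ref, abs=1e-9)

    def test_wrong_cell_count_names_problem(self):
        prof = make_profile()
        with pytest.raises(ConfigurationError, match="volume categories"):
            aaf_injury(prof, {"nonbinge": [1.5], "binge": [2.0] * 4}, "inj")
        with pytest.raises(ConfigurationError, match="binge"):
            aaf_injury(prof, {"nonbinge": [1.5] * 4}, "inj")


class TestHIV:
    def test_threshold_above_cap(self):
        prof = make_profile()
        assert aaf_hiv(prof, 300.0, 2.0).aaf == 0.0

    def test_exposed_mass_closed_form(self):
        res = aaf_categorical(StratumKey("White", "35-44", "men"), "HIV/AIDS",
                              "hiv", [0.2], [2.0])
        assert res.aaf == pytest.approx(0.2 / 1.2, abs=1e-12)

    def test_monotone_in_exposed_mass(self):
        masses = np.linspace(0.0, 0.8, 9)
        aafs = [aaf_categorical(StratumKey("W", "35-44", "men"), "h", "hiv",
                                [m], [2.0]).aaf for m in masses]
        assert np.all(np.diff(aafs) > 0)

    def test_invalid_parameters_rejected(self):
        prof = make_profile()
        with pytest.raises(ConfigurationError):
            aaf_hiv(prof, -1.0, 2.0)
        with pytest.raises(ConfigurationError):
            aaf_hiv(prof, 48.0, 0.0)


class TestWhollyAttributable:
    CAUSE = CauseGroup("Alcohol use disorders", "F10", "noncommunicable",
                       "wholly_attributable")

    def test_always_one(self):
        assert aaf_wholly_attributable(make_profile(), self.CAUSE).aaf == 1.0

    def test_zero_drinking_still_one_with_warning(self, caplog):
        prof = make_profile(p_abstainer=1.0, p_former=0.0, mean_gpd=0.0)
        with caplog.at_level("WARNING"):
            res = aaf_wholly_attributable(prof, self.CAUSE)
        assert res.aaf == 1.0
        assert "inconsistent" in caplog.text

    def test_flag_mismatch_rejected(self):
        chronic = CauseGroup("Diabetes", "E10", "noncommunicable", "chronic",
                             protective_ok=True)
        with pytest.raises(ConfigurationError):
            aaf_wholly_attributable(make_profile(), chronic)


class TestInvariants:
    def test_null_risk_all_methods(self, registry):
        prof = make_profile(p_abstainer=0.3, p_former=0.2)
        assert aaf_chronic(prof, NULL).aaf == 0.0
        null = RiskFunction("c", "men", "constant", (1.0,))
        assert aaf_ihd(prof, null, null).aaf == 0.0
        assert aaf_injury(prof, TestInjury.CELLS_NULL, "inj").aaf == 0.0
        assert aaf_categorical(prof.stratum, "h", "hiv", [0.3], [1.0]).aaf == 0.0

    def test_monotone_in_current_prevalence(self):
        rng = np.random.default_rng(5)
        rf = RiskFunction("c", "men", "log_linear", (0.012,), rr_former=1.1)
        for _ in range(10):
            mean = rng.uniform(5, 60)
            p_former = rng.uniform(0, 0.3)
            aafs = []
            for p_cur in np.linspace(0.0, 1.0 - p_former, 6):
                p_abs = max(0.0, 1.0 - p_former - p_cur)
                prof = make_profile(p_abstainer=p_abs, p_former=p_former,
                                    mean_gpd=mean if p_cur else 0.0)
                aafs.append(aaf_chronic(prof, rf).aaf)
            assert np.all(np.diff(aafs) >= -1e-12)

    def test_aaf_never_exceeds_one(self, registry):
        prof = make_profile(p_abstainer=0.05, p_former=0.05, mean_gpd=80.0,
                            binge_prevalence=0.8)
        df = compute_aafs([prof], registry)
        assert (df.aaf <= 1.0).all()
        assert (df.loc[df.method == "wholly_attributable", "aaf"] == 1.0).all()
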