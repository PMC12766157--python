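"""Mixture cure model fitting on grouped relative survival."""

import numpy as np
import pandas as pd
import pytest

from mrisk import (CureModelSpec, SimulationConfig, StratumSim, SurvivalLaw,
                   InstantDeathLaw, apply_eligibility, build_lifetable,
                   fit_mixture_cure, predict_rs, select_family,
                   simulate_cohort)
from mrisk.cure_model import CureModelFit, PatternFit
from mrisk.relative_survival import GroupedLifeTable, LIFETABLE_COLUMNS


def _flat_lifetable(p_obs=0.99, p_exp=0.99, n0=10_000, k=15):
    """Synthetic life table whose relative survival is exactly 1."""
    rows, n = [], float(n0)
    for i in range(k):
        d = n * (1.0 - p_obs)
        rows.append({"interval": i + 1, "start": 12 * i, "end": 12 * (i + 1),
                     "n": n, "d": d, "w": 0.0, "n_eff": n,
                     "p_obs": p_obs, "p_exp": p_exp, "r_int": p_obs / p_exp,
                     "rs_cum": (p_obs / p_exp) ** (i + 1), "se_rs": 0.001})
        n -= d
    tab = pd.DataFrame(rows)[list(LIFETABLE_COLUMNS)]
    return GroupedLifeTable(stratum="flat", interval_width=12, table=tab)


class TestPredictRs:
    def test_closed_forms(self, weibull_truth_fit):
        fit = weibull_truth_fit
        assert predict_rs(fit, 0.0) == pytest.approx(1.0)
        c = fit.patterns[0].c
        assert predict_rs(fit, 1e9) == pytest.approx(c, abs=1e-6)

    def test_exponential_special_case(self):
        # hand-built fit: c = 0.5, λ = 1/24, γ = 1 → RS(24) = 0.5 + 0.5/e
        fit = CureModelFit(
            stratum="x", family="weibull", spec=CureModelSpec(),
            beta_c=np.array([0.0]), beta_lam=np.array([np.log(1 / 24)]),
            log_gamma=0.0, se=None, loglik=0.0, converged=True, n_params=3,
            patterns=[PatternFit({}, 0.5, 1 / 24, 1.0, False)], tables=[])
        assert predict_rs(fit, 24.0) == pytest.approx(0.5 + 0.5 * np.exp(-1),
                                                      abs=1e-12)
        with pytest.raises(KeyError):
            predict_rs(fit, 10.0, {"age_group": "15-44"})


class TestFitting:
    def test_recovers_weibull_truth(self, weibull_truth_fit):
        """ĉ within ±0.02, shape and median within 5% (n = 50,000)."""
        pf = weibull_truth_fit.patterns[0]
        assert weibull_truth_fit.converged
        assert pf.c == pytest.approx(0.70, abs=0.02)
        assert pf.gamma == pytest.approx(1.2, rel=0.05)
        median = np.log(2.0) ** (1 / pf.gamma) / pf.lam
        assert median == pytest.approx(36.0, rel=0.05)

    def test_flat_rs_drives_cure_to_boundary(self):
        fit = fit_mixture_cure(_flat_lifetable(), CureModelSpec("weibull"))
        pf = fit.patterns[0]
        assert pf.boundary
        assert pf.c > 0.99

    def test_no_cure_fit_tracks_lifetable(self, rate_table):
        """c = 0 truth: fitted RS within 2 SE of the life-table RS."""
        config = SimulationConfig(
            n_subjects=20_000,
            strata=[StratumSim("III", 1.0, 0.0,
                               SurvivalLaw("weibull", 36.0, 1.2))],
            s4_law=InstantDeathLaw(), rate_table=rate_table, seed=14)
        records, _ = simulate_cohort(config)
        eligible, _ = apply_eligibility(records)
        lt = build_lifetable(eligible, rate_table, stratum="III")
        fit = fit_mixture_cure(lt, CureModelSpec("weibull"), stratum="III")
        rs_model = predict_rs(fit, lt.t_bounds[1:])
        resid = np.abs(rs_model - lt.rs_cum)
        assert np.all(resid <= 2.0 * lt.table["se_rs"].to_numpy() + 1e-9)

    def test_too_few_intervals_rejected(self):
        lt = _flat_lifetable(k=5)
        with pytest.raises(ValueError, match="8"):
            fit_mixture_cure(lt, CureModelSpec("weibull"))

    def test_reference_level_reparameterisation_invariance(
            self, weibull_truth_cohort, rate_table):
        """The maximised likelihood is unchanged by swapping the reference."""
        _, records, _ = weibull_truth_cohort
        eligible, _ = apply_eligibility(records)
        young = [r for r in eligible if r.age_dx <= 54]
        old = [r for r in eligible if r.age_dx > 54]
        tables = [
            ({"age_group": "15-54"}, build_lifetable(young, rate_table)),
            ({"age_group": "55-74"}, build_lifetable(old, rate_table)),
        ]
        lev_a = {"age_group": ["15-54", "55-74"]}
        lev_b = {"age_group": ["55-74", "15-54"]}
        fit_a = fit_mixture_cure(tables, CureModelSpec("weibull", lev_a))
        fit_b = fit_mixture_cure(tables, CureModelSpec("weibull", lev_b))
        assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-3)
        for pat in ({"age_group": "15-54"}, {"age_group": "55-74"}):
            assert fit_a.pattern_fit(pat).c == pytest.approx(
                fit_b.pattern_fit(pat).c, abs=1e-3)


class TestFamilySelection:
    @staticmethod
    def _fake(family, stratum, converged=True, loglik=-100.0):
        return CureModelFit(
            stratum=stratum, family=family, spec=CureModelSpec(family),
            beta_c=np.zeros(1), beta_lam=np.zeros(1), log_gamma=0.0,
            se=None, loglik=loglik, converged=converged, n_params=3,
            patterns=[PatternFit({}, 0.5, 0.05, 1.0, False)], tables=[])

    def test_loglogistic_preferred_when_all_converge(self):
        fits = {"weibull": {"I": self._fake("weibull", "I", loglik=-101)},
                "loglogistic": {"I": self._fake("loglogistic", "I")}}
        assert select_family(fits).family == "loglogistic"

    def test_single_failure_triggers_table_wide_weibull(self):
        fits = {
            "weibull": {s: self._fake("weibull", s) for s in "I II III".split()},
            "loglogistic": {
                "I": self._fake("loglogistic", "I"),
                "II": self._fake("loglogistic", "II", converged=False),
                "III": self._fake("loglogistic", "III")},
        }
        sel = select_family(fits)
        assert sel.family == "weibull"
        assert sel.triggering_strata == ["II"]

    def test_identical_likelihood_tie_breaks_to_weibull(self):
        fits = {"weibull": {"I": self._fake("weibull", "I")},
                "loglogistic": {"I": self._fake("loglogistic", "I")}}
        assert select_family(fits).family == "weibull"
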