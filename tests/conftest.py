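"""Shared fixtures: rate tables and moderately sized simulated cohorts.

Expensive simulations are session-scoped so several tests can reuse them.
All randomness is seeded; nothing here touches the network or disk outside
pytest's tmp directories.
"""

import numpy as np
import pytest

from mrisk import (CaseRecord, CureModelSpec, InstantDeathLaw,
                   SimulationConfig, StratumSim, SurvivalLaw,
                   apply_eligibility, build_lifetable, fit_mixture_cure,
                   gompertz_rate_table, simulate_cohort)


@pytest.fixture(scope="session")
def rate_table():
    return gompertz_rate_table()


@pytest.fixture(scope="session")
def weibull_truth_cohort(rate_table):
    """50k-subject cohort whose T* is exactly Weibull (T2 ≡ 0).

    Truth: c = 0.70, T* ~ Weibull(shape 1.2, median 36 months), other-cause
    mortality from the shared rate table, accrual 1997–2017 with follow-up
    to December 2018.
    """
    config = SimulationConfig(
        n_subjects=50_000,
        strata=[StratumSim("II", 1.0, 0.70, SurvivalLaw("weibull", 36.0, 1.2))],
        s4_law=InstantDeathLaw(),
        rate_table=rate_table,
        seed=11,
    )
    records, truth = simulate_cohort(config)
    return config, records, truth


@pytest.fixture(scope="session")
def weibull_truth_lifetable(weibull_truth_cohort, rate_table):
    _, records, _ = weibull_truth_cohort
    eligible, _ = apply_eligibility(records)
    return build_lifetable(eligible, rate_table, stratum="II")


@pytest.fixture(scope="session")
def weibull_truth_fit(weibull_truth_lifetable):
    return fit_mixture_cure(weibull_truth_lifetable,
                            CureModelSpec(family="weibull"), stratum="II")


def make_record(id="x", age=55, year_dx=2005, month_dx=6, stage="II",
                profile="HR+/HER2-", vital="alive", year_end=2018,
                month_end=12, basis="clinical/path") -> CaseRecord:
    return CaseRecord(id=id, sex="female", age_dx=age, year_dx=year_dx,
                      month_dx=month_dx, stage=stage, profile=profile,
                      vital_status=vital, year_end=year_end,
                      month_end=month_end, basis=basis)


@pytest.fixture
def record_factory():
    return make_record
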