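"""Model-agreement statistics for simulated-versus-observed comparisons.

For paired simulated (S) and observed (O) series: RMSE and its
mean-normalized percentage form; the Willmott (1981) index of agreement

    ID = 1 - sum((S - O)^2) / sum((|S - mu_O| + |O - mu_O|)^2),

which is <= 1 and equals 1 only for perfect agreement; the ordinary
least-squares slope/intercept/R^2 of simulated on observed; and the
two-sided Welch t-test of the two means.  A report is judged "good" when
the slope is near 1, the intercept near 0, R^2 near 1, the Welch p above
0.05 and the RMSE no larger than the observed replicate standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSeries:
    """Paired simulated and observed values in the same units."""

    sim: tuple
    obs: tuple

    def __post_init__(self) -> None:
        if len(self.sim) != len(self.obs):
            raise StatsError("sim and obs must have equal length")
        if len(self.sim) < 2:
            raise StatsError("need at least 2 pairs")

    @property
    def n(self) -> int:
        return len(self.sim)

    def arrays(self):
        return (
            np.asarray(self.sim, dtype=float),
            np.asarray(self.obs, dtype=float),
        )


@dataclass(frozen=True)
class EvalReport:
    """One row of agreement statistics for a sim/obs pairing."""

    rmse: float
    rmse_n_pct: float
    willmott_id: float
    slope: float
    intercept: float
    r2: float
    p_welch: float
    n: int


def rmse_n(pairs: PairedSeries) -> tuple[float, float]:
    """RMSE and the observed-mean-normalized RMSE in percent."""
    s, o = pairs.arrays()
    mu = o.mean()
    if mu == 0:
        raise StatsError("observed mean is zero; normalized RMSE undefined")
    rmse = float(np.sqrt(np.mean((s - o) ** 2)))
    return rmse, 100.0 * rmse / mu


def willmott_id(pairs: PairedSeries, typeset_variant: bool = False) -> float:
    """Willmott index of agreement (<= 1; 1 iff sim == obs).

    ``typeset_variant=True`` selects the difference-denominator variant
    sum((|S - mu_O| - |O - mu_O|)^2) for forensic comparison; the standard
    sum-form is the default.
    """
    s, o = pairs.arrays()
    mu = o.mean()
    sp = np.abs(s - mu)
    op = np.abs(o - mu)
    denom = np.sum((sp - op) ** 2) if typeset_variant else np.sum((sp + op) ** 2)
    if denom == 0:
        raise StatsError("agreement index undefined: zero potential-error denominator")
    return float(1.0 - np.sum((s - o) ** 2) / denom)


def linreg_stats(pairs: PairedSeries) -> tuple[float, float, float]:
    """OLS of simulated on observed: (slope, intercept, R^2)."""
    s, o = pairs.arrays()
    if pairs.n < 3:
        raise StatsError("need at least 3 pairs for regression")
    if np.var(o) == 0:
        raise StatsError("observed values have zero variance")
    res = sps.linregress(o, s)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def welch_p(pairs: PairedSeries) -> float:
    """Two-sided Welch t-test p-value for mean(sim) vs mean(obs).

    Uses Welch-Satterthwaite degrees of freedom.  When both sides have zero
    variance and equal means the test is degenerate and p = 1 by convention.
    """
    s, o = pairs.arrays()
    if np.var(s) == 0 and np.var(o) == 0:
        return 1.0 if s.mean() == o.mean() else 0.0
    t = sps.ttest_ind(s, o, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):
        return 1.0 if s.mean() == o.mean() else 0.0
    return p


def evaluate(pairs: PairedSeries) -> EvalReport:
    """Full agreement report for one sim/obs pairing."""
    rmse, rmsen = rmse_n(pairs)
    slope, intercept, r2 = linreg_stats(pairs)
    return EvalReport(
        rmse=rmse,
        rmse_n_pct=rmsen,
        willmott_id=willmott_id(pairs),
        slope=slope,
        intercept=intercept,
        r2=r2,
        p_welch=welch_p(pairs),
        n=pairs.n,
    )


def agreement_criteria(
    report: EvalReport,
    obs_sd: float,
    slope_band: tuple = (0.75, 1.25),
    intercept_limit: float | None = None,
    r2_min: float = 0.8,
    p_min: float = 0.05,
) -> dict:
    """Boolean verdicts of the standard model-acceptance reading.

    Good agreement: slope near 1, intercept near 0 (within
    ``intercept_limit``, default one observed SD), R^2 high, Welch p above
    0.05 (means not distinguishable) and RMSE within the observed SD.
    """
    if intercept_limit is None:
        intercept_limit = obs_sd
    return {
        "slope_ok": slope_band[0] <= report.slope <= slope_band[1],
        "intercept_ok": abs(report.intercept) <= intercept_limit,
        "r2_ok": report.r2 >= r2_min,
        "means_indistinguishable": report.p_welch > p_min,
        "rmse_within_obs_sd": report.rmse <= obs_sd,
    }
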