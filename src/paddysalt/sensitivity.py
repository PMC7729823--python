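"""One-at-a-time sensitivity protocol and variance decomposition.

Each of the four salinity-response parameters (a_pn, b_pn, a_tr, b_tr) is
perturbed individually by +-1..6 standard deviations while the others stay
at their base values; every perturbed parameter set is run across a grid of
salinity levels and weather years; outputs (yield, total biomass, total
transpiration, water productivity) are collected into a long table; and the
share of output variance attributable to the parameter factor versus the
environment factor is quantified by balanced two-way ANOVA with
method-of-moments variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .salinity import SalinityParams

logger = logging.getLogger(__name__)

PARAM_NAMES = ("a_pn", "b_pn", "a_tr", "b_tr")
DEFAULT_MULTIPLIERS = (-6, -5, -4, -3, -2, -1, 1, 2, 3, 4, 5, 6)
DEFAULT_LEVELS = (1.0, 4.0, 8.0, 12.0)  # control (fresh range) + treatments, dS/m


class SensitivityError(ValueError):
    pass


def default_sds(base: SalinityParams, frac: float = 0.05) -> dict:
    """Fractional parameter SDs (default 5% of the base value).

    The greenhouse SDs of the response parameters are not available, so the
    default perturbation scale is a package choice, configurable here.
    """
    return {name: frac * getattr(base, name) for name in PARAM_NAMES}


def build_grid(
    base: SalinityParams,
    sds: dict | None = None,
    multipliers=DEFAULT_MULTIPLIERS,
    levels=DEFAULT_LEVELS,
    years=(0,),
) -> pd.DataFrame:
    """One-at-a-time perturbation grid.

    One row per (parameter, multiplier, salinity level, year) with the
    perturbed parameter value, plus one baseline row per (level, year)
    (``parameter='baseline'``, multiplier 0).  Perturbations that would
    push a parameter non-positive are dropped with a warning.
    """
    if sds is None:
        sds = default_sds(base)
    for name in PARAM_NAMES:
        if sds.get(name, 0) <= 0:
            raise SensitivityError(f"SD for {name} must be positive")
    if 0 in multipliers:
        raise SensitivityError("multiplier 0 is reserved for the baseline rows")

    rows = []
    for level in levels:
        for year in years:
            rows.append(
                dict(
                    parameter="baseline",
                    multiplier=0,
                    value=np.nan,
                    level=level,
                    year=year,
                )
            )
    for name in PARAM_NAMES:
        for m in multipliers:
            value = getattr(base, name) + m * sds[name]
            if value <= 0:
                logger.warning(
                    "dropping %s multiplier %+d: perturbed value %.4f <= 0",
                    name,
                    m,
                    value,
                )
                continue
            for level in levels:
                for year in years:
                    rows.append(
                        dict(
                            parameter=name,
                            multiplier=m,
                            value=value,
                            level=level,
                            year=year,
                        )
                    )
    return pd.DataFrame(rows)


def water_productivity(yield_kg_ha: float, transpiration_mm: float) -> float:
    """Grain yield per unit seasonal transpiration (kg/ha/mm)."""
    if transpiration_mm <= 0:
        raise SensitivityError("transpiration must be positive")
    if yield_kg_ha < 0:
        raise SensitivityError("yield must be non-negative")
    return yield_kg_ha / transpiration_mm


def run_scenarios(grid: pd.DataFrame, runner, base: SalinityParams) -> pd.DataFrame:
    """Run one season per grid row and collect the outputs.

    ``runner(params, level, year)`` must return a
    :class:`~paddysalt.crop.SeasonResult`; the salinity pattern of a level
    is the runner's business and is held identical across years.  Rows are
    independent, so the result table is invariant to execution order.
    """
    records = []
    for row in grid.itertuples(index=False):
        params = (
            base
            if row.parameter == "baseline"
            else base.replace(**{row.parameter: row.value})
        )
        try:
            season = runner(params, row.level, row.year)
        except Exception as exc:  # re-raise with the grid-cell context
            raise RuntimeError(
                f"scenario failed at parameter={row.parameter} "
                f"multiplier={row.multiplier} level={row.level} year={row.year}: {exc}"
            ) from exc
        records.append(
            dict(
                parameter=row.parameter,
                multiplier=row.multiplier,
                level=row.level,
                year=row.year,
                yield_kg_ha=season.yield_kg_ha,
                wagt_kg_ha=season.final_wagt,
                transpiration_mm=season.total_transpiration_mm,
                water_productivity=water_productivity(
                    season.yield_kg_ha, season.total_transpiration_mm
                ),
            )
        )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class VarianceComponents:
    """Percent contributions to output variance, plus the output CV."""

    pct: dict
    cv_pct: float


def variance_components(
    table: pd.DataFrame,
    value_col: str,
    factor_a: str = "parameter_setting",
    factor_b: str = "env",
) -> VarianceComponents:
    """Balanced two-way ANOVA variance components (method of moments).

    Factor A (e.g. the perturbed-parameter setting) and factor B (the
    environment: year x salinity level) must form a balanced crossed layout.
    Components: sigma2_A = (MS_A - MS_E)/(r*b), sigma2_B = (MS_B - MS_E)/(r*a),
    sigma2_E = MS_E, negative estimates truncated at zero; contributions are
    reported as percentages summing to 100.  Constant outputs give all-zero
    components and zero CV.
    """
    counts = table.groupby([factor_a, factor_b]).size()
    if counts.nunique() > 1:
        raise SensitivityError("unbalanced table: unequal cell counts")
    r = int(counts.iloc[0])
    y = table[value_col].to_numpy(dtype=float)
    grand = y.mean()
    a_levels = table[factor_a].unique()
    b_levels = table[factor_b].unique()
    a, b = len(a_levels), len(b_levels)
    if len(table) != a * b * r:
        raise SensitivityError("table is not a complete crossed layout")

    cv = 0.0 if grand == 0 else 100.0 * y.std(ddof=0) / abs(grand)
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        return VarianceComponents(
            pct={factor_a: 0.0, factor_b: 0.0, "residual": 0.0}, cv_pct=0.0
        )

    mean_a = table.groupby(factor_a)[value_col].mean()
    mean_b = table.groupby(factor_b)[value_col].mean()
    ss_a = r * b * float(np.sum((mean_a.to_numpy() - grand) ** 2))
    ss_b = r * a * float(np.sum((mean_b.to_numpy() - grand) ** 2))
    ss_e = max(0.0, ss_total - ss_a - ss_b)

    df_a, df_b = a - 1, b - 1
    df_e = len(y) - 1 - df_a - df_b
    ms_a = ss_a / df_a if df_a else 0.0
    ms_b = ss_b / df_b if df_b else 0.0
    ms_e = ss_e / df_e if df_e > 0 else 0.0

    var_a = max(0.0, (ms_a - ms_e) / (r * b)) if df_a else 0.0
    var_b = max(0.0, (ms_b - ms_e) / (r * a)) if df_b else 0.0
    var_e = ms_e
    total = var_a + var_b + var_e
    if total == 0:
        pct = {factor_a: 0.0, factor_b: 0.0, "residual": 0.0}
    else:
        pct = {
            factor_a: 100.0 * var_a / total,
            factor_b: 100.0 * var_b / total,
            "residual": 100.0 * var_e / total,
        }
    return VarianceComponents(pct=pct, cv_pct=cv)


def decompose_outputs(
    results: pd.DataFrame,
    outputs=("yield_kg_ha", "wagt_kg_ha", "water_productivity"),
) -> pd.DataFrame:
    """Variance decomposition of each output of a scenario table.

    The perturbed-parameter setting (parameter x multiplier) is factor A,
    the environment (level x year) factor B.  Baseline rows are excluded
    (they are not part of the crossed design).
    """
    t = results[results["parameter"] != "baseline"].copy()
    t["parameter_setting"] = (
        t["parameter"] + ":" + t["multiplier"].astype(int).astype(str)
    )
    t["env"] = t["level"].astype(str) + "/" + t["year"].astype(str)
    rows = []
    for out in outputs:
        vc = variance_components(t, out)
        rows.append(
            dict(
                output=out,
                parameter_pct=vc.pct["parameter_setting"],
                environment_pct=vc.pct["env"],
                residual_pct=vc.pct["residual"],
                cv_pct=vc.cv_pct,
            )
        )
    return pd.DataFrame(rows)


def per_parameter_decomposition(
    results: pd.DataFrame,
    outputs=("yield_kg_ha", "wagt_kg_ha", "water_productivity"),
) -> pd.DataFrame:
    """Contribution of each individual parameter's variation to each output.

    The one-at-a-time design varies a single parameter per slice, so each
    parameter's share is estimated from its own slice of the table:
    factor A = the multiplier (the parameter's perturbation level), factor
    B = the environment.  The parameter_pct column is that parameter's
    variance share against the environmental variability it was crossed
    with.
    """
    t = results[results["parameter"] != "baseline"].copy()
    t["env"] = t["level"].astype(str) + "/" + t["year"].astype(str)
    rows = []
    for param in sorted(t["parameter"].unique()):
        sub = t[t["parameter"] == param]
        for out in outputs:
            vc = variance_components(sub, out, factor_a="multiplier", factor_b="env")
            rows.append(
                dict(
                    parameter=param,
                    output=out,
                    parameter_pct=vc.pct["multiplier"],
                    environment_pct=vc.pct["env"],
                    residual_pct=vc.pct["residual"],
                    cv_pct=vc.cv_pct,
                )
            )
    return pd.DataFrame(rows)
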