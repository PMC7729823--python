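"""Configuration and file I/O.

All tables travel as plain CSV in one unit system: ISO-8601 dates, day
indices 0-based from transplanting, depths in mm, EC in dS/m, tensions in
kPa, biomass in kg/ha.  Converters live at this boundary only; the rest of
the package never sees a date string.

The run configuration is a YAML mapping validated strictly: unknown keys
are an error (no silently ignored typos), referenced files must exist, and
the fully resolved configuration is echoed to the log for provenance.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import crop as crop_mod
from . import soil as soil_mod
from .calibrate import ResponseCurve
from .crop import CropParams, SeasonResult, simulate_season
from .genotypes import get_genotype
from .salinity import ConversionConstants, ECMeasurementSeries, SalinityParams
from .soil import IrrigationEvent, Pond, SoilLayer, SoilProfile
from .stats import PairedSeries, evaluate

logger = logging.getLogger(__name__)

WEATHER_COLUMNS = ("date", "tmin", "tmax", "rad", "rain")


class ConfigError(ValueError):
    pass


def read_weather_csv(path) -> pd.DataFrame:
    """Read and validate a daily weather table.

    Requires columns date,tmin,tmax,rad,rain; consecutive calendar days
    (gaps are an error listing the missing dates); tmin <= tmax per row
    (violations are an error naming the date); non-negative radiation and
    rain.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing weather columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: unparseable date — {exc}") from exc
    for col in ("tmin", "tmax", "rad", "rain"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ConfigError(
                f"{path}: malformed {col} value at line {int(bad[0]) + 2}"
            )
        df[col] = vals
    # calendar continuity
    expected = pd.date_range(df["date"].iloc[0], df["date"].iloc[-1], freq="D")
    if len(expected) != len(df) or (df["date"].to_numpy() != expected.to_numpy()).any():
        gaps = expected.difference(pd.DatetimeIndex(df["date"]))
        raise ConfigError(
            f"{path}: weather table has calendar gaps: "
            f"{[d.date().isoformat() for d in gaps[:5]]}"
        )
    bad = df[df["tmin"] > df["tmax"]]
    if len(bad):
        d = bad["date"].iloc[0].date().isoformat()
        raise ConfigError(f"{path}: tmin > tmax on {d}")
    if (df["rad"] < 0).any() or (df["rain"] < 0).any():
        raise ConfigError(f"{path}: negative radiation or rain")
    return df.reset_index(drop=True)


def write_weather_csv(df: pd.DataFrame, path) -> None:
    out = df.loc[:, list(WEATHER_COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_ec_csv(path, origin=None) -> ECMeasurementSeries:
    """Read sparse EC measurements (columns date,ec_dsm) into day indices.

    Day 0 is ``origin`` (the transplanting date) when given, else the first
    measurement date.
    """
    df = pd.read_csv(path)
    for col in ("date", "ec_dsm"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    dates = pd.to_datetime(df["date"], format="ISO8601")
    origin = dates.iloc[0] if origin is None else pd.Timestamp(origin)
    days = (dates - origin).dt.days
    return ECMeasurementSeries(tuple(int(d) for d in days), tuple(df["ec_dsm"]))


def write_ec_csv(days, ec, path, origin) -> None:
    origin = pd.Timestamp(origin)
    dates = [origin + pd.Timedelta(days=int(d)) for d in days]
    pd.DataFrame(
        {"date": [d.strftime("%Y-%m-%d") for d in dates], "ec_dsm": ec}
    ).to_csv(path, index=False)


def read_irrigation_csv(path) -> list:
    """Irrigation schedule: columns day,depth_mm,ec_dsm."""
    df = pd.read_csv(path)
    for col in ("day", "depth_mm", "ec_dsm"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    return [
        IrrigationEvent(day=int(r.day), depth_mm=float(r.depth_mm), ec_dsm=float(r.ec_dsm))
        for r in df.itertuples(index=False)
    ]


def write_irrigation_csv(events, path) -> None:
    pd.DataFrame(
        [dict(day=e.day, depth_mm=e.depth_mm, ec_dsm=e.ec_dsm) for e in events]
    ).to_csv(path, index=False)


def read_response_csv(path) -> dict:
    """Greenhouse response curves: columns ec_dsm,rate,process.

    Returns {process: ResponseCurve}.
    """
    df = pd.read_csv(path)
    for col in ("ec_dsm", "rate", "process"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    curves = {}
    for process, sub in df.groupby("process"):
        curves[str(process)] = ResponseCurve(
            tuple(sub["ec_dsm"]), tuple(sub["rate"]), str(process)
        )
    return curves


# ---------------------------------------------------------------------------
# run configuration

_TOP_KEYS = {
    "site",
    "transplant_date",
    "mode",
    "genotype",
    "season_days",
    "seed",
    "weather",
    "ec_series",
    "irrigation",
    "soil",
    "pond",
    "crop",
    "salinity",
    "constants",
    "normalize_fs",
    "auto_flood_depth_mm",
    "max_ec_manager",
    "output_dir",
}
_SOIL_KEYS = {
    "n_layers",
    "thickness_mm",
    "theta_sat",
    "theta_fc",
    "theta_wp",
    "theta_init",
    "chloride_kg_ha",
}
_POND_KEYS = {"depth_mm", "bund_height_mm", "percolation_mm_d"}
_CONSTANTS_KEYS = {"osmotic_kpa_per_dsm", "chloride_ppm_per_dsm"}
_SALINITY_KEYS = {"a_pn", "b_pn", "a_tr", "b_tr"}
_CROP_KEYS = set(CropParams.__dataclass_fields__)


@dataclass
class RunConfig:
    """Fully resolved simulation run configuration."""

    site: str = "synthetic-tropical"
    transplant_date: str = "2012-01-15"
    mode: str = "measured"
    genotype: str = "IR64"
    season_days: int = 150
    seed: int = 0
    weather: str | None = None
    ec_series: str | None = None
    irrigation: str | None = None
    soil: SoilProfile = field(default_factory=soil_mod.default_profile)
    pond: Pond = field(default_factory=soil_mod.default_pond)
    crop: CropParams = field(default_factory=CropParams)
    salinity: SalinityParams | None = None
    constants: ConversionConstants = field(default_factory=ConversionConstants)
    normalize_fs: bool = False
    auto_flood_depth_mm: float = 30.0
    max_ec_manager: float | None = None
    output_dir: str = "out"

    def resolved_salinity(self) -> SalinityParams:
        return self.salinity if self.salinity is not None else get_genotype(self.genotype)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def read_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys anywhere are rejected by name; referenced files must
    exist; the resolved configuration is logged.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    cfg = RunConfig()
    for key in ("site", "transplant_date", "mode", "genotype", "season_days",
                "seed", "normalize_fs", "auto_flood_depth_mm", "max_ec_manager",
                "output_dir"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if cfg.mode not in ("measured", "simulated"):
        raise ConfigError(f"mode must be 'measured' or 'simulated', got {cfg.mode!r}")

    for key in ("weather", "ec_series", "irrigation"):
        if raw.get(key) is not None:
            p = (path.parent / raw[key]).resolve()
            if not p.exists():
                raise ConfigError(f"referenced file does not exist: {p}")
            setattr(cfg, key, str(p))

    if "soil" in raw:
        _check_keys(raw["soil"], _SOIL_KEYS, "soil")
        cfg.soil = soil_mod.default_profile(**raw["soil"])
    if "pond" in raw:
        _check_keys(raw["pond"], _POND_KEYS, "pond")
        cfg.pond = soil_mod.default_pond(**raw["pond"])
    if "crop" in raw:
        _check_keys(raw["crop"], _CROP_KEYS, "crop")
        cfg.crop = CropParams(**raw["crop"])
    if "salinity" in raw:
        _check_keys(raw["salinity"], _SALINITY_KEYS, "salinity")
        cfg.salinity = SalinityParams(genotype=cfg.genotype, **raw["salinity"])
    if "constants" in raw:
        _check_keys(raw["constants"], _CONSTANTS_KEYS, "constants")
        cfg.constants = ConversionConstants(**raw["constants"])

    logger.info("resolved run config: %s", cfg)
    return cfg


def run_from_config(cfg: RunConfig) -> SeasonResult:
    """Build all simulation inputs from a config and run the season."""
    from .synth import TROPICAL, generate_weather

    if cfg.weather is not None:
        weather = read_weather_csv(cfg.weather)
        start = pd.Timestamp(cfg.transplant_date)
        weather = weather[weather["date"] >= start].reset_index(drop=True)
    else:
        weather = generate_weather(TROPICAL, n_years=1, seed=cfg.seed,
                                   start=cfg.transplant_date)
    weather = weather.iloc[: cfg.season_days]

    ec_series = None
    if cfg.ec_series is not None:
        ec_series = read_ec_csv(cfg.ec_series, origin=cfg.transplant_date)
    elif cfg.mode == "measured":
        ec_series = ECMeasurementSeries((0,), (0.0,))  # fresh-water default

    schedule = read_irrigation_csv(cfg.irrigation) if cfg.irrigation else None
    if cfg.mode == "simulated" and schedule is None:
        raise ConfigError("simulated-EC mode requires an irrigation schedule")

    return simulate_season(
        weather,
        cfg.soil,
        cfg.pond,
        cfg.crop,
        cfg.resolved_salinity(),
        mode=cfg.mode,
        ec_series=ec_series,
        schedule=schedule,
        constants=cfg.constants,
        normalize_fs=cfg.normalize_fs,
        auto_flood_depth_mm=cfg.auto_flood_depth_mm,
        max_ec_manager=cfg.max_ec_manager,
    )


def write_results(result: SeasonResult, outdir, obs: pd.DataFrame | None = None):
    """Write daily trajectories, a summary, and (optionally) an evaluation.

    Deterministic content: two runs with identical inputs produce
    byte-identical files.  Returns the list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    daily_path = outdir / "daily.csv"
    result.daily.to_csv(daily_path, index=False, float_format="%.6g")
    written.append(daily_path)

    summary = pd.DataFrame(
        [
            dict(
                genotype=result.genotype,
                yield_kg_ha=result.yield_kg_ha,
                final_wagt_kg_ha=result.final_wagt,
                total_transpiration_mm=result.total_transpiration_mm,
                maturity_day=result.maturity_day,
            )
        ]
    )
    summary_path = outdir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.6g")
    written.append(summary_path)

    if obs is not None:
        report_path = outdir / "evaluation.csv"
        rows = []
        daily = result.daily.set_index("day")
        for variable, sub in obs.groupby("variable"):
            col = {"wagt": "wagt", "lai": "lai", "yield": "wso"}.get(str(variable))
            if col is None or len(sub) < 3:
                continue
            sim = tuple(float(daily.loc[int(d), col]) for d in sub["day"])
            rep = evaluate(PairedSeries(sim, tuple(sub["value"])))
            rows.append(
                dict(
                    variable=variable,
                    n=rep.n,
                    p_t=rep.p_welch,
                    beta=rep.intercept,
                    alpha=rep.slope,
                    r2=rep.r2,
                    rmse=rep.rmse,
                    rmse_n_pct=rep.rmse_n_pct,
                    id=rep.willmott_id,
                )
            )
        pd.DataFrame(rows).to_csv(report_path, index=False, float_format="%.6g")
        written.append(report_path)
    return written


def file_digest(path) -> str:
    """SHA-256 of a file, for run-provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
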