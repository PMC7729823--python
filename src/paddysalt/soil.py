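"""Tipping-bucket soil water balance with a ponded layer and chloride transport.

The profile is a stack of fully-mixed layers.  Water added at the surface
fills the pond up to the bund height (excess runs off), the pond percolates
into the top layer at a fixed design rate (puddled-paddy behaviour), and
each layer spills water above field capacity to the layer below on the same
day; spill from the bottom layer leaves the profile as drainage.
Evaporation is taken from the pond first, then from the top layer;
transpiration is extracted over the root zone in proportion to
plant-available water (above wilting point).

Chloride moves advectively with every water flux at the concentration of the
fully-mixed source compartment: pond -> layer 1 with percolation, layer i ->
layer i+1 with inter-layer spill, out of the profile with drainage, over the
bund with runoff (at the mixed pond concentration), and into the plant with
the transpiration stream.  Only evaporation carries no salt, so it
concentrates the remaining solution.  Both the water and the chloride ledger
are closed every step and a violation raises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .salinity import (
    ConversionConstants,
    DEFAULT_CONSTANTS,
    ec_from_chloride,
    layer_chloride_conc,
)

logger = logging.getLogger(__name__)

WATER_TOL = 1e-6  # mm
SALT_TOL = 1e-9  # kg/ha


class SoilError(ValueError):
    """Invalid soil state or flux."""


@dataclass
class SoilLayer:
    """One fully-mixed soil layer.

    Water contents are volumetric (m3/m3); chloride is a mass (kg/ha)
    dissolved in the layer's water.  ``air_entry_kpa`` and ``shape`` are the
    Campbell retention-curve parameters used for matric tension.
    """

    thickness_mm: float
    theta_sat: float
    theta_fc: float
    theta_wp: float
    theta: float
    chloride_kg_ha: float = 0.0
    air_entry_kpa: float = 0.1
    shape: float = 5.0

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise SoilError("layer thickness must be positive")
        if not (0 < self.theta_wp < self.theta_fc < self.theta_sat <= 1.0):
            raise SoilError(
                "need 0 < wilting point < field capacity < saturation <= 1, got "
                f"wp={self.theta_wp}, fc={self.theta_fc}, sat={self.theta_sat}"
            )
        if not (0 <= self.theta <= self.theta_sat + 1e-12):
            raise SoilError(f"water content {self.theta} outside [0, sat]")
        if self.chloride_kg_ha < 0:
            raise SoilError("layer chloride must be non-negative")

    @property
    def water_mm(self) -> float:
        return self.theta * self.thickness_mm

    @water_mm.setter
    def water_mm(self, value: float) -> None:
        self.theta = value / self.thickness_mm

    @property
    def fc_mm(self) -> float:
        return self.theta_fc * self.thickness_mm

    @property
    def wp_mm(self) -> float:
        return self.theta_wp * self.thickness_mm

    @property
    def sat_mm(self) -> float:
        return self.theta_sat * self.thickness_mm


@dataclass
class SoilProfile:
    """Ordered stack of soil layers, top first."""

    layers: list

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise SoilError("soil profile needs at least one layer")

    @property
    def depth_mm(self) -> float:
        return sum(l.thickness_mm for l in self.layers)

    @property
    def total_water_mm(self) -> float:
        return sum(l.water_mm for l in self.layers)

    @property
    def total_chloride_kg_ha(self) -> float:
        return sum(l.chloride_kg_ha for l in self.layers)

    def copy(self) -> "SoilProfile":
        return SoilProfile([replace(l) for l in self.layers])


@dataclass
class Pond:
    """Ponded surface water held between the soil surface and the bund."""

    depth_mm: float = 0.0
    chloride_kg_ha: float = 0.0
    bund_height_mm: float = 100.0
    percolation_mm_d: float = 5.0

    def __post_init__(self) -> None:
        if self.depth_mm < 0 or self.chloride_kg_ha < 0:
            raise SoilError("pond depth and chloride must be non-negative")
        if self.bund_height_mm < 0 or self.percolation_mm_d < 0:
            raise SoilError("bund height and percolation rate must be non-negative")

    def copy(self) -> "Pond":
        return replace(self)


@dataclass(frozen=True)
class IrrigationEvent:
    """One irrigation application: day index, depth and water salinity."""

    day: int
    depth_mm: float
    ec_dsm: float

    def __post_init__(self) -> None:
        if self.depth_mm < 0 or self.ec_dsm < 0:
            raise SoilError("irrigation depth and EC must be non-negative")


def irrigation_salt_load(
    event: IrrigationEvent, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> float:
    """Chloride mass (kg/ha) applied by one irrigation event.

    The irrigation water's chloride concentration is taken as
    ``divisor * EC_iw`` ppm — the exact inverse of the chloride-to-EC
    conversion — so a soil solution flushed with water at EC_iw settles at
    EC_iw.  Mass follows from ``ppm * depth / 100`` (1 ppm in 1 mm over
    1 ha = 0.01 kg).
    """
    conc_ppm = constants.chloride_ppm_per_dsm * event.ec_dsm
    return conc_ppm * event.depth_mm / 100.0


@dataclass
class WaterFluxes:
    """Daily water fluxes (all mm), with the mixing bases salt needs.

    ``pond_water_pre_perc`` and the per-layer ``water_pre_*`` arrays record
    the source-compartment water at the moment each flux left it, which is
    the denominator for fully-mixed advective chloride transport.
    """

    rain: float
    irrigation: float
    runoff: float
    pond_water_pre_runoff: float
    percolation: float
    pond_water_pre_perc: float
    layer_inflow: np.ndarray
    layer_outflow: np.ndarray
    water_pre_outflow: np.ndarray
    drainage: float
    evap_pond: float
    evap_soil: float
    transp_by_layer: np.ndarray
    water_pre_transp: np.ndarray
    transpiration: float

    @property
    def evaporation(self) -> float:
        return self.evap_pond + self.evap_soil


def step_water(
    profile: SoilProfile,
    pond: Pond,
    rain_mm: float,
    irrigation_mm: float,
    pot_evap_mm: float,
    transp_demand_mm: float,
    root_depth_mm: float | None = None,
) -> WaterFluxes:
    """Advance the water balance one day, mutating profile and pond.

    Returns the day's fluxes.  Raises if the internal ledger
    (storage change = inflows - outflows) fails to close to 1e-6 mm.
    """
    for name, v in (
        ("rain", rain_mm),
        ("irrigation", irrigation_mm),
        ("potential evaporation", pot_evap_mm),
        ("transpiration demand", transp_demand_mm),
    ):
        if v < 0:
            raise SoilError(f"{name} must be non-negative, got {v}")

    layers = profile.layers
    n = len(layers)
    storage0 = pond.depth_mm + profile.total_water_mm

    # surface additions fill the pond; excess above the bund runs off
    pond.depth_mm += rain_mm + irrigation_mm
    pond_water_pre_runoff = pond.depth_mm
    runoff = max(0.0, pond.depth_mm - pond.bund_height_mm)
    pond.depth_mm -= runoff

    # pond percolates into layer 1 at the design rate
    pond_water_pre_perc = pond.depth_mm
    percolation = min(pond.depth_mm, pond.percolation_mm_d)
    pond.depth_mm -= percolation

    # tipping-bucket cascade: spill above field capacity, top to bottom
    layer_inflow = np.zeros(n)
    layer_outflow = np.zeros(n)
    water_pre_outflow = np.zeros(n)
    inflow = percolation
    for i, layer in enumerate(layers):
        layer_inflow[i] = inflow
        w = layer.water_mm + inflow
        water_pre_outflow[i] = w
        out = max(0.0, w - layer.fc_mm)
        # never hold more than saturation even transiently
        layer.water_mm = min(w - out, layer.sat_mm)
        out = w - layer.water_mm
        layer_outflow[i] = out
        inflow = out
    drainage = inflow

    # evaporation: pond first, then the top layer down to wilting point
    evap_pond = min(pond.depth_mm, pot_evap_mm)
    pond.depth_mm -= evap_pond
    remaining = pot_evap_mm - evap_pond
    top = layers[0]
    evap_soil = min(remaining, max(0.0, top.water_mm - top.wp_mm))
    top.water_mm = top.water_mm - evap_soil

    # transpiration over the root zone, proportional to available water
    if root_depth_mm is None:
        root_depth_mm = profile.depth_mm
    if root_depth_mm <= 0:
        raise SoilError("root depth must be positive")
    frac = _root_fractions(profile, root_depth_mm)
    water_pre_transp = np.array([l.water_mm for l in layers])
    avail = np.array(
        [max(0.0, l.water_mm - l.wp_mm) * f for l, f in zip(layers, frac)]
    )
    total_avail = float(avail.sum())
    transpiration = min(transp_demand_mm, total_avail)
    transp_by_layer = np.zeros(n)
    if transpiration > 0 and total_avail > 0:
        transp_by_layer = avail / total_avail * transpiration
        for layer, t in zip(layers, transp_by_layer):
            layer.water_mm = layer.water_mm - t

    storage1 = pond.depth_mm + profile.total_water_mm
    balance = (
        storage1
        - storage0
        - (rain_mm + irrigation_mm)
        + runoff
        + drainage
        + evap_pond
        + evap_soil
        + transpiration
    )
    if abs(balance) > WATER_TOL:
        raise SoilError(f"water ledger failed to close: residual {balance:.3e} mm")

    return WaterFluxes(
        rain=rain_mm,
        irrigation=irrigation_mm,
        runoff=runoff,
        pond_water_pre_runoff=pond_water_pre_runoff,
        percolation=percolation,
        pond_water_pre_perc=pond_water_pre_perc,
        layer_inflow=layer_inflow,
        layer_outflow=layer_outflow,
        water_pre_outflow=water_pre_outflow,
        drainage=drainage,
        evap_pond=evap_pond,
        evap_soil=evap_soil,
        transp_by_layer=transp_by_layer,
        water_pre_transp=water_pre_transp,
        transpiration=transpiration,
    )


@dataclass
class SaltFluxes:
    """Daily chloride fluxes (kg/ha)."""

    applied: float
    leached: float
    plant_uptake: float
    runoff: float


def step_salt(
    profile: SoilProfile,
    pond: Pond,
    salt_in_kg_ha: float,
    fluxes: WaterFluxes,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> SaltFluxes:
    """Move chloride with the day's water fluxes, mutating profile and pond.

    Must be called after :func:`step_water` with that call's fluxes.  Each
    flux carries chloride at the fully-mixed source concentration.  The
    ledger ``delta(storage) = salt_in - leached - uptake - runoff`` must
    close to 1e-9 kg/ha or the step raises.
    """
    if salt_in_kg_ha < 0:
        raise SoilError("applied salt must be non-negative")
    layers = profile.layers
    total0 = pond.chloride_kg_ha + profile.total_chloride_kg_ha

    pond.chloride_kg_ha += salt_in_kg_ha

    # overflow leaves at the mixed pond concentration
    runoff_salt = 0.0
    if fluxes.runoff > 0:
        if fluxes.runoff > fluxes.pond_water_pre_runoff + WATER_TOL:
            raise SoilError("runoff exceeds pond water — inconsistent fluxes")
        runoff_salt = (
            pond.chloride_kg_ha * fluxes.runoff / fluxes.pond_water_pre_runoff
        )
        pond.chloride_kg_ha -= runoff_salt

    # pond -> layer 1 with percolation
    moved = 0.0
    if fluxes.percolation > 0:
        if fluxes.percolation > fluxes.pond_water_pre_perc + WATER_TOL:
            raise SoilError("percolation exceeds pond water — inconsistent fluxes")
        moved = pond.chloride_kg_ha * fluxes.percolation / fluxes.pond_water_pre_perc
        pond.chloride_kg_ha -= moved

    # cascade top-down at the mixed concentration of (layer + inflow)
    inflow_salt = moved
    leached = 0.0
    for i, layer in enumerate(layers):
        layer.chloride_kg_ha += inflow_salt
        out_w = fluxes.layer_outflow[i]
        inflow_salt = 0.0
        if out_w > 0:
            basis = fluxes.water_pre_outflow[i]
            if out_w > basis + WATER_TOL:
                raise SoilError("layer outflow exceeds its water — inconsistent fluxes")
            inflow_salt = layer.chloride_kg_ha * out_w / basis
            layer.chloride_kg_ha -= inflow_salt
    leached = inflow_salt

    # pond dried out: remaining salt crusts onto the top layer
    if pond.depth_mm <= 0 and pond.chloride_kg_ha > 0:
        layers[0].chloride_kg_ha += pond.chloride_kg_ha
        pond.chloride_kg_ha = 0.0

    # transpiration stream carries solute at the layer concentration
    uptake = 0.0
    for i, layer in enumerate(layers):
        t = fluxes.transp_by_layer[i]
        if t > 0:
            basis = fluxes.water_pre_transp[i]
            if t > basis + WATER_TOL:
                raise SoilError("transpiration exceeds layer water")
            u = layer.chloride_kg_ha * t / basis
            layer.chloride_kg_ha -= u
            uptake += u

    total1 = pond.chloride_kg_ha + profile.total_chloride_kg_ha
    residual = total1 - total0 - salt_in_kg_ha + leached + uptake + runoff_salt
    if abs(residual) > SALT_TOL * max(1.0, total0 + salt_in_kg_ha):
        raise SoilError(f"chloride ledger failed to close: residual {residual:.3e}")

    return SaltFluxes(
        applied=salt_in_kg_ha,
        leached=leached,
        plant_uptake=uptake,
        runoff=runoff_salt,
    )


def matric_tension(layer: SoilLayer, ponded: bool = False) -> float:
    """Matric tension (kPa) of a layer from the Campbell retention form.

    Zero when ponded water stands above the profile or the layer is
    saturated; otherwise ``tau = tau_e * (theta / theta_sat) ** (-shape)``,
    monotone decreasing in water content.
    """
    if layer.theta <= 0:
        raise SoilError("matric tension undefined for a dry layer (theta <= 0)")
    if ponded or layer.theta >= layer.theta_sat:
        return 0.0
    return layer.air_entry_kpa * (layer.theta / layer.theta_sat) ** (-layer.shape)


def _root_fractions(profile: SoilProfile, root_depth_mm: float) -> np.ndarray:
    """Fraction of each layer's thickness intersected by the root zone."""
    frac = np.zeros(len(profile.layers))
    top = 0.0
    for i, layer in enumerate(profile.layers):
        bottom = top + layer.thickness_mm
        overlap = max(0.0, min(bottom, root_depth_mm) - top)
        frac[i] = overlap / layer.thickness_mm
        top = bottom
    return frac


def root_zone_ec(
    profile: SoilProfile,
    root_depth_mm: float,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Root-zone soil solution EC (dS/m).

    Thickness-weighted mean of the layer solution chloride concentrations
    over the layers intersected by the root zone, converted to EC.  A root
    depth beyond the profile is clamped (with a warning) to the profile
    depth.
    """
    if root_depth_mm <= 0:
        raise SoilError("root depth must be positive")
    if root_depth_mm > profile.depth_mm:
        logger.warning(
            "root depth %.0f mm exceeds profile depth %.0f mm; clamping",
            root_depth_mm,
            profile.depth_mm,
        )
        root_depth_mm = profile.depth_mm
    frac = _root_fractions(profile, root_depth_mm)
    weights = np.array([l.thickness_mm for l in profile.layers]) * frac
    concs = np.array(
        [
            layer_chloride_conc(l.chloride_kg_ha, l.water_mm) if w > 0 else 0.0
            for l, w in zip(profile.layers, weights)
        ]
    )
    mean_ppm = float((weights * concs).sum() / weights.sum())
    return ec_from_chloride(mean_ppm, constants)


def default_profile(
    n_layers: int = 4,
    thickness_mm: float = 200.0,
    theta_sat: float = 0.50,
    theta_fc: float = 0.35,
    theta_wp: float = 0.15,
    theta_init: float | None = None,
    chloride_kg_ha: float = 0.0,
) -> SoilProfile:
    """A generic puddled-paddy profile: 4 x 200 mm clay-loam layers at
    field capacity, salt-free unless stated."""
    theta_init = theta_fc if theta_init is None else theta_init
    per_layer_cl = chloride_kg_ha / n_layers
    return SoilProfile(
        [
            SoilLayer(
                thickness_mm=thickness_mm,
                theta_sat=theta_sat,
                theta_fc=theta_fc,
                theta_wp=theta_wp,
                theta=theta_init,
                chloride_kg_ha=per_layer_cl,
            )
            for _ in range(n_layers)
        ]
    )


def default_pond(
    depth_mm: float = 30.0,
    bund_height_mm: float = 100.0,
    percolation_mm_d: float = 5.0,
) -> Pond:
    """A ponded paddy surface with a 100 mm bund and 5 mm/d design
    percolation (typical puddled soil)."""
    return Pond(
        depth_mm=depth_mm,
        chloride_kg_ha=0.0,
        bund_height_mm=bund_height_mm,
        percolation_mm_d=percolation_mm_d,
    )
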