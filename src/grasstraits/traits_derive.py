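"""Derivation of leaf and stem functional traits from raw measurements.

Covers the hydraulic conductance/conductivity calculations from
pressure-chamber flow measurements, simple mass/area ratios (SLA, LDMC,
stem density, intrinsic water-use efficiency), anatomical maximum stomatal
conductance from stomatal density and guard-cell geometry, turgor-loss
point from pressure-volume curves, and the log/absolute-value transform
applied to traits before comparative analysis.

Units follow the trait table conventions: masses enter in mg (flow
collections) or g (tissue masses), areas in m2 for conductances, lengths
in m, pressures in MPa; derived values carry the units stated per
function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlowMeasurement",
    "StomatalSurface",
    "PVCurve",
    "StomatalGeometry",
    "TraitTable",
    "k_leaf",
    "k_stem",
    "simple_ratios",
    "g_wmax",
    "turgor_loss_point",
    "prepare_traits",
    "generate_pv_curve",
    "NEGATIVE_TRAITS",
]

WATER_MOLAR_MASS = 18.015  # g/mol

# traits stored as negative numbers; |.| is taken before the log transform
NEGATIVE_TRAITS = ("Psi_tlp", "Psi_pre", "Psi_mid", "d13C")


@dataclass
class FlowMeasurement:
    """Paired flow collections at two balancing pressures.

    ``dW1``/``dW2`` are solution masses (mg) collected over ``interval``
    seconds at chamber pressures ``psi1`` < ``psi2`` (MPa).  ``area`` (m2,
    leaf) or ``length`` (m, stem segment) normalizes the flow.
    """

    dW1: float
    dW2: float
    interval: float
    psi1: float
    psi2: float
    area: float | None = None
    length: float | None = None

    def __post_init__(self):
        if self.psi2 <= self.psi1:
            raise ValueError(f"psi2 ({self.psi2}) must exceed psi1 ({self.psi1})")
        if self.interval <= 0:
            raise ValueError("collection interval must be positive")


@dataclass
class StomatalSurface:
    """Stomatal measurements for one leaf surface.

    ``gl``/``gw`` are guard-cell length and width (um); ``std`` is stomatal
    density (per mm2).  Hypostomatous leaves have adaxial std = 0.
    """

    gl: float
    gw: float
    std: float
    surface: str = "abaxial"

    def __post_init__(self):
        if min(self.gl, self.gw, self.std) < 0:
            raise ValueError("stomatal measurements must be nonnegative")


@dataclass
class StomatalGeometry:
    """Geometry rule and physical constants for anatomical g_wmax.

    Defaults: pore length = gl/2, pore depth = gw/2, maximum pore area
    a_max = pi (pore length / 2)^2; water-vapour diffusivity and molar air
    volume at 25 C.  All four are configurable so alternative published
    geometries can be matched exactly.
    """

    diffusivity: float = 2.49e-5       # m2 s-1
    molar_volume: float = 2.24e-2      # m3 mol-1
    pore_length_frac: float = 0.5      # pore length as fraction of gl
    pore_depth_frac: float = 0.5       # pore depth as fraction of gw


@dataclass
class PVCurve:
    """A leaf pressure-volume curve: paired (psi_leaf MPa, RWC) points."""

    psi: np.ndarray
    rwc: np.ndarray

    def __post_init__(self):
        self.psi = np.asarray(self.psi, float)
        self.rwc = np.asarray(self.rwc, float)
        if self.psi.shape != self.rwc.shape:
            raise ValueError("psi and rwc must have the same length")
        if np.any(self.psi >= 0):
            raise ValueError("leaf water potentials must be negative")
        if np.any((self.rwc <= 0) | (self.rwc > 1)):
            raise ValueError("RWC must lie in (0, 1]")


@dataclass
class TraitTable:
    """Species x trait values plus per-trait metadata.

    ``meta`` carries one row per trait with columns ``class``
    (structural/physiological) and ``negative`` (stored as negative values,
    |.| before log).
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def subset(self, trait_class: str) -> pd.DataFrame:
        keep = self.meta.index[self.meta["class"] == trait_class]
        return self.data[list(keep)]


def k_leaf(m: FlowMeasurement) -> float:
    """Leaf hydraulic conductance, mmol m-2 s-1 MPa-1.

    (dW2 - dW1) / [leaf area x time x (psi2 - psi1)], with collected masses
    converted from mg to mmol of water (18.015 mg/mmol).
    """
    if m.area is None or m.area <= 0:
        raise ValueError("k_leaf needs a positive leaf area (m2)")
    dflow = m.dW2 - m.dW1
    if dflow < 0:
        warnings.warn("negative flow difference (dW2 < dW1); passing through")
    mmol = dflow / WATER_MOLAR_MASS
    return mmol / (m.area * m.interval * (m.psi2 - m.psi1))


def k_stem(m: FlowMeasurement, A_SV: float, A_L: float) -> tuple[float, float, float]:
    """Stem hydraulic conductivity and its normalizations.

    K_h = (dW2 - dW1) x stem length / [time x (psi2 - psi1)] in
    kg m s-1 MPa-1 (flow masses mg -> kg); K_S = K_h / A_SV (vessel area,
    m2) and K_L = K_h / A_L (distal leaf area, m2).
    """
    if m.length is None or m.length <= 0:
        raise ValueError("k_stem needs a positive segment length (m)")
    if A_SV <= 0 or A_L <= 0:
        raise ValueError("A_SV and A_L must be positive")
    kg = (m.dW2 - m.dW1) * 1e-6
    K_h = kg * m.length / (m.interval * (m.psi2 - m.psi1))
    return K_h, K_h / A_SV, K_h / A_L


def simple_ratios(
    *,
    leaf_area: float | None = None,
    leaf_dry_mass: float | None = None,
    leaf_saturated_mass: float | None = None,
    stem_dry_mass: float | None = None,
    stem_volume: float | None = None,
    stem_area: float | None = None,
    A: float | None = None,
    g_s: float | None = None,
) -> dict[str, float]:
    """The ratio traits; only those whose inputs are supplied are returned.

    SLA = leaf area / leaf dry mass; SD = stem dry mass / volume;
    LDMC = dry / saturated mass; A_L/A_S = leaf area / stem cross-section
    area; WUE_i = A / g_s.  Units are the caller's (e.g. cm2 and g give
    SLA in cm2 g-1).
    """
    out: dict[str, float] = {}

    def ratio(name, num, den, den_name):
        if num is None or den is None:
            return
        if den == 0:
            raise ZeroDivisionError(f"{name}: zero {den_name}")
        out[name] = num / den

    ratio("SLA", leaf_area, leaf_dry_mass, "leaf dry mass")
    ratio("SD", stem_dry_mass, stem_volume, "stem volume")
    ratio("LDMC", leaf_dry_mass, leaf_saturated_mass, "saturated mass")
    ratio("AL_AS", leaf_area, stem_area, "stem cross-section area")
    ratio("WUE_i", A, g_s, "stomatal conductance")
    return out


def _surface_conductance(s: StomatalSurface, geom: StomatalGeometry) -> float:
    if s.std == 0:
        return 0.0
    std_m2 = s.std * 1e6                      # mm-2 -> m-2
    pore_length = s.gl * 1e-6 * geom.pore_length_frac
    pore_depth = s.gw * 1e-6 * geom.pore_depth_frac
    a_max = math.pi * (pore_length / 2.0) ** 2
    denom = pore_depth + (math.pi / 2.0) * math.sqrt(a_max / math.pi)
    return (geom.diffusivity / geom.molar_volume) * std_m2 * a_max / denom


def g_wmax(abaxial: StomatalSurface, adaxial: StomatalSurface | None = None,
           geom: StomatalGeometry | None = None) -> float:
    """Anatomical maximum stomatal conductance to water, mol m-2 s-1.

    Per surface g = (d / v) std a_max / (pore depth + (pi/2) sqrt(a_max/pi));
    both surfaces sum.  Hypostomatous leaves pass ``adaxial=None`` or an
    adaxial surface with std = 0.
    """
    geom = geom or StomatalGeometry()
    total = _surface_conductance(abaxial, geom)
    if adaxial is not None:
        total += _surface_conductance(adaxial, geom)
    return total


def turgor_loss_point(curve: PVCurve) -> float:
    """Water potential at the turgor-loss point (MPa) from a PV curve.

    Classic two-segment analysis of 1/psi against (1 - RWC): beyond turgor
    loss the relationship is linear (psi is purely osmotic); the breakpoint
    between the curved turgid segment and the linear dry segment is found
    by minimizing total squared error over all splits with >= 3 points per
    segment.  The dry segment must be convincingly linear (R2 >= 0.95).
    Because the turgid segment is curved globally but the transition is a
    local kink, the kink abscissa is located by intersecting the dry line
    with a line through the three turgid points nearest the split, and
    psi_tlp is the dry (osmotic) line evaluated there.
    """
    if curve.psi.size < 6:
        raise ValueError(f"need >= 6 PV points, got {curve.psi.size}")
    order = np.argsort(1.0 - curve.rwc)       # increasing water deficit
    x = (1.0 - curve.rwc)[order]
    yinv = (1.0 / curve.psi)[order]
    psi = curve.psi[order]
    n = x.size

    def linfit(xs, ys):
        A = np.column_stack([np.ones_like(xs), xs])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        resid = ys - A @ coef
        sse = float(resid @ resid)
        tss = float(np.sum((ys - ys.mean()) ** 2))
        r2 = 1.0 - sse / tss if tss > 0 else 1.0
        return coef, sse, r2

    best = None
    for b in range(3, n - 2):                 # wet: [0, b), dry: [b, n)
        _, sse_w, _ = linfit(x[:b], yinv[:b])
        cd, sse_d, r2_d = linfit(x[b:], yinv[b:])
        if r2_d < 0.95:
            continue
        tot = sse_w + sse_d
        if best is None or tot < best[0] - 1e-15:
            best = (tot, b, cd)
    if best is None:
        raise RuntimeError("no admissible breakpoint: dry segment never linear (R2 >= 0.95)")
    _, b, cd = best
    # degenerate: the two segments are one line -> no turgor anywhere
    _, _, r2_all = linfit(x, yinv)
    if r2_all > 0.999:
        raise RuntimeError("PV points collinear in 1/psi vs (1 - RWC): no turgor-loss point")
    # kink abscissa from the local wet line vs the dry line, clamped near
    # the split; psi_tlp is osmotic (the dry line) at the kink
    cw, _, _ = linfit(x[b - 3:b], yinv[b - 3:b])
    denom = cw[1] - cd[1]
    x_star = (cd[0] - cw[0]) / denom if abs(denom) > 1e-12 else 0.5 * (x[b - 1] + x[b])
    x_star = float(np.clip(x_star, x[b - 3], x[b]))
    return float(1.0 / (cd[0] + cd[1] * x_star))


def generate_pv_curve(
    pi0: float = -1.5,
    apoplastic_fraction: float = 0.2,
    rwc_tlp: float = 0.9,
    n_points: int = 14,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[PVCurve, float]:
    """Synthetic PV curve from the classic osmotic + linear-turgor model.

    Osmotic potential follows pi(R) = pi0 (1 - af) / (R - af) with
    apoplastic fraction ``af``; turgor declines linearly from -pi0 at full
    hydration to zero at ``rwc_tlp``.  Returns the curve and the analytic
    turgor-loss point pi(rwc_tlp) for recovery checks.  Gaussian noise
    (``noise_sd`` MPa) perturbs psi only.
    """
    af = apoplastic_fraction
    if not (0 <= af < rwc_tlp < 1):
        raise ValueError("need 0 <= apoplastic fraction < rwc_tlp < 1")
    rng = rng or np.random.default_rng(0)
    # bench-drying sampling: start near full turgor and dry well past the
    # turgor-loss point so the osmotic segment is resolved
    rwc = np.linspace(0.98, max(af + 0.1, rwc_tlp - 0.2), n_points)
    osmotic = pi0 * (1 - af) / (rwc - af)
    turgor = np.where(rwc > rwc_tlp, -pi0 * (rwc - rwc_tlp) / (1 - rwc_tlp), 0.0)
    psi = osmotic + turgor
    if noise_sd > 0:
        psi = psi + rng.normal(0.0, noise_sd, size=psi.shape)
        psi = np.minimum(psi, -1e-3)
    tlp_true = pi0 * (1 - af) / (rwc_tlp - af)
    return PVCurve(psi, rwc), float(tlp_true)


def prepare_traits(table: TraitTable) -> TraitTable:
    """Natural-log transform of every analysed trait column.

    Traits listed as ``negative`` in the metadata (water potentials, d13C)
    take absolute values first; a column flagged negative must be strictly
    negative throughout, and no transformed value may be zero.  Metadata is
    preserved; missing values pass through as missing.
    """
    data = table.data.copy()
    for trait in data.columns:
        col = data[trait]
        vals = col.dropna()
        negative = bool(table.meta.loc[trait, "negative"]) if trait in table.meta.index else False
        if negative:
            bad = vals.index[vals >= 0]
            if len(bad):
                raise ValueError(
                    f"trait {trait} flagged negative has nonnegative values for species {list(bad)}"
                )
            col = -col
            vals = -vals
        if (vals <= 0).any():
            bad = list(vals.index[vals <= 0])
            raise ValueError(f"trait {trait}: nonpositive values for species {bad} cannot be logged")
        data[trait] = np.log(col)
    return TraitTable(data, table.meta.copy())
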