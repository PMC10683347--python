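"""Chromatography math: loads, standard-curve titers, breakthrough curves
and dynamic binding capacity (DBC) at a set breakthrough threshold.

A breakthrough experiment loads clarified harvest at titer C0 (mg/mL) onto
a protein A column of bed volume V_c (mL); flowthrough fractions are
collected and their titer C measured. The breakthrough ratio C/C0 versus
cumulative loaded volume crosses 10% at volume V_10%, and

    DBC_10% = (V_10% - V_0) * C0 / V_c

with V_0 the system offset/delay volume. The breakthrough ratio is attached
to the fraction midpoint volume (unbiased for linear segments), and V_10%
is found by linear interpolation between adjacent midpoints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ChromatographyError",
    "StandardCurve",
    "FractionTable",
    "BreakthroughCurve",
    "ColumnSpec",
    "DBCResult",
    "oversaturation_load",
    "fit_standard_curve",
    "titer_from_peak_area",
    "titer_from_absorbance",
    "build_breakthrough",
    "find_v10",
    "dbc_10",
    "dbc_from_uv_chromatogram",
]

RATIO_FLAG_TOLERANCE = 0.05  # ratios above 1 + this are flagged as suspect


class ChromatographyError(ValueError):
    """Invalid chromatography input or an unsatisfiable breakthrough query."""


def oversaturation_load(v_inject: float, c0: float, v_column: float) -> float:
    """Oversaturation concentration C_S = V_I * C0 / V_c (mg per mL resin)."""
    if v_inject <= 0 or c0 <= 0 or v_column <= 0:
        raise ChromatographyError("all oversaturation-load inputs must be > 0")
    return v_inject * c0 / v_column


@dataclass(frozen=True)
class StandardCurve:
    """Linear peak-area calibration: area = m * mass + b.

    ``m`` in peak-area units per mg, ``b`` in peak-area units;
    ``residual_sd`` is the SD of the fit residuals (ddof = 2).
    """

    m: float
    b: float
    residual_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ChromatographyError("a standard curve needs at least 2 points")
        if self.m <= 0:
            raise ChromatographyError(
                f"standard-curve gradient must be > 0 for a valid assay, got {self.m}"
            )


def fit_standard_curve(masses, areas) -> StandardCurve:
    """Ordinary least squares line through (mass on column, peak area)."""
    x = np.asarray(masses, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ChromatographyError("masses and areas must be equal-length vectors")
    if x.size < 2:
        raise ChromatographyError("need at least 2 calibration points")
    if np.ptp(x) == 0:
        raise ChromatographyError("all calibration masses are identical")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    rsd = float(np.sqrt(np.sum(resid**2) / (x.size - 2))) if x.size > 2 else 0.0
    return StandardCurve(m=float(fit.slope), b=float(fit.intercept), residual_sd=rsd, n=int(x.size))


def titer_from_peak_area(curve: StandardCurve, peak_area: float, injection_mL: float) -> float:
    """Titer C0 = ((S_A - b) / m) / I_V; negative masses clip to 0 with a warning."""
    if injection_mL <= 0:
        raise ChromatographyError("injection volume must be > 0")
    mass = (peak_area - curve.b) / curve.m
    if mass < 0:
        warnings.warn(
            f"peak area {peak_area} below the curve intercept; titer clipped to 0",
            stacklevel=2,
        )
        mass = 0.0
    return mass / injection_mL


def titer_from_absorbance(a280, epsilon: float, path_cm: float):
    """Beer-Lambert titer c = A / (epsilon * l), epsilon in mL mg^-1 cm^-1."""
    if epsilon <= 0 or path_cm <= 0:
        raise ChromatographyError("extinction coefficient and path length must be > 0")
    a = np.asarray(a280, dtype=float)
    c = a / (epsilon * path_cm)
    return float(c) if c.ndim == 0 else c


@dataclass(frozen=True)
class FractionTable:
    """Contiguous flowthrough fractions with measured titers and load titer C0."""

    v_start: np.ndarray
    v_end: np.ndarray
    titer: np.ndarray
    c0: float

    def __post_init__(self) -> None:
        vs = np.asarray(self.v_start, dtype=float)
        ve = np.asarray(self.v_end, dtype=float)
        t = np.asarray(self.titer, dtype=float)
        if not (vs.shape == ve.shape == t.shape) or vs.ndim != 1 or vs.size == 0:
            raise ChromatographyError("fraction columns must be equal-length vectors")
        if np.any(ve <= vs):
            raise ChromatographyError("each fraction must have v_end > v_start")
        if vs.size > 1 and not np.allclose(ve[:-1], vs[1:]):
            raise ChromatographyError("fractions must be contiguous and non-overlapping")
        if np.any(np.diff(vs) <= 0):
            raise ChromatographyError("fraction volumes must be increasing")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ChromatographyError("titers must be finite and >= 0")
        object.__setattr__(self, "v_start", vs)
        object.__setattr__(self, "v_end", ve)
        object.__setattr__(self, "titer", t)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.v_start + self.v_end)

    @classmethod
    def from_titers(cls, titers, c0: float, fraction_mL: float = 2.0, v_offset: float = 0.0):
        """Build a table of equal ``fraction_mL`` fractions starting at ``v_offset``."""
        t = np.asarray(titers, dtype=float)
        vs = v_offset + fraction_mL * np.arange(t.size)
        return cls(vs, vs + fraction_mL, t, c0)


@dataclass(frozen=True)
class BreakthroughCurve:
    """Breakthrough ratio C/C0 at cumulative loaded volume (fraction midpoints)."""

    volumes: np.ndarray
    ratios: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        if v.shape != r.shape or v.ndim != 1 or v.size == 0:
            raise ChromatographyError("volumes and ratios must be equal-length vectors")
        if np.any(np.diff(v) <= 0):
            raise ChromatographyError("volumes must be strictly increasing")
        if np.any(r < -RATIO_FLAG_TOLERANCE):
            raise ChromatographyError("breakthrough ratios are substantially negative")
        flags = r > 1.0 + RATIO_FLAG_TOLERANCE
        r = np.clip(r, 0.0, None)  # small negative baseline noise clips to 0
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "flagged", flags)


def build_breakthrough(fractions: FractionTable) -> BreakthroughCurve:
    """Per-fraction ratio C/C0 attached to the fraction midpoint volume."""
    if fractions.c0 <= 0:
        raise ChromatographyError("load titer C0 must be > 0")
    ratios = fractions.titer / fractions.c0
    curve = BreakthroughCurve(fractions.midpoints, ratios)
    if curve.flagged.any():
        warnings.warn(
            f"{int(curve.flagged.sum())} fraction(s) exceed C/C0 = "
            f"{1 + RATIO_FLAG_TOLERANCE}: check C0",
            stacklevel=2,
        )
    return curve


def find_v10(
    curve: BreakthroughCurve, threshold: float = 0.10, crossing: str = "first"
) -> float:
    """Volume at the upward crossing of ``threshold`` (linear interpolation).

    With ``crossing="first"`` (default) the first upward crossing is used;
    a point exactly at the threshold returns that point's volume, and if
    the first point is already above the threshold the load started past
    breakthrough and no crossing volume can be located. With
    ``crossing="sustained"`` the last upward crossing is used instead — the
    boundary of the final exceedance run — which is robust to noisy titer
    estimates jittering around the threshold in early blank fractions. The
    two conventions coincide on monotone curves.
    """
    if not 0 < threshold < 1:
        raise ChromatographyError("threshold must be in (0, 1)")
    r, v = curve.ratios, curve.volumes
    above = np.nonzero(r >= threshold)[0]
    if above.size == 0:
        raise ChromatographyError("column not saturated to threshold")
    if crossing == "first":
        if r[0] > threshold:
            raise ChromatographyError(
                "first fraction already above the breakthrough threshold; "
                "the load started past breakthrough"
            )
        i = int(above[0])
    elif crossing == "sustained":
        below = np.nonzero(r < threshold)[0]
        if below.size == 0:
            if r[0] == threshold:
                return float(v[0])
            raise ChromatographyError(
                "every fraction is above the breakthrough threshold; "
                "the load started past breakthrough"
            )
        j = int(below[-1])
        if j == r.size - 1:
            raise ChromatographyError("column not saturated to threshold at run end")
        i = j + 1
    else:
        raise ChromatographyError(f"unknown crossing mode '{crossing}'")
    if r[i] == threshold:
        return float(v[i])
    frac = (threshold - r[i - 1]) / (r[i] - r[i - 1])
    return float(v[i - 1] + frac * (v[i] - v[i - 1]))


@dataclass(frozen=True)
class ColumnSpec:
    """Column bed volume V_c and system offset/delay volume V_0, both mL."""

    v_c: float
    v_0: float = 0.0

    def __post_init__(self) -> None:
        if self.v_c <= 0:
            raise ChromatographyError("column bed volume must be > 0")
        if self.v_0 < 0:
            raise ChromatographyError("offset volume must be >= 0")


@dataclass(frozen=True)
class DBCResult:
    """DBC at a breakthrough threshold, with the inputs echoed."""

    v10_mL: float
    dbc_mg_per_mL: float
    method: str
    inputs: dict = field(default_factory=dict)


def dbc_10(v10: float, col: ColumnSpec, c0: float, method: str = "HPAC") -> DBCResult:
    """DBC_10% = (V_10% - V_0) * C0 / V_c, in mg per mL of resin."""
    if c0 <= 0:
        raise ChromatographyError("load titer C0 must be > 0")
    if v10 < col.v_0:
        raise ChromatographyError(
            f"V_10%={v10} mL is below the offset volume V_0={col.v_0} mL"
        )
    dbc = (v10 - col.v_0) * c0 / col.v_c
    return DBCResult(
        v10_mL=float(v10),
        dbc_mg_per_mL=float(dbc),
        method=method,
        inputs={"c0_mg_per_mL": c0, "v_c_mL": col.v_c, "v_0_mL": col.v_0},
    )


def dbc_from_uv_chromatogram(
    volumes,
    a280,
    col: ColumnSpec,
    c0: float,
    epsilon: float,
    path_cm: float,
    *,
    baseline_until: float,
    threshold: float = 0.10,
    mode: str = "beer_lambert",
) -> DBCResult:
    """DBC from a continuous UV trace (volume mL, A280 AU).

    The flat pre-load region (volumes <= ``baseline_until``) is averaged and
    subtracted. In ``beer_lambert`` mode the signal is converted to mg/mL
    with the extinction coefficient and divided by C0; in ``plateau`` mode
    the signal is normalized to the mean of the top decile of the trace
    (full-breakthrough plateau) instead.
    """
    v = np.asarray(volumes, dtype=float)
    a = np.asarray(a280, dtype=float)
    if v.shape != a.shape or v.ndim != 1 or v.size < 3:
        raise ChromatographyError("trace must be equal-length volume/absorbance vectors")
    base_mask = v <= baseline_until
    if not base_mask.any():
        raise ChromatographyError("no baseline region before baseline_until")
    signal = a - float(a[base_mask].mean())
    if mode == "beer_lambert":
        ratios = titer_from_absorbance(signal, epsilon, path_cm) / c0
    elif mode == "plateau":
        k = max(1, signal.size // 10)
        plateau = float(np.sort(signal)[-k:].mean())
        if plateau <= 0:
            raise ChromatographyError("no breakthrough plateau in trace")
        ratios = signal / plateau
    else:
        raise ChromatographyError(f"unknown UV mode '{mode}'")
    curve = BreakthroughCurve(v, np.clip(ratios, 0.0, None))
    v10 = find_v10(curve, threshold)
    res = dbc_10(v10, col, c0, method="UV")
    res.inputs.update({"epsilon": epsilon, "path_cm": path_cm, "mode": mode})
    return res
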