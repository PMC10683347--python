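"""Spectral conditioning operators applied before chemometric modelling.

Four operators are provided, each on a single :class:`~raman_dbc.spectra.Spectrum`
and, through :func:`apply_pipeline`, row-wise on a
:class:`~raman_dbc.spectra.SpectraBlock`:

``snv_normalize``
    Standard normal variate scatter correction: per-spectrum centering and
    scaling to unit sample standard deviation (ddof=1). Removes multiplicative
    scatter ``a*x + b`` exactly for any ``a > 0``.
``savgol_filter``
    Savitzky-Golay local polynomial smoothing / differentiation. Derivatives
    are scaled per cm^-1 (divided by channel spacing**d), so derivative
    spectra are comparable across instruments with different spacing. The
    axis must be uniform within 1% relative; otherwise resample first with
    :func:`resample_uniform`. Edges are handled by evaluating the polynomial
    fitted to the first/last full window (no mirror padding).
``rubberband_baseline``
    Baseline estimated as the piecewise-linear interpolation of the lower
    convex hull of the (wavenumber, intensity) points, then subtracted.
``crop``
    Closed-interval wavenumber window selection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter as _scipy_savgol

from .spectra import (
    DegenerateSpectrumError,
    NonUniformAxisError,
    SpectraBlock,
    Spectrum,
    SpectrumError,
)

__all__ = [
    "snv_normalize",
    "savgol_filter",
    "rubberband_baseline",
    "crop",
    "resample_uniform",
    "PreprocessConfig",
    "SnvStep",
    "SavgolStep",
    "RubberbandStep",
    "CropStep",
    "apply_pipeline",
    "PRESETS",
]

AXIS_UNIFORMITY_REL_TOL = 0.01


def snv_normalize(s: Spectrum) -> Spectrum:
    """Standard normal variate: center and scale to unit sample SD."""
    y = s.intensities
    sd = float(np.std(y, ddof=1))
    if sd == 0.0:
        raise DegenerateSpectrumError(
            "SNV undefined for a constant spectrum (zero variance)"
        )
    return s.with_intensities((y - y.mean()) / sd)


def _validate_savgol(window: int, polynomial: int, derivative: int, n_channels: int | None = None) -> None:
    if window != int(window) or polynomial != int(polynomial) or derivative != int(derivative):
        raise SpectrumError("savgol parameters must be integers")
    if window % 2 != 1:
        raise SpectrumError(f"savgol window must be odd, got {window}")
    if polynomial < 0 or derivative < 0:
        raise SpectrumError("savgol orders must be non-negative")
    if window < polynomial + 2:
        raise SpectrumError(
            f"savgol window ({window}) must be >= polynomial order + 2 ({polynomial + 2})"
        )
    if derivative > polynomial:
        raise SpectrumError(
            f"savgol derivative order ({derivative}) exceeds polynomial order ({polynomial})"
        )
    if n_channels is not None and window > n_channels:
        raise SpectrumError(
            f"savgol window ({window}) exceeds spectrum length ({n_channels})"
        )


def savgol_filter(s: Spectrum, window: int, polynomial: int, derivative: int = 0) -> Spectrum:
    """Savitzky-Golay smoothing/differentiation, derivative scaled per cm^-1."""
    _validate_savgol(window, polynomial, derivative, len(s))
    if not s.is_uniform(AXIS_UNIFORMITY_REL_TOL):
        raise NonUniformAxisError(
            "channel spacing varies by more than 1%; resample to a uniform axis "
            "first (see resample_uniform)"
        )
    y = _scipy_savgol(
        s.intensities,
        window_length=int(window),
        polyorder=int(polynomial),
        deriv=int(derivative),
        delta=s.spacing,
        mode="interp",
    )
    return s.with_intensities(y)


def _lower_hull_indices(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (monotone chain)."""
    hull: list[int] = []
    for i in range(w.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (w[a] - w[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (w[i] - w[o])
            if cross <= 0:  # clockwise or collinear: middle point is not a vertex
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_baseline(s: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Lower-convex-hull ("rubber band") baseline and corrected spectrum.

    Returns ``(baseline, corrected)`` where ``corrected = s - baseline``. The
    corrected intensities are exactly zero at every hull vertex and >= 0 up
    to floating tolerance elsewhere.
    """
    if len(s) < 3:
        raise SpectrumError("rubber-band baseline needs at least 3 points")
    w, y = s.wavenumbers, s.intensities
    idx = _lower_hull_indices(w, y)
    baseline = np.interp(w, w[idx], y[idx])
    return s.with_intensities(baseline), s.with_intensities(y - baseline)


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep channels with ``lo <= wavenumber <= hi`` (closed interval)."""
    if not lo < hi:
        raise SpectrumError(f"crop bounds must satisfy lo < hi, got ({lo}, {hi})")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    n = int(mask.sum())
    if n == 0:
        raise SpectrumError(f"crop({lo}, {hi}) selects no channels")
    if n < 2:
        raise SpectrumError(f"crop({lo}, {hi}) selects fewer than 2 channels")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask])


def resample_uniform(s: Spectrum, n: int | None = None) -> Spectrum:
    """Linear interpolation onto a uniform axis with the same endpoints."""
    if n is None:
        n = len(s)
    if n < 2:
        raise SpectrumError("resampling needs at least 2 channels")
    w = np.linspace(s.wavenumbers[0], s.wavenumbers[-1], n)
    return Spectrum(w, np.interp(w, s.wavenumbers, s.intensities))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class SnvStep:
    name: str = "snv"

    def apply(self, s: Spectrum) -> Spectrum:
        return snv_normalize(s)

    def params(self) -> dict:
        return {}


@dataclass(frozen=True)
class SavgolStep:
    window: int
    polynomial: int
    derivative: int = 0
    name: str = "savgol"

    def __post_init__(self) -> None:
        _validate_savgol(self.window, self.polynomial, self.derivative)

    def apply(self, s: Spectrum) -> Spectrum:
        return savgol_filter(s, self.window, self.polynomial, self.derivative)

    def params(self) -> dict:
        return {
            "window": self.window,
            "polynomial": self.polynomial,
            "derivative": self.derivative,
        }


@dataclass(frozen=True)
class RubberbandStep:
    name: str = "rubberband"

    def apply(self, s: Spectrum) -> Spectrum:
        return rubberband_baseline(s)[1]

    def params(self) -> dict:
        return {}


@dataclass(frozen=True)
class CropStep:
    lo: float
    hi: float
    name: str = "crop"

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SpectrumError(f"crop bounds must satisfy lo < hi, got ({self.lo}, {self.hi})")

    def apply(self, s: Spectrum) -> Spectrum:
        return crop(s, self.lo, self.hi)

    def params(self) -> dict:
        return {"lo": self.lo, "hi": self.hi}


_STEP_NAMES = {"snv": SnvStep, "savgol": SavgolStep, "rubberband": RubberbandStep, "crop": CropStep}


@dataclass(frozen=True)
class PreprocessConfig:
    """Ordered preprocessing recipe.

    Parse from a compact string, e.g. ``"snv,savgol:15:1:1,crop:1598:1688"``.
    """

    steps: tuple = ()

    def __post_init__(self) -> None:
        for st in self.steps:
            if not hasattr(st, "apply"):
                raise SpectrumError(f"not a preprocessing step: {st!r}")
        object.__setattr__(self, "steps", tuple(self.steps))

    @classmethod
    def parse(cls, text: str) -> "PreprocessConfig":
        steps = []
        text = text.strip()
        if not text:
            return cls(())
        for token in text.split(","):
            parts = token.strip().split(":")
            name, args = parts[0], parts[1:]
            if name not in _STEP_NAMES:
                raise SpectrumError(f"unknown preprocessing step '{name}'")
            if name == "savgol":
                if len(args) not in (2, 3):
                    raise SpectrumError("savgol takes window:polynomial[:derivative]")
                steps.append(SavgolStep(*(int(a) for a in args)))
            elif name == "crop":
                if len(args) != 2:
                    raise SpectrumError("crop takes lo:hi")
                steps.append(CropStep(float(args[0]), float(args[1])))
            else:
                if args:
                    raise SpectrumError(f"step '{name}' takes no arguments")
                steps.append(_STEP_NAMES[name]())
        return cls(tuple(steps))

    def describe(self) -> str:
        out = []
        for st in self.steps:
            p = st.params()
            out.append(st.name if not p else st.name + ":" + ":".join(str(v) for v in p.values()))
        return ",".join(out)


def apply_pipeline(block: SpectraBlock, cfg: PreprocessConfig) -> tuple[SpectraBlock, list[dict]]:
    """Apply each step of ``cfg`` in order to every row independently.

    Returns the processed block and a processing log (one entry per step,
    recording the operator, its parameters and the edge policy where
    relevant). Per-operator errors are re-raised annotated with the sample
    id of the offending row.
    """
    log: list[dict] = []
    current = block
    for st in cfg.steps:
        rows = []
        axis = None
        for sid, spec in zip(current.sample_ids, current):
            try:
                out = st.apply(spec)
            except SpectrumError as exc:
                raise type(exc)(f"sample '{sid}': {exc}") from exc
            if axis is None:
                axis = out.wavenumbers
            rows.append(out.intensities)
        current = current.with_axis(axis, np.vstack(rows))
        entry = {"step": st.name, "params": st.params()}
        if st.name == "savgol":
            entry["edge_policy"] = "first/last full-window polynomial fit"
            entry["derivative_scaling"] = "per cm^-1"
        log.append(entry)
    return current, log


#: Named recipes. ``zeroth``/``first_derivative``/``second_derivative`` are the
#: calibration recipes; ``amide_display`` is the baseline-corrected
#: second-derivative recipe used for amide I band inspection.
PRESETS = {
    "zeroth": PreprocessConfig((SnvStep(),)),
    "first_derivative": PreprocessConfig((SnvStep(), SavgolStep(15, 1, 1))),
    "second_derivative": PreprocessConfig((SnvStep(), SavgolStep(25, 2, 2))),
    "amide_display": PreprocessConfig((RubberbandStep(), SnvStep(), SavgolStep(27, 2, 2))),
}
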