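"""Three-band amide I decomposition for secondary-structure monitoring.

The amide I region (~1600-1700 cm^-1) is split into three sub-bands:
beta-sheet (1657-1688 cm^-1), alpha-helix (1630-1656 cm^-1) and
aromatic/tertiary signal (1598-1630 cm^-1). Each band's magnitude is the
trapezoidal integral over its wavenumber range and the decomposition
reports each band as a percentage of the total.

Integration convention: bands are integrated as continuous wavenumber
intervals with values interpolated at the exact band edges, so a boundary
shared by two bands contributes half to each (no double counting); the
one-wavenumber gap between the alpha (ends 1656) and beta (starts 1657)
band definitions is assigned to the beta band. On second-derivative
spectra protein bands appear as negative lobes, so the band magnitude is
the integral of the absolute value of the negative part; on zeroth-order
baseline-corrected spectra the plain integral is used.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import AxisMismatchError, Spectrum, SpectrumError

__all__ = [
    "AmideBandScheme",
    "AmideIDecomposition",
    "amide_percentages",
    "band_integral",
    "band_difference",
    "replicate_stability",
]


def _default_bands() -> dict:
    return {
        "beta": (1657.0, 1688.0),
        "alpha": (1630.0, 1656.0),
        "aromatic": (1598.0, 1630.0),
    }


@dataclass(frozen=True)
class AmideBandScheme:
    """Named (lo, hi) wavenumber windows; defaults give the three amide I bands."""

    bands: dict = field(default_factory=_default_bands)
    #: bands whose upper edge abuts a gap claimed by the band above it
    gap_assignments: dict = field(default_factory=lambda: {"beta": (1656.0, 1657.0)})

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise SpectrumError(f"band '{name}' has lo >= hi")
        spans = sorted(self.bands.values())
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise SpectrumError("bands overlap beyond shared boundaries")

    def integration_range(self, name: str) -> tuple[float, float]:
        lo, hi = self.bands[name]
        if name in self.gap_assignments:
            glo, ghi = self.gap_assignments[name]
            if ghi == lo:
                lo = glo
            elif glo == hi:
                hi = ghi
        return lo, hi


@dataclass(frozen=True)
class AmideIDecomposition:
    """Integrated magnitude and percentage of total per band."""

    magnitudes: dict
    percentages: dict
    total: float


def band_integral(s: Spectrum, lo: float, hi: float, *, second_derivative: bool = False) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated band edges.

    With ``second_derivative=True`` the integrand is the absolute value of
    the negative part of the spectrum (protein bands as negative lobes);
    otherwise the signed intensities are integrated directly.
    """
    w, y = s.wavenumbers, s.intensities
    if lo < w[0] or hi > w[-1]:
        raise SpectrumError(
            f"band [{lo}, {hi}] cm^-1 not covered by the spectrum axis "
            f"[{w[0]}, {w[-1]}]"
        )
    inner = (w > lo) & (w < hi)
    wi = np.concatenate(([lo], w[inner], [hi]))
    yi = np.concatenate(([np.interp(lo, w, y)], y[inner], [np.interp(hi, w, y)]))
    if second_derivative:
        yi = np.abs(np.minimum(yi, 0.0))
    return float(np.trapezoid(yi, wi))


def amide_percentages(
    s: Spectrum,
    scheme: AmideBandScheme | None = None,
    *,
    second_derivative: bool = False,
) -> AmideIDecomposition:
    """Per-band integrated magnitude and percentage of the amide I total."""
    scheme = scheme or AmideBandScheme()
    mags = {
        name: band_integral(s, *scheme.integration_range(name), second_derivative=second_derivative)
        for name in scheme.bands
    }
    total = float(sum(mags.values()))
    if total <= 0:
        raise SpectrumError("total amide I magnitude is zero; nothing to decompose")
    pct = {name: 100.0 * m / total for name, m in mags.items()}
    return AmideIDecomposition(magnitudes=mags, percentages=pct, total=total)


def band_difference(
    s1: Spectrum, s2: Spectrum, band: tuple[float, float], *, second_derivative: bool = False
) -> float:
    """Signed difference of integrated band magnitudes, s1 - s2."""
    if not np.array_equal(s1.wavenumbers, s2.wavenumbers):
        raise AxisMismatchError("spectra are not on a common wavenumber axis")
    lo, hi = band
    return band_integral(s1, lo, hi, second_derivative=second_derivative) - band_integral(
        s2, lo, hi, second_derivative=second_derivative
    )


def replicate_stability(groups) -> tuple[float, float]:
    """One-way ANOVA of a band percentage across replicate groups.

    ``groups`` is a sequence of per-group value lists (e.g. the beta-band
    percentage from repeated measurements at different times). Returns
    ``(F, p)``; a large p indicates no detectable drift between groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise SpectrumError("ANOVA needs at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise SpectrumError("each ANOVA group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise SpectrumError("ANOVA groups contain non-finite values")
    if all(np.ptp(g) == 0 for g in arrays) and np.ptp([g.mean() for g in arrays]) == 0:
        return 0.0, 1.0  # all values identical: no variance anywhere
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
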