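"""Containers for single and stacked wavenumber-aligned Raman spectra.

Wavenumber axes are stored in ascending order (cm^-1). Every operator in
this package preserves the axis bit-for-bit unless it explicitly crops or
resamples it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "SpectraBlock",
    "SpectrumError",
    "DegenerateSpectrumError",
    "AxisMismatchError",
    "NonUniformAxisError",
]


class SpectrumError(ValueError):
    """Invalid spectral data (shape, ordering or finiteness)."""


class DegenerateSpectrumError(SpectrumError):
    """An operation received a spectrum it cannot meaningfully process."""


class AxisMismatchError(SpectrumError):
    """Two objects that must share a wavenumber axis do not."""


class NonUniformAxisError(SpectrumError):
    """Channel spacing is not uniform enough for the requested operation."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SpectrumError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise SpectrumError(f"{name} contains non-finite values")
    return arr


def _check_axis(wavenumbers: np.ndarray) -> None:
    if wavenumbers.size < 2:
        raise SpectrumError("a spectrum needs at least 2 channels")
    if np.any(np.diff(wavenumbers) <= 0):
        raise SpectrumError("wavenumbers must be strictly increasing")


@dataclass(frozen=True)
class Spectrum:
    """A single Raman measurement: intensity versus wavenumber (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        w = _as_float_vector(self.wavenumbers, "wavenumbers")
        y = _as_float_vector(self.intensities, "intensities")
        if w.size != y.size:
            raise SpectrumError(
                f"wavenumbers ({w.size}) and intensities ({y.size}) differ in length"
            )
        _check_axis(w)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def spacing(self) -> float:
        """Mean channel spacing in cm^-1."""
        return float(np.mean(np.diff(self.wavenumbers)))

    def is_uniform(self, rel_tol: float = 0.01) -> bool:
        """True if channel spacing is uniform within ``rel_tol`` relative."""
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d.mean()) <= rel_tol * d.mean()))

    def with_intensities(self, intensities) -> "Spectrum":
        """Return a spectrum on the same axis with new intensities."""
        return Spectrum(self.wavenumbers, intensities)


@dataclass(frozen=True)
class SpectraBlock:
    """A stack of spectra sharing one wavenumber axis.

    Parameters
    ----------
    wavenumbers : array, shape (p,)
        Common axis, cm^-1, strictly increasing.
    intensities : array, shape (n, p)
        One row per sample.
    sample_ids : sequence of str
        Unique labels, one per row.
    concentrations : array, shape (n,), optional
        Analyte titer per sample in mg/mL (all >= 0).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: tuple
    concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = _as_float_vector(self.wavenumbers, "wavenumbers")
        _check_axis(w)
        m = np.asarray(self.intensities, dtype=float)
        if m.ndim != 2:
            raise SpectrumError(f"intensity matrix must be 2-D, got shape {m.shape}")
        if not np.all(np.isfinite(m)):
            raise SpectrumError("intensity matrix contains non-finite values")
        if m.shape[1] != w.size:
            raise SpectrumError(
                f"intensity matrix has {m.shape[1]} channels but axis has {w.size}"
            )
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != m.shape[0]:
            raise SpectrumError(
                f"{len(ids)} sample ids for {m.shape[0]} spectra"
            )
        if len(set(ids)) != len(ids):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise SpectrumError(f"duplicate sample ids: {dup}")
        conc = self.concentrations
        if conc is not None:
            conc = _as_float_vector(conc, "concentrations")
            if conc.size != m.shape[0]:
                raise SpectrumError("concentrations length does not match sample count")
            if np.any(conc < 0):
                raise SpectrumError("concentrations must be >= 0")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", m)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "concentrations", conc)

    @property
    def n_samples(self) -> int:
        return int(self.intensities.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.intensities.shape[1])

    def spectrum(self, key) -> Spectrum:
        """Row as a :class:`Spectrum`; ``key`` is an index or a sample id."""
        if isinstance(key, str):
            key = self.sample_ids.index(key)
        return Spectrum(self.wavenumbers, self.intensities[key])

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(self.n_samples):
            yield self.spectrum(i)

    def with_intensities(self, intensities) -> "SpectraBlock":
        return SpectraBlock(self.wavenumbers, intensities, self.sample_ids, self.concentrations)

    def with_axis(self, wavenumbers, intensities) -> "SpectraBlock":
        return SpectraBlock(wavenumbers, intensities, self.sample_ids, self.concentrations)

    def with_concentrations(self, concentrations) -> "SpectraBlock":
        return SpectraBlock(self.wavenumbers, self.intensities, self.sample_ids, concentrations)

    def subset(self, indices: Sequence[int]) -> "SpectraBlock":
        idx = np.asarray(indices, dtype=int)
        conc = None if self.concentrations is None else self.concentrations[idx]
        return SpectraBlock(
            self.wavenumbers,
            self.intensities[idx],
            tuple(self.sample_ids[i] for i in idx),
            conc,
        )

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[Spectrum],
        sample_ids: Sequence[str],
        concentrations=None,
    ) -> "SpectraBlock":
        if not spectra:
            raise SpectrumError("need at least one spectrum")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if not np.array_equal(s.wavenumbers, axis):
                raise AxisMismatchError("spectra do not share a common wavenumber axis")
        return cls(axis, np.vstack([s.intensities for s in spectra]), tuple(sample_ids), concentrations)

    @classmethod
    def concatenate(cls, blocks: Sequence["SpectraBlock"]) -> "SpectraBlock":
        """Stack blocks sample-wise; all must share the axis and carry
        concentrations either everywhere or nowhere."""
        if not blocks:
            raise SpectrumError("need at least one block")
        axis = blocks[0].wavenumbers
        for b in blocks[1:]:
            if not np.array_equal(b.wavenumbers, axis):
                raise AxisMismatchError("blocks do not share a common wavenumber axis")
        has_conc = [b.concentrations is not None for b in blocks]
        if any(has_conc) and not all(has_conc):
            raise SpectrumError("cannot concatenate blocks with and without concentrations")
        conc = np.concatenate([b.concentrations for b in blocks]) if all(has_conc) else None
        ids = tuple(s for b in blocks for s in b.sample_ids)
        return cls(axis, np.vstack([b.intensities for b in blocks]), ids, conc)
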