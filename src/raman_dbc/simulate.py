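"""Seeded generator of complete synthetic breakthrough experiments.

Each simulated experiment emulates the structure of a protein A
breakthrough study on clarified harvest: flowthrough fractions whose
analyte titer follows a logistic breakthrough curve, one Raman spectrum
per fraction, a dense UV chromatogram of the same run, affinity-assay peak
areas per fraction, and a peak-area standard curve — all with known ground
truth.

Spectral model (per sample)::

    I(w) = a * (titer * protein(w) + g_b * background(w) + g_l * baseline(w))
           + offset + N(0, sigma^2)

where ``protein`` is a sum of Gaussian amide I component bands (beta-sheet
at 1672 cm^-1, alpha-helix at 1643 cm^-1, aromatic at 1612 cm^-1; band
areas scale linearly with titer), ``background`` holds media/host-cell
bands outside the amide I window, ``baseline`` is a broad polynomial, and
``a``/``offset`` are per-sample multiplicative scatter and additive offset.
``g_b``/``g_l`` are per-sample background and baseline scale factors. Five
latent variables therefore vary independently per spectrum: titer,
background scale, baseline scale, scatter and offset.

Breakthrough model: C(V) = C0 / (1 + exp(-k (V - V_mid))), giving the
closed forms V_10% = V_mid - ln(9)/k and DBC_10% = (V_10% - V_0) C0 / V_c.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .chromatography import ColumnSpec, FractionTable
from .preprocess import PreprocessConfig, apply_pipeline
from .spectra import SpectraBlock, Spectrum

__all__ = [
    "SimulationError",
    "GaussianBand",
    "SynthConfig",
    "GroundTruth",
    "RunData",
    "generate_spectrum",
    "generate_breakthrough_run",
    "generate_standard_curve_data",
    "propagated_noise_floor",
    "DEFAULT_INJECTION_VOLUMES_UL",
]

PLATE_CAPACITY = 96  # fractions per run (one deep-well plate)

DEFAULT_INJECTION_VOLUMES_UL = (5.0, 7.0, 10.0, 15.0, 20.0, 25.0, 30.0)


class SimulationError(ValueError):
    """Invalid or internally inconsistent simulation configuration."""


@dataclass(frozen=True)
class GaussianBand:
    """A component band: center (cm^-1), width sigma (cm^-1), integrated area."""

    center: float
    sigma: float
    area: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise SimulationError("band sigma must be > 0")
        if self.area < 0:
            raise SimulationError("band area must be >= 0")

    def profile(self, w: np.ndarray, shape: str = "gaussian", eta: float = 0.3) -> np.ndarray:
        """Area-normalized line profile times the band area."""
        g = np.exp(-0.5 * ((w - self.center) / self.sigma) ** 2) / (
            self.sigma * math.sqrt(2 * math.pi)
        )
        if shape == "gaussian":
            return self.area * g
        if shape == "pseudo_voigt":
            gamma = self.sigma * math.sqrt(2 * math.log(2))  # match Gaussian HWHM
            lor = gamma / (math.pi * ((w - self.center) ** 2 + gamma**2))
            return self.area * ((1 - eta) * g + eta * lor)
        raise SimulationError(f"unknown band shape '{shape}'")


def _default_protein_bands() -> tuple:
    # amide I components; areas per mg/mL in a 5:3:2 beta:alpha:aromatic ratio
    return (
        GaussianBand(1672.0, 5.0, 50.0),
        GaussianBand(1643.0, 4.0, 30.0),
        GaussianBand(1612.0, 5.0, 20.0),
    )


def _default_background_bands() -> tuple:
    # media / host-cell protein features away from the amide I window
    return (
        GaussianBand(850.0, 15.0, 400.0),
        GaussianBand(1003.0, 4.0, 150.0),
        GaussianBand(1080.0, 12.0, 300.0),
        GaussianBand(1250.0, 20.0, 250.0),
        GaussianBand(1450.0, 18.0, 350.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Full generative description of a simulated breakthrough experiment."""

    seed: int = 0
    # wavenumber axis
    wn_lo: float = 600.0
    wn_hi: float = 1800.0
    wn_step: float = 1.0
    # spectral model
    protein_bands: tuple = field(default_factory=_default_protein_bands)
    background_bands: tuple = field(default_factory=_default_background_bands)
    baseline_coeffs: tuple = (200.0, -80.0, 40.0)  # polynomial in x = (w-lo)/(hi-lo)
    band_shape: str = "gaussian"
    voigt_eta: float = 0.3
    background_scale_range: tuple = (0.9, 1.1)
    baseline_scale_range: tuple = (0.9, 1.1)
    scatter_range: tuple = (0.9, 1.1)
    offset_range: tuple = (-2.0, 2.0)
    noise_sigma: float = 1.0  # detector counts
    # breakthrough model
    c0: float = 2.5  # load titer, mg/mL
    k_per_mL: float = 0.3  # logistic steepness
    v_mid_mL: float = 78.0  # logistic midpoint volume
    load_volume_mL: float = 120.0
    fraction_mL: float = 2.0
    # column
    v_c_mL: float = 4.7
    v_0_mL: float = 1.2
    # UV chromatogram
    epsilon: float = 1.44  # mL mg^-1 cm^-1
    path_cm: float = 0.2
    uv_baseline_au: float = 0.02
    uv_noise_au: float = 0.005
    uv_step_mL: float = 0.25
    # affinity-assay (peak area) model
    std_m: float = 1000.0  # area per mg
    std_b: float = 5.0
    area_noise_sigma: float = 0.15
    injection_mL: float = 0.010

    def __post_init__(self) -> None:
        if self.k_per_mL <= 0:
            raise SimulationError("logistic steepness k must be > 0")
        if self.noise_sigma < 0 or self.uv_noise_au < 0 or self.area_noise_sigma < 0:
            raise SimulationError("noise levels must be >= 0")
        if self.c0 <= 0 or self.v_c_mL <= 0 or self.fraction_mL <= 0:
            raise SimulationError("c0, bed volume and fraction size must be > 0")
        if self.wn_step <= 0 or self.wn_hi <= self.wn_lo:
            raise SimulationError("invalid wavenumber axis specification")

    # -- derived quantities -------------------------------------------------

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.wn_hi - self.wn_lo) / self.wn_step)) + 1
        return self.wn_lo + self.wn_step * np.arange(n)

    @property
    def column(self) -> ColumnSpec:
        return ColumnSpec(v_c=self.v_c_mL, v_0=self.v_0_mL)

    @property
    def latent_dim(self) -> int:
        """Independently drawn latent variables per spectrum: titer,
        background scale, baseline scale, scatter, offset."""
        return 5

    def breakthrough_titer(self, v) -> np.ndarray:
        """C(V) = C0 / (1 + exp(-k (V - V_mid)))."""
        return self.c0 / (1.0 + np.exp(-self.k_per_mL * (np.asarray(v, dtype=float) - self.v_mid_mL)))

    def true_v10(self, threshold: float = 0.10) -> float:
        return self.v_mid_mL - math.log((1 - threshold) / threshold) / self.k_per_mL

    def true_dbc(self, threshold: float = 0.10) -> float:
        return (self.true_v10(threshold) - self.v_0_mL) * self.c0 / self.v_c_mL

    # -- construction helpers ----------------------------------------------

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)

    def with_protein_areas(self, areas) -> "SynthConfig":
        """Same band positions/widths with redistributed areas (a 'new' analyte)."""
        bands = tuple(
            GaussianBand(b.center, b.sigma, float(a))
            for b, a in zip(self.protein_bands, areas, strict=True)
        )
        return self.replace(protein_bands=bands)

    def with_target_dbc(self, dbc: float, threshold: float = 0.10) -> "SynthConfig":
        """Move the logistic midpoint so the closed-form DBC equals ``dbc``."""
        v10 = dbc * self.v_c_mL / self.c0 + self.v_0_mL
        v_mid = v10 + math.log((1 - threshold) / threshold) / self.k_per_mL
        return self.replace(v_mid_mL=v_mid)

    def aged(self, cycles: int, decay_per_cycle: float = 0.002) -> "SynthConfig":
        """Emulate column ageing: shrink the bound mass (V_mid) per cycle."""
        span = self.true_v10() - self.v_0_mL
        new_span = span * (1.0 - decay_per_cycle) ** cycles
        return self.replace(v_mid_mL=self.v_0_mL + new_span + math.log(9.0) / self.k_per_mL)

    def scaled_noise(self, factor: float) -> "SynthConfig":
        """Scale every stochastic noise level by ``factor``."""
        return self.replace(
            noise_sigma=self.noise_sigma * factor,
            uv_noise_au=self.uv_noise_au * factor,
            area_noise_sigma=self.area_noise_sigma * factor,
        )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one simulated run."""

    titers: np.ndarray
    v10_mL: float
    dbc_mg_per_mL: float
    latent_dim: int


@dataclass(frozen=True)
class RunData:
    """One simulated breakthrough run with every measurement modality."""

    spectra: SpectraBlock
    fractions: FractionTable
    hpac_areas: np.ndarray
    uv_volumes: np.ndarray
    uv_a280: np.ndarray
    truth: GroundTruth
    config: SynthConfig


def _component_profiles(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = cfg.wavenumbers
    protein = np.zeros_like(w)
    for b in cfg.protein_bands:
        protein += b.profile(w, cfg.band_shape, cfg.voigt_eta)
    background = np.zeros_like(w)
    for b in cfg.background_bands:
        background += b.profile(w, cfg.band_shape, cfg.voigt_eta)
    x = (w - cfg.wn_lo) / (cfg.wn_hi - cfg.wn_lo)
    baseline = np.polynomial.polynomial.polyval(x, cfg.baseline_coeffs)
    return protein, background, baseline


def clean_spectrum(
    cfg: SynthConfig,
    titer: float,
    *,
    background_scale: float = 1.0,
    baseline_scale: float = 1.0,
    scatter: float = 1.0,
    offset: float = 0.0,
) -> Spectrum:
    """Deterministic (noise-free) spectrum at explicit latent values."""
    if titer < 0:
        raise SimulationError("titer must be >= 0")
    protein, background, baseline = _component_profiles(cfg)
    y = scatter * (titer * protein + background_scale * background + baseline_scale * baseline) + offset
    return Spectrum(cfg.wavenumbers, y)


def generate_spectrum(cfg: SynthConfig, titer: float, rng: np.random.Generator | None = None) -> Spectrum:
    """One noisy spectrum at ``titer`` with random scatter, offset and
    background/baseline scales drawn from the configured ranges."""
    if rng is None:
        rng = cfg.rng()
    a = rng.uniform(*cfg.scatter_range)
    offset = rng.uniform(*cfg.offset_range)
    gb = rng.uniform(*cfg.background_scale_range)
    gl = rng.uniform(*cfg.baseline_scale_range)
    s = clean_spectrum(
        cfg, titer, background_scale=gb, baseline_scale=gl, scatter=a, offset=offset
    )
    noise = rng.normal(0.0, cfg.noise_sigma, s.intensities.size) if cfg.noise_sigma > 0 else 0.0
    return s.with_intensities(s.intensities + noise)


def generate_breakthrough_run(
    cfg: SynthConfig, rng: np.random.Generator | None = None, *, threshold: float = 0.10
) -> RunData:
    """Simulate a full run: fraction spectra, fraction table, assay areas,
    UV trace and ground truth."""
    if rng is None:
        rng = cfg.rng()
    n_frac = int(cfg.load_volume_mL / cfg.fraction_mL)
    if n_frac < 2:
        raise SimulationError("load volume spans fewer than 2 fractions")
    if n_frac > PLATE_CAPACITY:
        raise SimulationError(
            f"{n_frac} fractions exceed the {PLATE_CAPACITY}-well plate capacity"
        )
    starts = cfg.fraction_mL * np.arange(n_frac)
    mids = starts + 0.5 * cfg.fraction_mL
    titers = cfg.breakthrough_titer(mids)
    if titers[-1] / cfg.c0 <= threshold:
        raise SimulationError(
            "run length insufficient: breakthrough never crosses the threshold"
        )

    spectra = [generate_spectrum(cfg, t, rng) for t in titers]
    ids = [f"F{i + 1:02d}" for i in range(n_frac)]
    block = SpectraBlock.from_spectra(spectra, ids, concentrations=titers)

    fractions = FractionTable(starts, starts + cfg.fraction_mL, titers, cfg.c0)

    masses = titers * cfg.injection_mL
    hpac_areas = cfg.std_m * masses + cfg.std_b + rng.normal(0.0, cfg.area_noise_sigma, n_frac)

    uv_volumes = np.arange(0.0, cfg.load_volume_mL + 1e-9, cfg.uv_step_mL)
    uv_clean = cfg.epsilon * cfg.path_cm * cfg.breakthrough_titer(uv_volumes) + cfg.uv_baseline_au
    uv_a280 = uv_clean + rng.normal(0.0, cfg.uv_noise_au, uv_volumes.size)

    truth = GroundTruth(
        titers=titers,
        v10_mL=cfg.true_v10(threshold),
        dbc_mg_per_mL=cfg.true_dbc(threshold),
        latent_dim=cfg.latent_dim,
    )
    return RunData(block, fractions, hpac_areas, uv_volumes, uv_a280, truth, cfg)


def generate_standard_curve_data(
    cfg: SynthConfig,
    volumes_uL=DEFAULT_INJECTION_VOLUMES_UL,
    stock_mg_per_mL: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(mass on column mg, peak area) pairs from an injection-volume series."""
    if rng is None:
        rng = cfg.rng()
    vols = np.asarray(volumes_uL, dtype=float)
    if np.any(vols <= 0):
        raise SimulationError("injection volumes must be > 0")
    masses = vols * 1e-3 * stock_mg_per_mL  # uL * mg/mL -> mg
    areas = cfg.std_m * masses + cfg.std_b + rng.normal(0.0, cfg.area_noise_sigma, masses.size)
    return masses, areas


def propagated_noise_floor(
    cfg: SynthConfig,
    preprocess: PreprocessConfig,
    n_mc: int = 200,
    rng: np.random.Generator | None = None,
    at_titer: float | None = None,
) -> float:
    """Minimum achievable titer RMSE (mg/mL) of a linear estimator on
    preprocessed spectra, at the configured noise and scale-variation levels.

    SNV normalization is scale-invariant, so a spectrum at titer ``t`` with
    component scales ``(g_b, g_l)`` is first-order indistinguishable from
    one at a different titer with rescaled components: titer is identifiable
    only through the prior spread of the per-sample scale factors. The floor
    therefore propagates both detector noise and those latent variations.

    Construction: linearize the generator around ``at_titer`` (default
    C0/2) in the preprocessed space, giving a tangent model
    ``x = x0 + A (theta - theta0) + noise`` with
    ``theta = (titer, g_b, g_l, scatter, offset)``. Detector-noise
    covariance in the tangent space is estimated from ``n_mc`` noise
    realizations pushed through the full pipeline. The returned value is
    the posterior SD of titer under a flat titer prior and the configured
    uniform priors on the nuisance parameters — the precision limit any
    calibration linear in the processed spectrum can reach; model error
    (e.g. normalization curvature) comes on top of it.
    """
    if rng is None:
        rng = cfg.rng()
    if cfg.noise_sigma <= 0:
        raise SimulationError("noise floor needs noise_sigma > 0")
    t0 = 0.5 * cfg.c0 if at_titer is None else float(at_titer)
    d_t, d_g, d_o = 0.05, 0.05, 0.5
    probes = [
        clean_spectrum(cfg, t0),
        clean_spectrum(cfg, t0 + d_t),
        clean_spectrum(cfg, t0 - d_t),
        clean_spectrum(cfg, t0, background_scale=1 + d_g),
        clean_spectrum(cfg, t0, baseline_scale=1 + d_g),
        clean_spectrum(cfg, t0, scatter=1 + d_g),
        clean_spectrum(cfg, t0, offset=d_o),
    ]
    base = probes[0].intensities
    noisy = [
        Spectrum(cfg.wavenumbers, base + rng.normal(0.0, cfg.noise_sigma, base.size))
        for _ in range(n_mc)
    ]
    ids = [f"p{i}" for i in range(len(probes))] + [f"mc{i}" for i in range(n_mc)]
    block = SpectraBlock.from_spectra(probes + noisy, ids)
    proc, _ = apply_pipeline(block, preprocess)
    P = proc.intensities
    A = np.stack(
        [
            (P[1] - P[2]) / (2 * d_t),
            (P[3] - P[0]) / d_g,
            (P[4] - P[0]) / d_g,
            (P[5] - P[0]) / d_g,
            (P[6] - P[0]) / d_o,
        ],
        axis=1,
    )
    if not np.any(A[:, 0]):
        raise SimulationError("titer response vanished; check the band model")
    # uniform(lo, hi) prior SD = (hi - lo) / sqrt(12); flat prior on titer
    def usd(rng_pair):
        return (rng_pair[1] - rng_pair[0]) / math.sqrt(12.0)

    prior_sd = np.array(
        [
            np.inf,
            usd(cfg.background_scale_range),
            usd(cfg.baseline_scale_range),
            usd(cfg.scatter_range),
            usd(cfg.offset_range),
        ]
    )
    Q, _ = np.linalg.qr(A)
    M = Q.T @ A
    E = (P[len(probes):] - P[0]) @ Q
    C = np.cov(E.T)
    C += (1e-10 * np.trace(C) / C.shape[0]) * np.eye(C.shape[0])
    with np.errstate(divide="ignore"):
        # flat prior (inf SD) -> zero precision; a fixed nuisance (zero SD)
        # contributes a very stiff, but finite, pin
        prior_prec = np.where(
            np.isinf(prior_sd), 0.0, 1.0 / np.maximum(prior_sd, 1e-9) ** 2
        )
    H = M.T @ np.linalg.solve(C, M) + np.diag(prior_prec)
    cov = np.linalg.inv(H)
    return float(math.sqrt(cov[0, 0]))
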