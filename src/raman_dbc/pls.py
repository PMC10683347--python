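"""PLS1 regression (NIPALS) linking preprocessed spectra to analyte titer.

The model is fitted on mean-centred data only: channels are not autoscaled,
since SNV already row-normalizes and column autoscaling of derivative
spectra amplifies noise channels. For a single response the NIPALS weight
update has a closed fixed point, but the implementation iterates to a
tolerance so that the convergence contract is explicit.

Model selection follows an explicit, reproducible formalization of the
"no further gain in RMSECV" rule: the smallest number of components A for
which the relative RMSECV improvement from A to A+1 falls below ``rel_tol``
(default 1%). If RMSECV has already reached a numerical floor (1e-8 of the
response SD) the current A is accepted; if no A qualifies, A_max - 1 is
returned, since the last component cannot be justified as "no further
gain" without evaluating beyond it.

Error metrics
-------------
RMSE = sqrt(sum((y_i - yhat_i)^2) / n). RMSEC is this on the training fit,
RMSECV on leave-one-out held-out predictions (full NIPALS refit per fold,
including re-centering), RMSEP on an independent test set.
Q^2 = 1 - PRESS / TSS with TSS about the full-sample mean of y
(1 = perfect prediction, ~0 = no predictive ability).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import AxisMismatchError, SpectraBlock, SpectrumError

__all__ = [
    "PLSModel",
    "CVReport",
    "PredictionAssessment",
    "PLSError",
    "rmse",
    "fit_pls",
    "predict",
    "loocv",
    "select_components",
    "assess_prediction",
    "model_to_json",
    "model_from_json",
]


class PLSError(ValueError):
    """Invalid input to, or failure of, PLS fitting/prediction."""


def rmse(actual, predicted) -> float:
    """Root mean square error between two equal-length titer vectors."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise PLSError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise PLSError("rmse undefined for empty vectors")
    return float(np.sqrt(np.mean((a - p) ** 2)))


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model with all truncations A = 1..A_max available.

    ``weights``/``loadings`` are (p, A_max); ``y_loadings`` is (A_max,).
    The regression coefficient vector for a truncation A is
    ``W_A (P_A^T W_A)^{-1} q_A`` and predictions are
    ``y_mean + (x - x_mean) . beta_A``.
    """

    wavenumbers: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    a_max: int
    a_selected: int | None = None
    preprocess: str | None = None

    def coefficients(self, a: int | None = None) -> np.ndarray:
        """Regression coefficient vector (per channel) at truncation ``a``."""
        if a is None:
            a = self.a_selected if self.a_selected is not None else self.a_max
        if not 0 <= a <= self.a_max:
            raise PLSError(f"truncation A={a} outside 0..{self.a_max}")
        if a == 0:
            return np.zeros_like(self.x_mean)
        W = self.weights[:, :a]
        P = self.loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def with_selected(self, a: int) -> "PLSModel":
        return PLSModel(
            self.wavenumbers, self.x_mean, self.y_mean, self.weights,
            self.loadings, self.y_loadings, self.a_max, a, self.preprocess,
        )


def fit_pls(
    block: SpectraBlock,
    a_max: int,
    *,
    tol: float = 1e-12,
    max_iter: int = 1000,
    rank_tol: float = 1e-12,
    preprocess: str | None = None,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS deflation on mean-centred data.

    If the deflated matrix is numerically exhausted before ``a_max``
    components (score variance below ``rank_tol`` times the first
    component's), the model is truncated there with a warning: further
    components would fit rounding error and produce unbounded coefficient
    vectors.
    """
    if block.concentrations is None:
        raise PLSError("training block carries no concentrations")
    X = np.array(block.intensities, dtype=float)
    y = np.array(block.concentrations, dtype=float)
    n, p = X.shape
    if n < 2:
        raise PLSError("need at least 2 training samples")
    if np.std(y) == 0:
        raise PLSError("zero-variance response: all training titers identical")
    if not 1 <= a_max <= min(n - 1, p):
        raise PLSError(f"A_max={a_max} outside 1..min(n-1, p)={min(n - 1, p)}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.empty((p, a_max))
    P = np.empty((p, a_max))
    q = np.empty(a_max)
    tt_first = None
    n_components = a_max
    for a in range(a_max):
        u = yc
        w_prev = None
        exhausted = False
        for _ in range(max_iter):
            w = Xc.T @ u
            nw = float(np.linalg.norm(w))
            if not np.isfinite(nw):
                raise PLSError(f"NIPALS failed at component {a + 1}: degenerate weight vector")
            if nw == 0.0:
                exhausted = True
                break
            w = w / nw
            t = Xc @ w
            tt = float(t @ t)
            if tt_first is not None and tt <= rank_tol * tt_first:
                exhausted = True
                break
            if tt == 0.0:
                raise PLSError(f"NIPALS failed at component {a + 1}: zero score vector")
            qa = float(yc @ t) / tt
            if w_prev is not None and np.linalg.norm(w - w_prev) < tol:
                break
            w_prev = w
            u = yc * qa  # PLS1: the y-score direction is fixed by y
        else:
            raise PLSError(
                f"NIPALS did not converge at component {a + 1} after {max_iter} iterations"
            )
        if exhausted:
            if a == 0:
                raise PLSError("NIPALS failed at component 1: no spectral variance")
            warnings.warn(
                f"training matrix numerically exhausted after {a} components; "
                f"model truncated (requested {a_max})",
                stacklevel=2,
            )
            n_components = a
            break
        t = Xc @ w
        tt = float(t @ t)
        if tt_first is None:
            tt_first = tt
        pa = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa

    W, P, q = W[:, :n_components], P[:, :n_components], q[:n_components]
    a_max = n_components
    return PLSModel(
        wavenumbers=np.array(block.wavenumbers),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        a_max=a_max,
        preprocess=preprocess,
    )


def predict(model: PLSModel, block: SpectraBlock, a: int | None = None) -> np.ndarray:
    """Predict titers (mg/mL) for each row of ``block`` at truncation ``a``."""
    if block.wavenumbers.size != model.wavenumbers.size or not np.allclose(
        block.wavenumbers, model.wavenumbers, rtol=0.0, atol=1e-9
    ):
        raise AxisMismatchError(
            "prediction block is not on the model's wavenumber axis; "
            "apply the training preprocessing (no silent interpolation)"
        )
    beta = model.coefficients(a)
    return model.y_mean + (block.intensities - model.x_mean) @ beta


@dataclass(frozen=True)
class CVReport:
    """Per-component-count error metrics from training fit and LOOCV."""

    a_max: int
    rmsec: np.ndarray
    rmsecv: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    selected_a: int
    rationale: str
    warnings: tuple = ()


def loocv(block: SpectraBlock, a_max: int, *, rel_tol: float = 0.01) -> CVReport:
    """Leave-one-out cross-validation with a full NIPALS refit per fold."""
    if block.concentrations is None:
        raise PLSError("block carries no concentrations")
    n = block.n_samples
    if n < 3:
        raise PLSError("LOOCV needs at least 3 samples")
    notes: list[str] = []
    a_eff = min(a_max, n - 2)
    if a_eff < a_max:
        notes.append(
            f"A_max={a_max} capped at n-2={a_eff} so each fold keeps a valid fit"
        )
    y = np.asarray(block.concentrations, dtype=float)

    full = fit_pls(block, a_eff)
    if full.a_max < a_eff:
        notes.append(
            f"training matrix rank-limited: metrics beyond A={full.a_max} "
            "repeat the exhausted fit"
        )
    rmsec = np.empty(a_eff)
    r2 = np.empty(a_eff)
    tss = float(np.sum((y - y.mean()) ** 2))
    for a in range(1, a_eff + 1):
        yhat = predict(full, block, min(a, full.a_max))
        rmsec[a - 1] = rmse(y, yhat)
        r2[a - 1] = 1.0 - float(np.sum((y - yhat) ** 2)) / tss

    cv_pred = np.empty((n, a_eff))
    idx = np.arange(n)
    for i in range(n):
        sub = block.subset(idx[idx != i])
        mdl = fit_pls(sub, a_eff)
        one = block.subset([i])
        for a in range(1, a_eff + 1):
            cv_pred[i, a - 1] = predict(mdl, one, min(a, mdl.a_max))[0]

    press = np.sum((cv_pred - y[:, None]) ** 2, axis=0)
    rmsecv = np.sqrt(press / n)
    q2 = 1.0 - press / tss

    floor = 1e-8 * float(np.std(y, ddof=1))
    selected, rationale = select_components(rmsecv, rel_tol=rel_tol, abs_floor=floor)
    return CVReport(
        a_max=a_eff,
        rmsec=rmsec,
        rmsecv=rmsecv,
        r2=r2,
        q2=q2,
        selected_a=selected,
        rationale=rationale,
        warnings=tuple(notes),
    )


def select_components(
    rmsecv, rel_tol: float = 0.01, abs_floor: float = 0.0
) -> tuple[int, str]:
    """Smallest A whose RMSECV improvement to A+1 is below ``rel_tol``.

    Accepts a :class:`CVReport` or a per-A RMSECV array. Returns
    ``(A, rationale)``. Ties break toward smaller A by construction. If every
    improvement up to A_max-1 exceeds the tolerance, A_max - 1 is returned.
    """
    if isinstance(rmsecv, CVReport):
        rmsecv = rmsecv.rmsecv
    r = np.asarray(rmsecv, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise PLSError("rmsecv must be a non-empty 1-D array")
    a_max = r.size
    if a_max == 1:
        return 1, "single candidate component count"
    for a in range(1, a_max):
        if r[a - 1] <= abs_floor:
            return a, f"RMSECV at A={a} already at numerical floor ({r[a-1]:.3g})"
        gain = (r[a - 1] - r[a]) / r[a - 1] if r[a - 1] > 0 else 0.0
        if gain < rel_tol:
            return a, (
                f"relative RMSECV gain from A={a} to A={a + 1} is "
                f"{gain:.4f} < {rel_tol}"
            )
    return a_max - 1, (
        f"every gain up to A={a_max - 1} exceeded {rel_tol}; capped at A_max-1"
    )


@dataclass(frozen=True)
class PredictionAssessment:
    """Held-out test-set performance at the model's selected truncation."""

    rmsep: float
    q2: float | None
    n: int
    a_used: int


def assess_prediction(
    model: PLSModel, test: SpectraBlock, a: int | None = None
) -> PredictionAssessment:
    """RMSEP and test-set Q^2 (about the test-set mean) at truncation ``a``."""
    if test.concentrations is None:
        raise PLSError("test block carries no concentrations")
    if a is None:
        a = model.a_selected if model.a_selected is not None else model.a_max
    y = np.asarray(test.concentrations, dtype=float)
    yhat = predict(model, test, a)
    err = rmse(y, yhat)
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = None if y.size < 2 or tss == 0.0 else 1.0 - float(np.sum((y - yhat) ** 2)) / tss
    return PredictionAssessment(rmsep=err, q2=q2, n=int(y.size), a_used=int(a))


# ---------------------------------------------------------------------------
# serialization


def model_to_json(model: PLSModel) -> str:
    """Portable JSON: everything needed to reproduce a prediction from file."""
    return json.dumps(
        {
            "format": "raman-dbc-pls-model",
            "version": 1,
            "wavenumbers": model.wavenumbers.tolist(),
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean,
            "weights": model.weights.tolist(),
            "loadings": model.loadings.tolist(),
            "y_loadings": model.y_loadings.tolist(),
            "a_max": model.a_max,
            "a_selected": model.a_selected,
            "preprocess": model.preprocess,
        }
    )


def model_from_json(text: str) -> PLSModel:
    d = json.loads(text)
    if d.get("format") != "raman-dbc-pls-model":
        raise PLSError("not a raman-dbc PLS model file")
    return PLSModel(
        wavenumbers=np.asarray(d["wavenumbers"], dtype=float),
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
        weights=np.asarray(d["weights"], dtype=float),
        loadings=np.asarray(d["loadings"], dtype=float),
        y_loadings=np.asarray(d["y_loadings"], dtype=float),
        a_max=int(d["a_max"]),
        a_selected=None if d.get("a_selected") is None else int(d["a_selected"]),
        preprocess=d.get("preprocess"),
    )
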