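"""Principal component regression and NIPALS PLS2 calibration.

Both engines work on mean-centered X (absorbance window) and Y (concentration)
blocks; centering means are stored in the fitted model so prediction applies
the calibration means, never the test set's own. PCR extracts components by
SVD of the centered X-block (same subspace as NIPALS PCA, numerically safer)
and regresses the centered Y on the leading scores. PLS2 runs the classic
NIPALS sequence with deflation of both blocks and assembles the regression
matrix as B = W (PᵀW)⁻¹ Qᵀ, so all four analytes are modelled simultaneously.
Leave-one-out cross-validation refits the chosen engine on every fold
(re-centering each time) and picks the latent-variable count with the smallest
analyte-averaged RMSECV, breaking near-ties toward fewer factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import CenteredBlock
from .synthetic_data import SpectraSet

__all__ = [
    "FactorModel",
    "CVCurve",
    "fit_pcr",
    "fit_pls",
    "predict",
    "loo_cross_validate",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


def _as_xy(X, Y):
    """Accept SpectraSet / CenteredBlock(+means) / ndarray for the X-block."""
    if isinstance(X, SpectraSet):
        wavelengths = X.wavelengths_nm
        Xraw = X.absorbance
    elif isinstance(X, CenteredBlock):
        wavelengths = X.wavelengths_nm
        Xraw = X.restore()
    else:
        Xraw = np.atleast_2d(np.asarray(X, dtype=float))
        wavelengths = np.arange(Xraw.shape[1], dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != Xraw.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    return Xraw, Y, np.asarray(wavelengths, dtype=float)


@dataclass
class FactorModel:
    """Fitted PCR or PLS calibration artifacts."""

    kind: str                      # "PCR" | "PLS"
    n_lv: int
    x_loadings: np.ndarray         # P: wavelengths × n_lv
    x_scores: np.ndarray           # T: samples × n_lv
    y_loadings: np.ndarray         # Q: analytes × n_lv
    coefficients: np.ndarray       # B: wavelengths × analytes
    x_means: np.ndarray
    y_means: np.ndarray
    wavelengths_nm: np.ndarray
    pls_weights: np.ndarray | None = None   # W: wavelengths × n_lv (PLS only)
    schema_version: int = 1

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "kind": self.kind,
            "n_lv": self.n_lv,
            "x_loadings": self.x_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_means": self.x_means.tolist(),
            "y_means": self.y_means.tolist(),
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "pls_weights": None if self.pls_weights is None else self.pls_weights.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        d = json.loads(Path(path).read_text())
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            kind=d["kind"],
            n_lv=int(d["n_lv"]),
            x_loadings=arr("x_loadings"),
            x_scores=arr("x_scores"),
            y_loadings=arr("y_loadings"),
            coefficients=arr("coefficients"),
            x_means=arr("x_means"),
            y_means=arr("y_means"),
            wavelengths_nm=arr("wavelengths_nm"),
            pls_weights=None if d["pls_weights"] is None else np.asarray(d["pls_weights"]),
            schema_version=int(d["schema_version"]),
        )


@dataclass
class CVCurve:
    """Leave-one-out RMSECV as a function of latent-variable count."""

    lv_counts: np.ndarray          # tested counts, starting at 0 (mean-only model)
    rmsecv: np.ndarray             # len(lv_counts) × n_analytes
    selected_lv: int

    @property
    def mean_rmsecv(self) -> np.ndarray:
        return self.rmsecv.mean(axis=1)


def fit_pcr(X, Y, n_lv: int) -> FactorModel:
    """Principal component regression with ``n_lv`` components.

    Components come from the SVD of the column-centered X-block; the centered
    Y-block is regressed on the leading scores by least squares.
    """
    Xraw, Y, wl = _as_xy(X, Y)
    n, p = Xraw.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
    x_means = Xraw.mean(axis=0)
    y_means = Y.mean(axis=0)
    Xc, Yc = Xraw - x_means, Y - y_means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[n_lv - 1] <= s[0] * 1e-12:
        raise np.linalg.LinAlgError("score matrix is rank deficient at the requested n_lv")
    T = U[:, :n_lv] * s[:n_lv]
    P = Vt[:n_lv].T
    # Q = (TᵀT)⁻¹ Tᵀ Yc; TᵀT is diagonal (s²) for SVD scores
    Q = (T.T @ Yc / (s[:n_lv] ** 2)[:, None]).T
    B = P @ np.diag(1.0 / s[:n_lv]) @ U[:, :n_lv].T @ Yc
    return FactorModel("PCR", n_lv, P, T, Q, B, x_means, y_means, wl)


def fit_pls(X, Y, n_lv: int) -> FactorModel:
    """NIPALS PLS2 with ``n_lv`` latent variables (all analytes jointly)."""
    Xraw, Y, wl = _as_xy(X, Y)
    n, p = Xraw.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
    x_means = Xraw.mean(axis=0)
    y_means = Y.mean(axis=0)
    Xc, Yc = Xraw - x_means, Y - y_means
    E, F = Xc.copy(), Yc.copy()
    m = Y.shape[1]
    W = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    for a in range(n_lv):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = None
        for _ in range(_NIPALS_MAX_ITER):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise np.linalg.LinAlgError("NIPALS weight vector vanished")
            w /= nw
            t = E @ w
            tt = t @ t
            if tt == 0:
                raise np.linalg.LinAlgError("NIPALS score vector vanished")
            q = F.T @ t / tt
            if q @ q == 0:
                break
            u = F @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= _NIPALS_TOL * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError("NIPALS inner loop failed to converge")
        p_a = E.T @ t / tt
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q)
        W[:, a], T[:, a], P[:, a], Q[:, a] = w, t, p_a, q
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return FactorModel("PLS", n_lv, P, T, Q, B, x_means, y_means, wl, pls_weights=W)


def predict(model: FactorModel, X_new) -> np.ndarray:
    """Predicted concentrations (µg/mL) for new spectra."""
    if isinstance(X_new, SpectraSet):
        if X_new.wavelengths_nm.size != model.wavelengths_nm.size or not np.allclose(
            X_new.wavelengths_nm, model.wavelengths_nm
        ):
            raise ValueError("wavelength grid of X_new does not match the training window")
        Xraw = X_new.absorbance
    else:
        Xraw = np.atleast_2d(np.asarray(X_new, dtype=float))
        if Xraw.shape[1] != model.x_means.size:
            raise ValueError("column count of X_new does not match the training window")
    return (Xraw - model.x_means) @ model.coefficients + model.y_means


def loo_cross_validate(
    X,
    Y,
    max_lv: int,
    kind: str = "PLS",
    selection_rtol: float = 1e-3,
    selection_atol: float = 1e-8,
) -> CVCurve:
    """Leave-one-out cross-validation over 0…``max_lv`` latent variables.

    Level 0 is the mean-only model (RMSECV equals the per-analyte SD of Y
    around the leave-one-out mean, n denominator). Every fold refits the
    engine on the remaining samples, re-centering both blocks. The selected
    count is the smallest one whose analyte-averaged RMSECV lies within
    ``max(selection_atol, selection_rtol · min)`` of the global minimum —
    a parsimony rule that returns the minimum-error model while ignoring
    numerically meaningless improvements.
    """
    Xraw, Y, _ = _as_xy(X, Y)
    n, m = Y.shape
    if max_lv > n - 2:
        raise ValueError("max_lv must be <= n_samples - 2")
    fit = {"PLS": fit_pls, "PCR": fit_pcr}[kind.upper()]
    lv_counts = np.arange(0, max_lv + 1)
    press = np.zeros((max_lv + 1, m))
    valid = np.ones(max_lv + 1, dtype=bool)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, Ytr = Xraw[keep], Y[keep]
        press[0] += (Ytr.mean(axis=0) - Y[i]) ** 2
        for lv in range(1, max_lv + 1):
            if not valid[lv]:
                continue
            try:
                model = fit(Xtr, Ytr, lv)
            except np.linalg.LinAlgError:
                # the data have no more extractable components on this fold
                valid[lv:] = False
                break
            press[lv] += (predict(model, Xraw[i:i + 1])[0] - Y[i]) ** 2
    rmsecv = np.sqrt(press / n)
    rmsecv[~valid] = np.nan
    mean_curve = rmsecv.mean(axis=1)
    best = np.nanmin(mean_curve)
    tol = max(selection_atol, selection_rtol * best)
    eligible = np.nonzero(valid & (mean_curve <= best + tol))[0]
    selected = int(lv_counts[eligible[0]])
    return CVCurve(lv_counts, rmsecv, selected)
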