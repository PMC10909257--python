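"""Multivariate curve resolution by alternating least squares (MCR-ALS).

The absorbance matrix is modelled bilinearly, D ≈ C Sᵀ, with C the sample ×
component concentration profiles and S the wavelength × component spectral
profiles — the Beer-Lambert law extended over the full wavelength window.
Starting from an initial spectral estimate (purest-sample selection by a
maximum-volume criterion, or user-provided spectra), the two factors are
refined alternately by least squares under constraints:

* non-negativity on C and/or S, enforced by per-row/per-column NNLS
  (active-set) or, optionally, by fast clipping of the unconstrained solution;
* a correlation constraint on C: each component's ALS concentration column is
  regressed on the matching reference concentration column over the
  calibration rows (c_als ≈ a + b·c_ref) and the whole column is transformed
  by (c − a)/b. This inner calibration anchors the resolved concentrations in
  real units (µg/mL), fixes the component permutation and removes the
  intensity ambiguity of the bilinear model.

Convergence is declared when the relative change in the lack of fit between
consecutive iterations drops below the tolerance (default 0.1%, the curve
resolution toolbox convention). Prediction of a new sample follows the
one-by-one scheme: the test spectrum is appended to the calibration matrix,
the ALS is re-run from the fitted spectra with the correlation constraint
restricted to the calibration rows, and the test row of C is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .synthetic_data import SpectraSet

__all__ = [
    "MCRConfig",
    "MCRModel",
    "fit_mcr_als",
    "predict_mcr",
    "lack_of_fit",
    "explained_variance",
    "match_components",
    "purest_rows",
]

_DEFAULT_CONSTRAINTS = frozenset({"non-negativity-C", "non-negativity-S", "correlation"})


@dataclass(frozen=True)
class MCRConfig:
    """Constraint set and convergence policy for the ALS refinement.

    ``convergence_tol`` is the relative lack-of-fit change between consecutive
    iterations, in percent of the previous LOF (0.1 → stop when LOF changes by
    less than 0.1% of itself). ``nnls=False`` switches non-negativity from
    active-set NNLS to clipping of the unconstrained least-squares solution.
    """

    n_components: int = 4
    constraints: frozenset = _DEFAULT_CONSTRAINTS
    convergence_tol: float = 0.1
    max_iter: int = 100
    init: str = "purest-variables"      # or "provided-spectra"
    init_spectra: np.ndarray | None = None
    nnls: bool = True
    divergence_slack: float = 1e-6      # tolerated relative LOF increase
    max_divergence: int = 10            # consecutive rises before aborting

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        unknown = set(self.constraints) - {
            "non-negativity-C", "non-negativity-S", "correlation",
        }
        if unknown:
            raise ValueError(f"unsupported constraints: {unknown}")


@dataclass
class MCRModel:
    """Resolved profiles and the optimization trace."""

    S: np.ndarray                  # wavelengths × K
    C: np.ndarray                  # samples × K (µg/mL once correlation is on)
    lof_trace: list
    r2: float
    n_iter: int
    correlation_fit: np.ndarray    # K × 2 columns (slope, intercept)
    config: MCRConfig
    wavelengths_nm: np.ndarray
    converged: bool


def lack_of_fit(D: np.ndarray, S: np.ndarray, C: np.ndarray) -> float:
    """% lack of fit: 100·√(Σe² / Σd²) with E = D − C Sᵀ."""
    D = np.asarray(D, dtype=float)
    ss_d = float(np.sum(D * D))
    if ss_d == 0:
        raise ValueError("lack of fit is undefined for an all-zero data matrix")
    E = D - C @ S.T
    return 100.0 * np.sqrt(float(np.sum(E * E)) / ss_d)


def explained_variance(D: np.ndarray, S: np.ndarray, C: np.ndarray) -> float:
    """% explained variance: R² = 100·(1 − Σe²/Σd²) = 100 − LOF²/100."""
    lof = lack_of_fit(D, S, C)
    return 100.0 - lof * lof / 100.0


def purest_rows(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` most mutually dissimilar rows of ``D``.

    Greedy maximum-volume selection on length-normalized rows (a determinant
    purest-variable criterion): start from the row with the largest norm, then
    repeatedly add the row whose component orthogonal to the span of the
    selection is largest.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    norms = np.linalg.norm(D, axis=1)
    Dn = D / np.where(norms == 0, 1.0, norms)[:, None]
    selected = [int(np.argmax(norms))]
    basis = Dn[selected[0]][None, :] / max(np.linalg.norm(Dn[selected[0]]), 1e-300)
    for _ in range(1, k):
        proj = Dn - (Dn @ basis.T) @ basis
        resid = np.linalg.norm(proj, axis=1)
        resid[selected] = -np.inf
        nxt = int(np.argmax(resid))
        selected.append(nxt)
        v = proj[nxt]
        basis = np.vstack([basis, v / max(np.linalg.norm(v), 1e-300)])
    return np.asarray(selected, dtype=int)


def match_components(resolved: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Column permutation aligning ``resolved`` to ``reference`` by max correlation.

    Returns ``perm`` such that ``resolved[:, perm[j]]`` corresponds to
    ``reference[:, j]`` (Hungarian assignment on |Pearson r|).
    """
    K = reference.shape[1]
    corr = np.zeros((K, resolved.shape[1]))
    for j in range(K):
        for l in range(resolved.shape[1]):
            r = np.corrcoef(reference[:, j], resolved[:, l])[0, 1]
            corr[j, l] = 0.0 if np.isnan(r) else abs(r)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm


def _solve_rows(A: np.ndarray, B: np.ndarray, nonneg: bool, use_nnls: bool) -> np.ndarray:
    """Minimize ||B − X Aᵀ|| row-wise for X (B: n×m, A: m×K → X: n×K)."""
    if not nonneg:
        return np.linalg.lstsq(A, B.T, rcond=None)[0].T
    if not use_nnls:
        return np.clip(np.linalg.lstsq(A, B.T, rcond=None)[0].T, 0.0, None)
    X = np.empty((B.shape[0], A.shape[1]))
    for i in range(B.shape[0]):
        X[i], _ = nnls(A, B[i])
    return X


def _als(
    D: np.ndarray,
    C_ref: np.ndarray | None,
    cal_rows: np.ndarray,
    config: MCRConfig,
    S0: np.ndarray,
    match_reference: bool,
) -> MCRModel:
    nn_c = "non-negativity-C" in config.constraints
    nn_s = "non-negativity-S" in config.constraints
    correlate = "correlation" in config.constraints and C_ref is not None
    K = config.n_components
    S = np.asarray(S0, dtype=float).copy()
    corr_fit = np.full((K, 2), np.nan)
    lof_trace: list[float] = []
    prev_lof = None
    converged = False
    n_diverging = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        C = _solve_rows(S, D, nn_c, config.nnls)
        if correlate:
            if it == 1 and match_reference:
                perm = match_components(C[cal_rows], C_ref)
                C, S = C[:, perm], S[:, perm]
            test_rows = np.setdiff1d(np.arange(C.shape[0]), cal_rows)
            for k in range(K):
                ref = C_ref[:, k]
                x = np.column_stack([np.ones(ref.size), ref])
                a, b = np.linalg.lstsq(x, C[cal_rows, k], rcond=None)[0]
                if abs(b) < 1e-12:
                    raise np.linalg.LinAlgError(
                        f"correlation constraint: component {k} is uncorrelated with its reference"
                    )
                # calibration entries: fitted values of the inner calibration
                # line, back-transformed to reference units (= the reference
                # concentrations); unknown rows: back-transformed ALS values
                C[cal_rows, k] = ref
                if test_rows.size:
                    C[test_rows, k] = (C[test_rows, k] - a) / b
                corr_fit[k] = (b, a)
        S = _solve_rows(C, D.T, nn_s, config.nnls)
        ctc = C.T @ C
        sts = S.T @ S
        if min(np.linalg.matrix_rank(ctc), np.linalg.matrix_rank(sts)) < K:
            raise np.linalg.LinAlgError("CᵀC or SᵀS became singular during ALS")
        lof = lack_of_fit(D, S, C)
        lof_trace.append(lof)
        if prev_lof is not None:
            if lof > prev_lof * (1.0 + config.divergence_slack) and lof > 1e-10:
                # constrained ALS may rise transiently while the constraints
                # reshape the profiles; abort only on a sustained climb
                n_diverging += 1
                if n_diverging >= config.max_divergence:
                    raise RuntimeError(
                        f"ALS diverged: lack of fit increased for "
                        f"{config.max_divergence} consecutive iterations "
                        f"(last {lof:.6g}%)"
                    )
            else:
                n_diverging = 0
            rel_change = abs(prev_lof - lof) / max(prev_lof, 1e-300) * 100.0
            if rel_change < config.convergence_tol:
                converged = True
                break
        if lof < 1e-10:  # exact reconstruction; nothing left to refine
            converged = True
            break
        prev_lof = lof
    r2 = explained_variance(D, S, C)
    return MCRModel(
        S=S,
        C=C,
        lof_trace=lof_trace,
        r2=r2,
        n_iter=it,
        correlation_fit=corr_fit,
        config=config,
        wavelengths_nm=np.array([]),
        converged=converged,
    )


def _as_matrix(D) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(D, SpectraSet):
        return D.absorbance, D.wavelengths_nm
    D = np.atleast_2d(np.asarray(D, dtype=float))
    return D, np.arange(D.shape[1], dtype=float)


def fit_mcr_als(D, C_ref: np.ndarray | None, config: MCRConfig | None = None) -> MCRModel:
    """Resolve ``D`` into K concentration and spectral profiles under constraints.

    ``C_ref`` holds the known calibration concentrations (one column per
    component, row-aligned with ``D``); it is required whenever the
    correlation constraint is active and ignored otherwise.
    """
    config = config or MCRConfig()
    Dm, wl = _as_matrix(D)
    if C_ref is not None:
        C_ref = np.atleast_2d(np.asarray(C_ref, dtype=float))
        if C_ref.shape[0] != Dm.shape[0]:
            raise ValueError("D and C_ref must be row-aligned")
    if "correlation" in config.constraints and C_ref is None:
        raise ValueError("correlation constraint requires reference concentrations")
    if config.init == "provided-spectra":
        if config.init_spectra is None:
            raise ValueError("init='provided-spectra' requires init_spectra")
        S0 = np.asarray(config.init_spectra, dtype=float)
        if S0.shape != (Dm.shape[1], config.n_components):
            raise ValueError("init_spectra must be n_wavelengths × n_components")
        match = False
    elif config.init == "purest-variables":
        S0 = Dm[purest_rows(Dm, config.n_components)].T
        match = True
    else:
        raise ValueError("init must be 'purest-variables' or 'provided-spectra'")
    cal_rows = np.arange(Dm.shape[0])
    model = _als(Dm, C_ref, cal_rows, config, S0, match_reference=match)
    model.wavelengths_nm = wl
    return model


def predict_mcr(
    model: MCRModel,
    test_spectrum,
    C_ref: np.ndarray,
    D_cal,
) -> np.ndarray:
    """One-by-one test-sample prediction (µg/mL).

    The test spectrum is appended to the calibration matrix, the ALS re-runs
    from the fitted spectral profiles, and the correlation constraint uses the
    calibration rows only; the resolved test row of C is returned.
    """
    Dm, _ = _as_matrix(D_cal)
    Tm, _ = _as_matrix(test_spectrum)
    if Tm.shape[0] != 1:
        raise ValueError("predict_mcr handles exactly one test sample per call")
    if Tm.shape[1] != Dm.shape[1]:
        raise ValueError("test spectrum wavelength count does not match calibration data")
    D_aug = np.vstack([Dm, Tm])
    config = replace(model.config, init="provided-spectra", init_spectra=model.S)
    cal_rows = np.arange(Dm.shape[0])
    refined = _als(D_aug, C_ref, cal_rows, config, model.S, match_reference=False)
    return refined.C[-1]
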