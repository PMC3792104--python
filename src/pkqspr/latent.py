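"""NIPALS latent-variable models: PCA calibration and multi-response PLS.

PCA is used to calibrate the chemical space before regression: compounds far
outside the descriptor cloud (Hotelling T² beyond the 95% F-critical value)
are flagged as outliers.  The regression itself is PLS2 — both responses,
log10 V_ss and f_u, are modeled with shared latent components, on the
hypothesis that the same physicochemical axes (lipophilicity vs. solubility/
charge) drive both endpoints with opposite signs.

All matrices entering these routines are assumed autoscaled (see
:mod:`pkqspr.preprocess`).  Components are extracted one at a time by NIPALS
iteration with deflation; convergence tolerance 1e-10, at most 500 iterations
per component.

Notation (columns indexed by component a = 1..A):

* ``W``  — X-weights (unit norm), ``W*`` = W (PᵀW)⁻¹ rotated weights
* ``P``  — X-loadings, ``T`` — X-scores, ``C`` — Y-loadings (m x A)
* ``B``  = W* Cᵀ — regression coefficients on the scaled spaces
* VIP_j  = sqrt(p Σ_a SSY_a w_ja² / Σ_a SSY_a), so mean(VIP²) = 1
* Q²     = 1 − PRESS/SS with 1/7 of the compounds left out per fold
* DModX  — observation residual SD normalized by the pooled model residual SD
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PCAModel",
    "PLSModel",
    "fit_pca",
    "pca_q2x",
    "hotelling_outliers",
    "fit_pls2",
    "cross_validate_q2",
    "vip_scores",
    "weight_plot_data",
    "dmodx",
    "reduce_variables",
    "select_n_components",
]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 5000
# if the iteration stalls above the target tolerance (near-degenerate
# eigenvalues), accept once the relative score change is below this floor
NIPALS_ACCEPT = 1e-7


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y.reshape(-1, 1) if Y.ndim == 1 else Y


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    n_components: int
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A), orthonormal columns
    r2x_per_component: np.ndarray
    r2x_cum: np.ndarray
    q2x: float | None = None
    score_variances: np.ndarray | None = None  # for Hotelling T²
    n_train: int = 0

    def project(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.loadings

    def hotelling_t2(self, X: np.ndarray | None = None) -> np.ndarray:
        T = self.scores if X is None else self.project(X)
        return np.sum(T**2 / self.score_variances, axis=1)

    def hotelling_critical(self, alpha: float = 0.05) -> float:
        n, A = self.n_train, self.n_components
        f_crit = stats.f.ppf(1 - alpha, A, n - A)
        return A * (n - 1) * (n + 1) / (n * (n - A)) * f_crit


def _nipals_component(X: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """One PCA component (t, p) by NIPALS power iteration."""
    variances = np.nansum(X**2, axis=0)
    t = X[:, int(np.argmax(variances))].copy()
    if np.allclose(t, 0):
        raise np.linalg.LinAlgError("deflated matrix is zero; too many components requested")
    change = np.inf
    for _ in range(max_iter):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
        t = t_new
        if change <= tol:
            break
    if change > NIPALS_ACCEPT:
        raise np.linalg.LinAlgError("NIPALS PCA did not converge")
    return t, p


def fit_pca(X: np.ndarray, n_components: int, tol: float = NIPALS_TOL, max_iter: int = NIPALS_MAX_ITER) -> PCAModel:
    """Fit a NIPALS PCA with deflation on an autoscaled matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    ss_total = np.sum(X**2)
    E = X.copy()
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    r2 = np.zeros(n_components)
    for a in range(n_components):
        t, pa = _nipals_component(E, tol, max_iter)
        T[:, a] = t
        P[:, a] = pa
        E = E - np.outer(t, pa)
        r2[a] = (t @ t) / ss_total
    return PCAModel(
        n_components=n_components,
        scores=T,
        loadings=P,
        r2x_per_component=r2,
        r2x_cum=np.cumsum(r2),
        score_variances=T.var(axis=0, ddof=1),
        n_train=n,
    )


def _nipals_component_missing(X: np.ndarray, mask: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
    """One PCA component on a matrix with masked (deleted) elements."""
    Xf = np.where(mask, X, 0.0)
    t = Xf[:, int(np.argmax(np.sum(Xf**2, axis=0)))].copy()
    if np.allclose(t, 0):
        t = np.ones(X.shape[0])
    for _ in range(max_iter):
        # p_j from rows where x_ij observed
        num = (Xf.T * t).sum(axis=1)
        den = (mask.T * t**2).sum(axis=1)
        p = num / np.where(den == 0, 1.0, den)
        nrm = np.linalg.norm(p)
        if nrm == 0:
            break
        p /= nrm
        num_t = Xf @ p
        den_t = mask @ p**2
        t_new = num_t / np.where(den_t == 0, 1.0, den_t)
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    return t, p


def pca_q2x(X: np.ndarray, n_components: int, n_groups: int = 7) -> float:
    """Cross-validated Q²X by element-wise deletion in ``n_groups`` diagonal groups.

    For each component the elements of each deletion group are held out in
    turn, the component is refit on the remaining elements, and the held-out
    elements are predicted; Q²X(cum) = 1 − Π_a PRESS_a / SS_a.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    flat_groups = (np.arange(n)[:, None] * p + np.arange(p)[None, :]) % n_groups
    E = X.copy()
    ratio = 1.0
    for _ in range(n_components):
        ss = np.sum(E**2)
        press = 0.0
        for g in range(n_groups):
            mask = flat_groups != g
            t, pl = _nipals_component_missing(E, mask)
            recon = np.outer(t, pl)
            press += np.sum((E[~mask] - recon[~mask]) ** 2)
        ratio *= press / ss
        t, pl = _nipals_component(E, NIPALS_TOL, NIPALS_MAX_ITER)
        E = E - np.outer(t, pl)
    return 1.0 - ratio


def hotelling_outliers(model: PCAModel, alpha: float = 0.05, ids: Sequence[str] | None = None):
    """Indices (or ids) of observations beyond the Hotelling T² critical value."""
    t2 = model.hotelling_t2()
    crit = model.hotelling_critical(alpha)
    idx = np.where(t2 > crit)[0]
    if ids is not None:
        return [ids[i] for i in idx]
    return idx


# ---------------------------------------------------------------------------
# PLS2
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray  # W (p, A), unit columns
    weights_star: np.ndarray  # W* = W (P'W)^-1
    x_loadings: np.ndarray  # P (p, A)
    scores: np.ndarray  # T (n, A)
    y_loadings: np.ndarray  # C (m, A)
    coef: np.ndarray  # B (p, m) on scaled space
    r2y: float = np.nan
    r2y_per_component: np.ndarray | None = None
    q2: float | None = None
    vip: np.ndarray | None = None
    response_names: tuple[str, ...] = ("logVss", "fu")
    variable_names: list[str] = field(default_factory=list)
    dmodx_s0: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict scaled responses for an autoscaled X."""
        return np.asarray(X, dtype=float) @ self.coef

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights_star

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "weights_star": self.weights_star.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "r2y": self.r2y,
            "q2": self.q2,
            "vip": None if self.vip is None else self.vip.tolist(),
            "response_names": list(self.response_names),
            "variable_names": self.variable_names,
            "dmodx_s0": self.dmodx_s0,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_components=d["n_components"],
            weights=np.asarray(d["weights"]),
            weights_star=np.asarray(d["weights_star"]),
            x_loadings=np.asarray(d["x_loadings"]),
            scores=np.empty((0, d["n_components"])),
            y_loadings=np.asarray(d["y_loadings"]),
            coef=np.asarray(d["coef"]),
            r2y=d.get("r2y", np.nan),
            q2=d.get("q2"),
            vip=None if d.get("vip") is None else np.asarray(d["vip"]),
            response_names=tuple(d.get("response_names", ("logVss", "fu"))),
            variable_names=d.get("variable_names", []),
            dmodx_s0=d.get("dmodx_s0", np.nan),
        )


def fit_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
    response_names: Sequence[str] | None = None,
    variable_names: Sequence[str] | None = None,
) -> PLSModel:
    """Fit multi-response PLS (PLS2) by NIPALS with deflation.

    ``X`` (n x p) and ``Y`` (n x m) must be autoscaled; rows with missing Y
    must be removed beforehand.  For a single response the inner loop
    converges in one pass and reduces to classical PLS1.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    m = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if np.any(np.isnan(Y)):
        raise ValueError("Y contains missing values; drop or impute before fitting")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("degenerate Y: zero-variance response")

    E, F = X.copy(), Y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    C = np.zeros((m, n_components))
    ssy_total = np.sum(Y**2)
    r2y_comp = np.zeros(n_components)
    for a in range(n_components):
        u = F[:, int(np.argmax(np.sum(F**2, axis=0)))].copy()
        if np.allclose(u, 0):
            raise np.linalg.LinAlgError("Y fully deflated; too many components")
        t_old = np.zeros(n)
        change = np.inf
        for _ in range(max_iter):
            w = E.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise np.linalg.LinAlgError("zero weight vector; X fully deflated")
            w /= nw
            t = E @ w
            c = F.T @ t / (t @ t)
            u = F @ c / (c @ c)
            change = np.linalg.norm(t - t_old) / max(np.linalg.norm(t), 1e-300)
            t_old = t
            if change <= tol:
                break
        if change > NIPALS_ACCEPT:
            raise np.linalg.LinAlgError("NIPALS PLS did not converge")
        pa = E.T @ t / (t @ t)
        E = E - np.outer(t, pa)
        F = F - np.outer(t, c)
        W[:, a], P[:, a], T[:, a], C[:, a] = w, pa, t, c
        r2y_comp[a] = (t @ t) * (c @ c) / ssy_total

    W_star = W @ np.linalg.inv(P.T @ W)
    B = W_star @ C.T
    resid = Y - T @ C.T
    r2y = 1.0 - np.sum(resid**2) / ssy_total
    ex = X - T @ P.T
    dof = (n - n_components - 1) * (p - n_components)
    s0 = np.sqrt(np.sum(ex**2) / dof) if dof > 0 else np.nan
    model = PLSModel(
        n_components=n_components,
        weights=W,
        weights_star=W_star,
        x_loadings=P,
        scores=T,
        y_loadings=C,
        coef=B,
        r2y=r2y,
        r2y_per_component=r2y_comp,
        response_names=tuple(response_names) if response_names else tuple(f"y{k}" for k in range(m)),
        variable_names=list(variable_names) if variable_names else [f"x{j}" for j in range(p)],
        dmodx_s0=s0,
    )
    model.vip = vip_scores(model)
    return model


def cross_validate_q2(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    n_folds: int = 7,
    seed: int = 0,
) -> dict:
    """Q² by leaving out 1/``n_folds`` of the compounds at a time.

    Each compound is predicted exactly once while excluded from fitting.
    Q² = 1 − PRESS/SS per response, with SS the centered total sum of squares
    of the supplied (scaled) Y; the pooled value uses summed PRESS and SS.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("fewer compounds than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 compounds")
    pred = np.full_like(Y, np.nan)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        sub = fit_pls2(X[mask], Y[mask], min(n_components, mask.sum() - 1, X.shape[1]))
        pred[fold] = X[fold] @ sub.coef
    press = np.sum((Y - pred) ** 2, axis=0)
    ss = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    q2_per = 1.0 - press / ss
    return {
        "per_response": q2_per,
        "pooled": float(1.0 - press.sum() / ss.sum()),
        "predictions": pred,
    }


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; mean of VIP² equals 1."""
    W = model.weights
    T = model.scores
    C = model.y_loadings
    p, A = W.shape
    ssy = np.array([(T[:, a] @ T[:, a]) * (C[:, a] @ C[:, a]) for a in range(A)])
    denom = ssy.sum()
    if denom == 0:
        return np.ones(p)
    w2 = W**2  # columns already unit norm
    return np.sqrt(p * (w2 @ ssy) / denom)


def weight_plot_data(model: PLSModel):
    """Coordinates for the PLS weight (w*c) plot and signed response projections.

    Returns a DataFrame with each variable's rotated weights on components 1–2,
    the response loadings on the same plane, and each variable's signed
    orthogonal projection onto each response direction: a positive projection
    means the descriptor pushes that response up.
    """
    import pandas as pd

    if model.n_components < 2:
        raise ValueError("weight plot needs at least 2 components")
    V = model.weights_star[:, :2]
    R = model.y_loadings[:, :2]  # (m, 2)
    rows = {}
    for k, rname in enumerate(model.response_names):
        direction = R[k]
        nrm = np.linalg.norm(direction)
        rows[f"proj_{rname}"] = V @ direction / (nrm if nrm > 0 else 1.0)
    df = pd.DataFrame({"variable": model.variable_names, "wc1": V[:, 0], "wc2": V[:, 1], **rows})
    responses = pd.DataFrame(
        {"response": list(model.response_names), "wc1": R[:, 0], "wc2": R[:, 1]}
    )
    return df, responses


def dmodx(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Normalized distance to the model plane per observation.

    Residual SD of each row (after removing the A latent dimensions), divided
    by the pooled training residual SD; training observations average about 1.
    """
    X = np.asarray(X, dtype=float)
    T = model.transform(X)
    E = X - T @ model.x_loadings.T
    p, A = model.x_loadings.shape
    si = np.sqrt(np.sum(E**2, axis=1) / (p - A))
    si[si < 1e-10] = 0.0  # exactly in-plane observations
    s0 = model.dmodx_s0 if model.dmodx_s0 > 1e-12 else 1.0
    return si / s0


def select_n_components(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int = 10,
    min_improvement: float = 0.01,
    n_folds: int = 7,
    seed: int = 0,
) -> int:
    """Add components while pooled Q² improves by more than ``min_improvement``."""
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    cap = min(max_components, X.shape[0] - 1 - X.shape[0] // n_folds, X.shape[1])
    best_a, best_q2 = 1, -np.inf
    for a in range(1, cap + 1):
        q2 = cross_validate_q2(X, Y, a, n_folds=n_folds, seed=seed)["pooled"]
        if q2 > best_q2 + (min_improvement if a > 1 else -np.inf):
            best_a, best_q2 = a, q2
        else:
            break
    return best_a


def reduce_variables(
    X: np.ndarray,
    Y: np.ndarray,
    variable_names: Sequence[str] | None = None,
    vip_cutoff: float = 0.8,
    max_rounds: int = 10,
    n_components: int | None = None,
    n_folds: int = 7,
    seed: int = 0,
) -> tuple[list[str], PLSModel, list[dict]]:
    """Iterative VIP-based variable reduction.

    Variables with VIP below the cutoff are dropped and the model refit; the
    procedure stops when cross-validated Q² no longer improves, no variable
    falls below the cutoff, or ``max_rounds`` is reached.  Returns the selected
    variable names, the final model, and an audit trail of per-round Q² and
    removals.
    """
    if vip_cutoff < 0:
        raise ValueError("vip_cutoff must be >= 0")
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    names = list(variable_names) if variable_names else [f"x{j}" for j in range(X.shape[1])]
    current = list(range(X.shape[1]))
    audit: list[dict] = []

    def fit_current(cols):
        Xc = X[:, cols]
        a = n_components if n_components is not None else select_n_components(Xc, Y, seed=seed)
        a = min(a, len(cols), Xc.shape[0] - 1)
        mdl = fit_pls2(Xc, Y, a, variable_names=[names[j] for j in cols])
        mdl.q2 = cross_validate_q2(Xc, Y, a, n_folds=n_folds, seed=seed)["pooled"]
        return mdl

    model = fit_current(current)
    best_model, best_cols = model, list(current)
    audit.append({"round": 0, "n_variables": len(current), "q2": model.q2, "removed": []})
    for rnd in range(1, max_rounds + 1):
        low = np.where(model.vip < vip_cutoff)[0]
        if low.size == 0 or low.size == len(current):
            if low.size == len(current):
                audit.append({"round": rnd, "n_variables": len(current), "q2": model.q2,
                              "removed": [], "note": "all variables below cutoff; stopping"})
            break
        removed = [model.variable_names[j] for j in low]
        current = [c for k, c in enumerate(current) if k not in set(low.tolist())]
        model = fit_current(current)
        audit.append({"round": rnd, "n_variables": len(current), "q2": model.q2, "removed": removed})
        if model.q2 > best_model.q2:
            best_model, best_cols = model, list(current)
        else:
            break
    if not best_cols:
        raise ValueError("variable reduction removed every variable")
    return [names[j] for j in best_cols], best_model, audit
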