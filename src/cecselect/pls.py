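"""Multi-response PLS regression by NIPALS.

The model projects a centered/scaled explanatory block X (n x K) and
response block Y (n x M) onto A latent components chosen to maximize the
covariance between the blocks' score vectors.  Full NIPALS-2 is used: both
blocks are deflated, so Y-side scores U are available, while predictions
depend only on X-side quantities.  Everything is deterministic — the inner
loop starts from the residual-Y column of largest variance, never from a
random vector.

Scaling defaults to unit variance (sample sd, n-1 denominator) on both
blocks; constant columns are given scale 1 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError

NIPALS_TOL = 1e-10

# NIPALS converges linearly at rate sigma2^2/sigma1^2 of the residual
# cross-covariance; near-tied singular values need well over 500 sweeps to
# push the relative score change below NIPALS_TOL, so the budget is generous.
NIPALS_MAX_ITER = 2000


def autoscale(
    values: np.ndarray, policy: str = "uv"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering/scaling.

    Policies: ``uv`` (unit variance), ``center_only``, ``pareto`` (scale by
    the square root of the sd).  Returns (scaled, center, scale, flags) where
    flags marks zero-variance columns (scale forced to 1).
    """
    if policy not in ("uv", "center_only", "pareto"):
        raise ValidationError(f"unknown scaling policy {policy!r}")
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("autoscale requires a missing-free grid")
    center = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    flags = sd == 0
    if policy == "center_only":
        scale = np.ones_like(sd)
    else:
        base = np.where(flags, 1.0, sd)
        scale = base if policy == "uv" else np.sqrt(base)
        scale = np.where(flags, 1.0, scale)
    return (arr - center) / scale, center, scale, flags


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray     # W, K x A, unit-norm columns
    x_loadings: np.ndarray    # P, K x A
    y_weights: np.ndarray     # C, M x A
    x_scores: np.ndarray      # T, n x A, mutually orthogonal columns
    y_scores: np.ndarray      # U, n x A
    coef: np.ndarray          # B, K x M, on the scaled spaces, cumulative
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    r2x: list[float]          # per-component share of scaled-X variance
    r2y: list[float]          # per-component share of scaled-Y variance
    x_names: list[str]
    y_names: list[str]
    scale_policy: str = "uv"
    x_const_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    y_const_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def check_invariants(self, tol: float = 1e-8) -> None:
        t = self.x_scores
        for i in range(self.n_components):
            for j in range(i + 1, self.n_components):
                lim = tol * np.linalg.norm(t[:, i]) * np.linalg.norm(t[:, j])
                if abs(t[:, i] @ t[:, j]) > lim:
                    raise ValidationError(f"score columns {i},{j} not orthogonal")
        norms = np.linalg.norm(self.x_weights, axis=0)
        if np.max(np.abs(norms - 1.0)) > tol:
            raise ValidationError("weight columns are not unit norm")
        if sum(self.r2x) > 1 + 1e-8 or sum(self.r2y) > 1 + 1e-8:
            raise ValidationError("per-component variance shares exceed 1")

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_names": self.x_names, "y_names": self.y_names,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_weights": self.y_weights.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_scores": self.y_scores.tolist(),
            "coef": self.coef.tolist(),
            "x_center": self.x_center.tolist(), "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center.tolist(), "y_scale": self.y_scale.tolist(),
            "r2x": self.r2x, "r2y": self.r2y,
            "scale_policy": self.scale_policy,
        }


def _as_array(block, names_hint: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(float), [str(c) for c in block.columns]
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{names_hint}{j + 1}" for j in range(arr.shape[1])]


def fit_pls(X, Y, n_components: int, *, scale_policy: str = "uv",
            tol: float = NIPALS_TOL, max_iter: int = NIPALS_MAX_ITER,
            truncate_on_nonconvergence: bool = False) -> PLSModel:
    """Fit an A-component NIPALS PLS model on autoscaled blocks.

    Per component: iterate w = X'u/|X'u|, t = Xw, c = Y't/t't, u = Yc/c'c to
    a relative tolerance on the score vector, then deflate both blocks by
    the rank-one component.  R2X_a and R2Y_a are the Frobenius shares of the
    initial scaled blocks captured by component a.

    Non-convergence of a component's inner loop raises by default; with
    ``truncate_on_nonconvergence`` the model is returned with the components
    fitted so far (cross-validation uses this: late components on an
    exhausted residual carry no structure worth failing over).
    """
    x_arr, x_names = _as_array(X, "x")
    y_arr, y_names = _as_array(Y, "y")
    n, k = x_arr.shape
    m = y_arr.shape[1]
    if y_arr.shape[0] != n:
        raise ValidationError("X and Y row counts differ")
    if n < 3:
        raise ValidationError("need at least 3 samples")
    if not 1 <= n_components <= min(n - 1, k):
        raise ValidationError(
            f"n_components={n_components} outside [1, min(n-1, K)={min(n - 1, k)}]")

    xs, x_center, x_scale, x_flags = autoscale(x_arr, scale_policy)
    ys, y_center, y_scale, y_flags = autoscale(y_arr, scale_policy)
    ssx0 = float((xs ** 2).sum())
    ssy0 = float((ys ** 2).sum())

    w_mat = np.zeros((k, n_components))
    p_mat = np.zeros((k, n_components))
    c_mat = np.zeros((m, n_components))
    t_mat = np.zeros((n, n_components))
    u_mat = np.zeros((n, n_components))
    r2x: list[float] = []
    r2y: list[float] = []
    xr, yr = xs.copy(), ys.copy()
    eps = np.finfo(float).tiny

    a_done = 0
    for a in range(n_components):
        col = int(np.argmax(yr.var(axis=0)))
        u = yr[:, col].copy()
        if np.linalg.norm(u) == 0:
            u = np.ones(n)
        t_old = None
        for _ in range(max_iter):
            w = xr.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError(f"component {a + 1}: X residual orthogonal to u")
            w /= nw
            t = xr @ w
            tt = t @ t
            if tt == 0:
                raise ConvergenceError(f"component {a + 1}: zero score vector")
            c = yr.T @ t / tt
            cc = c @ c
            if cc == 0:
                # Y residual exhausted; component still defined by X side
                break
            u = yr @ c / cc
            if t_old is not None:
                if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), eps):
                    break
            t_old = t
        else:
            if not truncate_on_nonconvergence:
                raise ConvergenceError(
                    f"component {a + 1}: no convergence in {max_iter} iterations")
            if a > 0:
                break
            # first component of a structureless block: singular values are
            # near-tied and any direction in the top subspace is
            # prediction-equivalent, so keep the final iterate
        t = xr @ w
        tt = t @ t
        c = yr.T @ t / tt
        p = xr.T @ t / tt
        xr = xr - np.outer(t, p)
        yr = yr - np.outer(t, c)
        w_mat[:, a], p_mat[:, a], c_mat[:, a] = w, p, c
        t_mat[:, a] = t
        u_mat[:, a] = u
        r2x.append(float(tt * (p @ p) / ssx0) if ssx0 > 0 else 0.0)
        r2y.append(float(tt * (c @ c) / ssy0) if ssy0 > 0 else 0.0)
        a_done = a + 1

    if a_done < n_components:
        w_mat, p_mat, c_mat = w_mat[:, :a_done], p_mat[:, :a_done], c_mat[:, :a_done]
        t_mat, u_mat = t_mat[:, :a_done], u_mat[:, :a_done]
        n_components = a_done
    pw = p_mat.T @ w_mat
    coef = w_mat @ np.linalg.solve(pw, c_mat.T)
    model = PLSModel(
        n_components=n_components, x_weights=w_mat, x_loadings=p_mat,
        y_weights=c_mat, x_scores=t_mat, y_scores=u_mat, coef=coef,
        x_center=x_center, x_scale=x_scale, y_center=y_center, y_scale=y_scale,
        r2x=r2x, r2y=r2y, x_names=x_names, y_names=y_names,
        scale_policy=scale_policy, x_const_flags=x_flags, y_const_flags=y_flags,
    )
    model.check_invariants()
    return model


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Apply the stored scaling, coefficients, and inverse Y scaling."""
    arr, _ = _as_array(X_new, "x")
    if arr.shape[1] != len(model.x_center):
        raise ValidationError(
            f"X_new has {arr.shape[1]} columns, model expects {len(model.x_center)}")
    xs = (arr - model.x_center) / model.x_scale
    return xs @ model.coef * model.y_scale + model.y_center


def predict_per_component(model: PLSModel, X_new) -> np.ndarray:
    """Cumulative predictions using the first a components, a = 1..A.

    Returns an (A, n_new, M) array on the original Y scale; the last slice
    equals :func:`predict`.  New rows are projected through the same
    deflation sequence as training rows.
    """
    arr, _ = _as_array(X_new, "x")
    if arr.shape[1] != len(model.x_center):
        raise ValidationError("column count mismatch")
    xs = (arr - model.x_center) / model.x_scale
    out = np.empty((model.n_components, arr.shape[0], len(model.y_center)))
    yhat_s = np.zeros((arr.shape[0], len(model.y_center)))
    xr = xs.copy()
    for a in range(model.n_components):
        t = xr @ model.x_weights[:, a]
        xr = xr - np.outer(t, model.x_loadings[:, a])
        yhat_s = yhat_s + np.outer(t, model.y_weights[:, a])
        out[a] = yhat_s * model.y_scale + model.y_center
    return out


def choose_components(
    X, Y, *, folds: int = 7, seed: int = 0, gain_threshold: float = 0.01,
    A_max: int | None = None, site_of=None,
) -> int:
    """Smallest-adequate component count by cross-validated gain.

    Components are added while the Q2Cum improvement of component a over
    a-1 is at least ``gain_threshold``; at least one component is always
    returned.
    """
    from .crossval import cumulative_q2  # local import to avoid a cycle

    x_arr, _ = _as_array(X, "x")
    n, k = x_arr.shape
    if A_max is None:
        A_max = min(n - 1, k, 10)
    A_max = max(1, min(A_max, n - 1 - n // folds, k)) if folds < n else min(A_max, n - 2, k)
    q2cum = cumulative_q2(X, Y, A_max, folds=folds, seed=seed, site_of=site_of)
    best, prev = 1, 0.0
    for a in range(1, A_max + 1):
        if q2cum[a - 1] - prev >= gain_threshold:
            best = a
            prev = q2cum[a - 1]
        else:
            break
    return best
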