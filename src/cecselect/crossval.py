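"""Cross-validated assessment of the PLS model.

Per response j the fold-wise predictive residual sum of squares PRESS_j is
compared against the cross-validated null SS0_j (training-fold mean as
predictor), giving Q2Y_j = 1 - PRESS_j/SS0_j and the pooled
Q2Cum = 1 - sum(PRESS)/sum(SS0).  Scaling and the PLS fit are refit inside
every training fold (no leakage) and residuals are taken on the original Y
scale.  Per-response significance follows the CV-ANOVA idea: an F statistic
on the predictive gain, F_j = ((SS0_j - PRESS_j)/A) / (PRESS_j/(n - A - 1))
with (A, n - A - 1) degrees of freedom.

Variable importance in projection (VIP) summarizes each X variable's
contribution to the explained Y variance across components; mean squared
VIP equals 1 by construction.  VIP inference is by delete-one-fold
jackknife: VIP is recomputed on every training fold, and a one-sided t
statistic tests H0: VIP <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .pls import PLSModel, _as_array, fit_pls, predict_per_component


def assign_folds(
    n: int, folds: int, seed: int, site_of=None, *, stratify: bool = True
) -> np.ndarray:
    """Seeded fold assignment, site-stratified round-robin.

    Samples are shuffled within each site and dealt to folds in a global
    round-robin, so every fold mixes sites.  Depends only on (n, folds,
    seed, site labels) — never on data values.  Leave-one-out (folds == n)
    is exempt from the mixed-site check.
    """
    if folds < 2 or folds > n:
        raise ValidationError(f"folds must be in [2, n={n}]")
    rng = np.random.default_rng(seed)
    fold_idx = np.empty(n, dtype=int)
    if site_of is None or not stratify:
        order = rng.permutation(n)
    else:
        labels = np.asarray(site_of)
        order = np.concatenate([
            rng.permutation(np.flatnonzero(labels == s))
            for s in sorted(set(labels.tolist()))
        ])
    for pos, sample in enumerate(order):
        fold_idx[sample] = pos % folds
    if stratify and site_of is not None and folds < n:
        labels = np.asarray(site_of)
        for f in range(folds):
            if len(set(labels[fold_idx == f].tolist())) < 2:
                raise ValidationError(
                    f"fold {f} contains samples from a single site; "
                    "use more folds or disable stratification")
    return fold_idx


def _fold_press(X, Y, A: int, fold_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(PRESS per (a, j) for a = 1..A cumulative components, SS0 per j).

    Both on the original Y scale.  A is capped per fold at the training
    rank limit min(n_train - 1, K).
    """
    x_arr, _ = _as_array(X, "x")
    y_arr, _ = _as_array(Y, "y")
    n, k = x_arr.shape
    m = y_arr.shape[1]
    press = np.zeros((A, m))
    ss0 = np.zeros(m)
    for f in sorted(set(fold_idx.tolist())):
        test = fold_idx == f
        train = ~test
        a_eff = min(A, int(train.sum()) - 1, k)
        model = fit_pls(x_arr[train], y_arr[train], a_eff,
                        truncate_on_nonconvergence=True)
        a_got = model.n_components
        preds = predict_per_component(model, x_arr[test])  # (a_got, n_test, m)
        resid = y_arr[test][None, :, :] - preds
        sq = (resid ** 2).sum(axis=1)                      # (a_got, m)
        press[:a_got] += sq
        if a_got < A:                                      # cap: reuse best available
            press[a_got:] += sq[-1]
        ss0 += ((y_arr[test] - y_arr[train].mean(axis=0)) ** 2).sum(axis=0)
    return press, ss0


def cumulative_q2(X, Y, A: int, *, folds: int = 7, seed: int = 0,
                  site_of=None) -> np.ndarray:
    """Q2Cum for 1..A components (one cross-validation pass)."""
    x_arr, _ = _as_array(X, "x")
    fold_idx = assign_folds(x_arr.shape[0], folds, seed, site_of)
    press, ss0 = _fold_press(X, Y, A, fold_idx)
    tot0 = ss0.sum()
    if tot0 <= 0:
        return np.zeros(A)
    return 1.0 - press.sum(axis=1) / tot0


@dataclass
class CVResult:
    fold_assignment: np.ndarray
    press: np.ndarray            # per response
    ss0: np.ndarray              # per response
    q2y: np.ndarray              # per response
    q2cum: float
    n_samples: int
    n_components: int
    y_names: list[str]

    def anova_table(self) -> pd.DataFrame:
        rows = [cv_anova(self, j) for j in range(len(self.y_names))]
        return pd.DataFrame(rows, columns=["F", "p"],
                            index=pd.Index(self.y_names, name="response"))


def cross_validate(
    X, Y, A: int, *, folds: int = 7, seed: int = 0, site_of=None,
    fold_idx: np.ndarray | None = None,
) -> CVResult:
    """Fold-wise refit (scaling and PLS) and held-out prediction."""
    x_arr, _ = _as_array(X, "x")
    y_arr, y_names = _as_array(Y, "y")
    if isinstance(Y, pd.DataFrame):
        y_names = [str(c) for c in Y.columns]
    if fold_idx is None:
        fold_idx = assign_folds(x_arr.shape[0], folds, seed, site_of)
    press, ss0 = _fold_press(X, Y, A, fold_idx)
    press_a = press[A - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        q2y = np.where(ss0 > 0, 1.0 - press_a / np.where(ss0 > 0, ss0, 1.0), 0.0)
    tot0 = ss0.sum()
    q2cum = float(1.0 - press_a.sum() / tot0) if tot0 > 0 else 0.0
    return CVResult(fold_assignment=fold_idx, press=press_a, ss0=ss0,
                    q2y=q2y, q2cum=q2cum, n_samples=x_arr.shape[0],
                    n_components=A, y_names=y_names)


def cv_anova(cv: CVResult, j: int) -> tuple[float, float]:
    """Per-response F test of the cross-validated predictive gain.

    F_j = ((SS0_j - PRESS_j)/A) / (PRESS_j/(n - A - 1)), clamped at zero
    when the model does not beat the null; p is the upper F tail with
    (A, n - A - 1) degrees of freedom.
    """
    n, A = cv.n_samples, cv.n_components
    if n <= A + 1:
        raise ValidationError(f"n={n} too small for A={A} (need n > A + 1)")
    ss0, press = float(cv.ss0[j]), float(cv.press[j])
    if ss0 <= 0:
        return 0.0, 1.0
    if press <= 0:
        return np.inf, 0.0
    f_stat = max((ss0 - press) / A / (press / (n - A - 1)), 0.0)
    p = float(stats.f.sf(f_stat, A, n - A - 1))
    return f_stat, p


def compute_vip(model: PLSModel) -> np.ndarray:
    """VIP_k = sqrt(K * sum_a SSY_a (w_ka / |w_a|)^2 / sum_a SSY_a).

    SSY_a is the Y variance explained by component a; weight columns are
    unit norm, so the per-component terms are the squared weights.
    """
    ssy = np.asarray(model.r2y, dtype=float)
    if ssy.sum() <= 0:
        raise ValidationError("model explains no Y variance; VIP undefined")
    w = model.x_weights
    k = w.shape[0]
    wnorm2 = (w ** 2) / (w ** 2).sum(axis=0, keepdims=True)
    return np.sqrt(k * (wnorm2 * ssy).sum(axis=1) / ssy.sum())


@dataclass
class VIPResult:
    vip: pd.Series                  # X variable -> VIP (full model)
    jackknife_se: pd.Series
    p: pd.Series                    # one-sided, H0: VIP <= 1
    loading_sign: pd.DataFrame      # X variable x component -> "+", "-", "0"
    n_folds: int


def vip_significance(
    X, Y, A: int, *, folds: int = 7, seed: int = 0, site_of=None,
    alpha_zero: float = 1e-10,
) -> VIPResult:
    """Full-model VIP with delete-one-fold jackknife inference.

    VIP is recomputed on each training fold's model; the jackknife standard
    error over folds feeds a one-sided t test (df = folds - 1) of
    H0: VIP <= 1.  Loading signs are read off the full-model X loadings for
    components 1 and 2 (values within ``alpha_zero`` of zero map to "0").
    """
    x_arr, x_names_arr = _as_array(X, "x")
    y_arr, _ = _as_array(Y, "y")
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else x_names_arr
    model = fit_pls(x_arr, y_arr, A)
    vip_full = compute_vip(model)

    fold_idx = assign_folds(x_arr.shape[0], folds, seed, site_of)
    fold_vips = []
    for f in sorted(set(fold_idx.tolist())):
        train = fold_idx != f
        a_eff = min(A, int(train.sum()) - 1, x_arr.shape[1])
        sub = fit_pls(x_arr[train], y_arr[train], a_eff)
        fold_vips.append(compute_vip(sub))
    fv = np.vstack(fold_vips)
    g = fv.shape[0]
    se = np.sqrt((g - 1) / g * ((fv - fv.mean(axis=0)) ** 2).sum(axis=0))

    p = np.empty(len(vip_full))
    for k in range(len(vip_full)):
        if se[k] == 0:
            p[k] = 0.0 if vip_full[k] > 1.0 else 1.0
        else:
            t_stat = (vip_full[k] - 1.0) / se[k]
            p[k] = float(stats.t.sf(t_stat, g - 1))

    n_show = min(2, model.n_components)
    signs = np.where(np.abs(model.x_loadings[:, :n_show]) < alpha_zero, "0",
                     np.where(model.x_loadings[:, :n_show] > 0, "+", "-"))
    loading_sign = pd.DataFrame(signs, index=x_names,
                                columns=[f"component{a + 1}" for a in range(n_show)])
    idx = pd.Index(x_names, name="variable")
    return VIPResult(vip=pd.Series(vip_full, index=idx, name="VIP"),
                     jackknife_se=pd.Series(se, index=idx, name="se"),
                     p=pd.Series(p, index=idx, name="p"),
                     loading_sign=loading_sign, n_folds=g)
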