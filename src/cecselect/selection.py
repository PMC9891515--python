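"""Backward elimination plus one-by-one re-introduction of responses.

The selection routine mirrors how the contaminant set is pruned against the
metabolite block: starting from all detected contaminants (plus temperature,
which is kept by force), a multi-response PLS model is cross-validated and
every response whose CV-ANOVA p exceeds alpha is removed — simultaneously —
until a fixed point.  Excluded responses are then offered back one at a
time (in descending global-model Q2Y order) and re-admitted only when their
CV-ANOVA p is below alpha AND the pooled Q2Cum strictly increases.  The full
trace of both phases is recorded so every decision is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ResponseBlock
from .errors import ValidationError
from .crossval import CVResult, _fold_press, assign_folds, cv_anova
from .pls import _as_array


@dataclass
class EliminationStep:
    retained: list[str]
    removed: dict[str, float]       # response -> CV-ANOVA p at removal
    q2cum: float                    # of the model the p-values came from
    n_components: int


@dataclass
class ReintroductionStep:
    candidate: str
    p: float
    q2cum_with: float
    q2cum_before: float
    accepted: bool
    order_index: int


@dataclass
class SelectionTrace:
    iterations: list[EliminationStep] = field(default_factory=list)
    reintroduction: list[ReintroductionStep] = field(default_factory=list)
    post_elimination: dict = field(default_factory=dict)
    final: dict = field(default_factory=dict)
    global_q2y: pd.Series | None = None
    global_q2cum: float | None = None
    ranked: pd.DataFrame | None = None
    empty_after_elimination: bool = False

    def check_invariants(self) -> None:
        sizes = [len(s.retained) for s in self.iterations]
        for prev, cur in zip(sizes, sizes[1:]):
            if cur >= prev:
                raise ValidationError("retained sets must strictly shrink")
        for step in self.reintroduction:
            if step.accepted and not (step.p < self._alpha
                                      and step.q2cum_with > step.q2cum_before):
                raise ValidationError(
                    f"accepted candidate {step.candidate!r} violates the dual criterion")
        post = self.post_elimination.get("q2cum", -np.inf)
        final = self.final.get("q2cum", post)
        if final is not None and post is not None and final < post - 1e-12:
            raise ValidationError("final Q2Cum below post-elimination Q2Cum")

    _alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self._alpha,
            "iterations": [
                {"retained": s.retained, "removed": s.removed,
                 "q2cum": s.q2cum, "n_components": s.n_components}
                for s in self.iterations
            ],
            "reintroduction": [
                {"candidate": s.candidate, "p": s.p,
                 "q2cum_with": s.q2cum_with, "q2cum_before": s.q2cum_before,
                 "accepted": s.accepted, "order_index": s.order_index}
                for s in self.reintroduction
            ],
            "post_elimination": self.post_elimination,
            "final": self.final,
            "global_q2cum": self.global_q2cum,
            "global_q2y": None if self.global_q2y is None else self.global_q2y.to_dict(),
            "empty_after_elimination": self.empty_after_elimination,
        }


def _assess(
    X, Y_df: pd.DataFrame, *, components, folds: int, seed: int, site_of,
    gain_threshold: float = 0.01,
) -> tuple[int, CVResult]:
    """One cross-validation pass: pick A (auto or fixed, capped by the
    training-fold rank limit) and return the CVResult at that A."""
    x_arr, _ = _as_array(X, "x")
    n, k = x_arr.shape
    fold_idx = assign_folds(n, folds, seed, site_of)
    n_train_min = n - int(np.bincount(fold_idx).max())
    cap = min(n - 1, k, n_train_min - 1)
    if components == "auto":
        a_max = max(min(cap, 10), 1)
        # deepen lazily: the gain rule almost always stops well before
        # a_max, so start with a short horizon and extend only if needed
        horizon = min(4, a_max)
        while True:
            press, ss0 = _fold_press(X, Y_df, horizon, fold_idx)
            tot0 = ss0.sum()
            q2cum = 1.0 - press.sum(axis=1) / tot0 if tot0 > 0 else np.zeros(horizon)
            best, prev = 1, 0.0
            for a in range(1, horizon + 1):
                if q2cum[a - 1] - prev >= gain_threshold:
                    best, prev = a, q2cum[a - 1]
                else:
                    break
            if best < horizon or horizon == a_max:
                break
            horizon = min(a_max, horizon + 3)
        a_used = best
    else:
        a_used = max(min(int(components), cap), 1)
        press, ss0 = _fold_press(X, Y_df, a_used, fold_idx)
    press_a = press[a_used - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        q2y = np.where(ss0 > 0, 1.0 - press_a / np.where(ss0 > 0, ss0, 1.0), 0.0)
    tot0 = ss0.sum()
    cv = CVResult(fold_assignment=fold_idx, press=press_a, ss0=ss0, q2y=q2y,
                  q2cum=float(1.0 - press_a.sum() / tot0) if tot0 > 0 else 0.0,
                  n_samples=n, n_components=a_used,
                  y_names=[str(c) for c in Y_df.columns])
    return a_used, cv


def _pvalues(cv: CVResult) -> dict[str, float]:
    return {name: cv_anova(cv, j)[1] for j, name in enumerate(cv.y_names)}


def backward_eliminate(
    X, Y: pd.DataFrame, *, alpha: float = 0.05, components="auto",
    folds: int = 7, seed: int = 0, site_of=None, force_keep=(),
) -> SelectionTrace:
    """Simultaneous removal of all responses with CV-ANOVA p > alpha,
    iterated to a fixed point.  Returns a partial trace (elimination phase
    plus the global-model Q2Y used to order re-introduction)."""
    force = set(force_keep)
    trace = SelectionTrace()
    trace._alpha = alpha
    current = [str(c) for c in Y.columns]

    a_used, cv = _assess(X, Y[current], components=components, folds=folds,
                         seed=seed, site_of=site_of)
    trace.global_q2y = pd.Series(cv.q2y, index=cv.y_names, name="Q2Y")
    trace.global_q2cum = cv.q2cum

    while True:
        pvals = _pvalues(cv)
        removable = {r: pvals[r] for r in current
                     if r not in force and pvals[r] > alpha}
        if not removable:
            trace.post_elimination = {
                "retained": current, "q2cum": cv.q2cum,
                "n_components": a_used,
                "p": pvals, "q2y": dict(zip(cv.y_names, cv.q2y.tolist())),
            }
            break
        current = [r for r in current if r not in removable]
        trace.iterations.append(EliminationStep(
            retained=list(current), removed=removable,
            q2cum=cv.q2cum, n_components=a_used))
        if not current:
            trace.empty_after_elimination = True
            trace.post_elimination = {"retained": [], "q2cum": None,
                                      "n_components": 0, "p": {}, "q2y": {}}
            break
        a_used, cv = _assess(X, Y[current], components=components, folds=folds,
                             seed=seed, site_of=site_of)
    return trace


def forward_reintroduce(
    X, Y: pd.DataFrame, trace: SelectionTrace, *, alpha: float = 0.05,
    components="auto", folds: int = 7, seed: int = 0, site_of=None,
) -> SelectionTrace:
    """Offer every eliminated response back, one at a time.

    Candidates are tried in descending global-model Q2Y (ties lexicographic)
    and retained iff CV-ANOVA p < alpha AND the pooled Q2Cum strictly
    increases; accepted candidates stay in the model for later trials.
    """
    all_cols = [str(c) for c in Y.columns]
    current = list(trace.post_elimination.get("retained", []))
    excluded = [r for r in all_cols if r not in set(current)]
    q2cum_before = trace.post_elimination.get("q2cum")
    if q2cum_before is None:
        q2cum_before = -np.inf

    gq = trace.global_q2y if trace.global_q2y is not None else pd.Series(dtype=float)
    order = sorted(excluded, key=lambda r: (-float(gq.get(r, -np.inf)), r))
    for idx, cand in enumerate(order):
        trial = [c for c in all_cols if c in set(current) | {cand}]
        a_used, cv = _assess(X, Y[trial], components=components, folds=folds,
                             seed=seed, site_of=site_of)
        p_cand = _pvalues(cv)[cand]
        accepted = bool(p_cand < alpha and cv.q2cum > q2cum_before)
        trace.reintroduction.append(ReintroductionStep(
            candidate=cand, p=p_cand, q2cum_with=cv.q2cum,
            q2cum_before=float(q2cum_before), accepted=accepted,
            order_index=idx))
        if accepted:
            current = trial
            q2cum_before = cv.q2cum

    if current:
        a_used, cv = _assess(X, Y[current], components=components, folds=folds,
                             seed=seed, site_of=site_of)
        pvals = _pvalues(cv)
        trace.final = {
            "responses": current, "q2cum": cv.q2cum, "n_components": a_used,
            "q2y": dict(zip(cv.y_names, cv.q2y.tolist())), "p": pvals,
        }
        ranked = pd.DataFrame({
            "Q2Y": [trace.final["q2y"][r] for r in current],
            "cv_anova_p": [pvals[r] for r in current],
        }, index=pd.Index(current, name="response"))
        order_ix = np.lexsort((ranked.index.to_numpy(),
                               -ranked["Q2Y"].to_numpy()))
        trace.ranked = ranked.iloc[order_ix]
    else:
        trace.final = {"responses": [], "q2cum": None, "n_components": 0,
                       "q2y": {}, "p": {}}
        trace.ranked = pd.DataFrame(columns=["Q2Y", "cv_anova_p"])
    trace.check_invariants()
    return trace


def select_contaminants(
    X, Y, *, alpha: float = 0.05, components="auto", folds: int = 7,
    seed: int = 0, site_of=None, force_keep=None,
) -> SelectionTrace:
    """Full selection: backward elimination then forward re-introduction.

    ``Y`` may be a :class:`ResponseBlock` (its force-keep set and site
    labels are used) or a plain DataFrame.  The trace carries the ranked
    final table (responses sorted by Q2Y descending, ties lexicographic).
    """
    if isinstance(Y, ResponseBlock):
        y_df = Y.values
        if force_keep is None:
            force_keep = Y.force_keep
        if site_of is None:
            site_of = Y.site_of.to_numpy()
    else:
        y_df = Y
    if y_df.shape[1] == 0:
        raise ValidationError("need at least one response")
    force_keep = tuple(force_keep or ())
    missing = set(force_keep) - {str(c) for c in y_df.columns}
    if missing:
        raise ValidationError(f"force_keep response(s) absent: {sorted(missing)}")
    trace = backward_eliminate(X, y_df, alpha=alpha, components=components,
                               folds=folds, seed=seed, site_of=site_of,
                               force_keep=force_keep)
    return forward_reintroduce(X, y_df, trace, alpha=alpha,
                               components=components, folds=folds, seed=seed,
                               site_of=site_of)
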