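"""Site-difference screen for metabolites.

Each metabolite is tested for site differences with one-way fixed-effects
ANOVA; metabolites with omnibus p below alpha form the explanatory block of
the downstream PLS model.  All site pairs are additionally compared with the
Tukey-Kramer honestly-significant-difference test (studentized-range
distribution on the within-group mean square; the Kramer form handles
unbalanced groups), and significant pairs can be rendered in the compact
letter-pair convention: pairs of the same lowercase letter mark sites that
differ significantly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MetaboliteMatrix
from .errors import ValidationError

_MEAN_EQ_RTOL = 1e-12


@dataclass
class ScreenResult:
    table: pd.DataFrame                 # metabolite x [F, p]
    group_means: pd.DataFrame           # metabolite x site
    pairwise: dict[str, pd.DataFrame]   # metabolite -> site x site Tukey p
    selected: list[str]
    alpha: float
    site_order: list[str]
    zero_variance: list[str] = field(default_factory=list)


def _anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Return (F, p, within-group mean square) for k groups.

    Zero within-group variance is resolved by continuity: unequal means give
    p = 0 (certain difference), equal means give p = 1.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    msw = ssw / (n - k)
    if msw <= 0:
        scale = max(abs(grand), 1.0)
        if np.ptp(means) <= _MEAN_EQ_RTOL * scale:
            return 0.0, 1.0, 0.0
        return np.inf, 0.0, 0.0
    f_stat = (ssb / (k - 1)) / msw
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return f_stat, p, msw


def _tukey_kramer(groups: list[np.ndarray], msw: float) -> np.ndarray:
    """All-pairs adjusted p via the studentized range; Kramer correction for
    unequal group sizes (reduces to classic Tukey HSD when balanced)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    dof = int(ns.sum()) - k
    means = np.array([g.mean() for g in groups])
    p = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if msw <= 0:
            scale = max(abs(means[i]), abs(means[j]), 1.0)
            pij = 1.0 if diff <= _MEAN_EQ_RTOL * scale else 0.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = diff / se
            pij = float(stats.studentized_range.sf(q, k, dof))
        p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


def anova_screen(
    matrix: MetaboliteMatrix,
    alpha: float = 0.05,
    *,
    log_transform: bool = False,
    site_order: list[str] | None = None,
    pairwise: bool = True,
) -> ScreenResult:
    """Per-metabolite one-way ANOVA across sites plus Tukey-Kramer pairs.

    Requires a normalized, fully imputed matrix, >=2 sites with >=2 samples
    each.  Tukey pairs are computed for every metabolite regardless of the
    omnibus result; only ``selected`` uses the omnibus p.  ``site_order``
    fixes the column/letter ordering (default: order of first appearance).
    ``pairwise=False`` skips the (slow) studentized-range evaluations for
    callers that only consume the omnibus screen; selection is unchanged.
    """
    if not matrix.normalized:
        raise ValidationError("screen requires a median-normalized matrix")
    if matrix.n_missing:
        raise ValidationError("screen requires an imputed (missing-free) matrix")
    seen: list[str] = []
    for s in matrix.site_of:
        if s not in seen:
            seen.append(s)
    order = list(site_order) if site_order is not None else seen
    if set(order) != set(seen):
        raise ValidationError("site_order must name exactly the observed sites")
    counts = matrix.site_of.value_counts()
    if len(order) < 2:
        raise ValidationError("need >=2 sites")
    small = [s for s in order if counts[s] < 2]
    if small:
        raise ValidationError(f"site(s) with <2 samples: {small}")

    arr = matrix.values.to_numpy(float)
    if log_transform:
        if (arr <= 0).any():
            raise ValidationError("log transform requires strictly positive values")
        arr = np.log(arr)
    site_idx = [np.flatnonzero((matrix.site_of == s).to_numpy()) for s in order]

    names = matrix.metabolite_names
    f_vals, p_vals = np.empty(len(names)), np.empty(len(names))
    means = np.empty((len(names), len(order)))
    pair_p: dict[str, pd.DataFrame] = {}
    zero_var: list[str] = []
    for m, name in enumerate(names):
        groups = [arr[idx, m] for idx in site_idx]
        f_vals[m], p_vals[m], msw = _anova_oneway(groups)
        if msw <= 0:
            zero_var.append(name)
        means[m] = [g.mean() for g in groups]
        if pairwise:
            pair_p[name] = pd.DataFrame(_tukey_kramer(groups, msw),
                                        index=order, columns=order)

    table = pd.DataFrame({"F": f_vals, "p": p_vals}, index=pd.Index(names, name="metabolite"))
    selected = [name for name, p in zip(names, p_vals) if p < alpha]
    return ScreenResult(table=table,
                        group_means=pd.DataFrame(means, index=names, columns=order),
                        pairwise=pair_p, selected=selected, alpha=alpha,
                        site_order=order, zero_variance=zero_var)


def letter_pairs(
    result: ScreenResult, metabolite: str, *, alpha: float | None = None
) -> dict[str, str]:
    """Compact letter-pair rendering of the significant Tukey site pairs.

    Pairs are enumerated in the fixed site order; the first significant pair
    gets letter ``a``, the next ``b``, and so on; each site's string is the
    concatenation (in letter order) of the letters of the pairs it belongs
    to.  Decoding the letters reconstructs the pair set exactly.
    """
    if metabolite not in result.pairwise:
        raise ValidationError(f"metabolite {metabolite!r} was not screened")
    alpha = result.alpha if alpha is None else alpha
    pmat = result.pairwise[metabolite]
    order = result.site_order
    sig = [(a, b) for a, b in combinations(order, 2) if pmat.loc[a, b] < alpha]
    if len(sig) > len(string.ascii_lowercase):
        raise ValidationError("more significant pairs than available letters")
    letters = {site: [] for site in order}
    for letter, (a, b) in zip(string.ascii_lowercase, sig):
        letters[a].append(letter)
        letters[b].append(letter)
    return {site: "".join(ls) for site, ls in letters.items()}


def decode_letter_pairs(strings: dict[str, str]) -> set[tuple[str, str]]:
    """Inverse of :func:`letter_pairs`: each letter names exactly one pair."""
    members: dict[str, list[str]] = {}
    for site, s in strings.items():
        for letter in s:
            members.setdefault(letter, []).append(site)
    pairs = set()
    for letter, sites in members.items():
        if len(sites) != 2:
            raise ValidationError(f"letter {letter!r} appears at {len(sites)} sites")
        pairs.add(tuple(sorted(sites)))
    return pairs
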