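"""Backward elimination and forward re-introduction of responses."""

import numpy as np
import pandas as pd
import pytest

from cecselect.datamodel import TEMPERATURE_RESPONSE
from cecselect.errors import ValidationError
from cecselect.preprocess import (aggregate_max_by_site, build_response_block,
                                  drop_undetected, impute_missing,
                                  median_normalize)
from cecselect.screen import anova_screen
from cecselect.selection import (backward_eliminate, forward_reintroduce,
                                 select_contaminants)


def study_blocks(study):
    panel, matrix, truth = study
    filt = drop_undetected(aggregate_max_by_site(panel))
    imp = impute_missing(median_normalize(matrix))
    scr = anova_screen(imp.matrix, 0.05, pairwise=False)
    yblock = build_response_block(filt.aggregate, imp.matrix)
    x = imp.matrix.values[scr.selected]
    return x, yblock, truth, filt


class TestBackwardEliminate:
    def test_strong_responses_reach_immediate_fixed_point(self, small_study):
        """With only factor-driven responses, nothing is removable."""
        x, yblock, truth, _ = study_blocks(small_study)
        keep = sorted(truth.active_contaminants) + [TEMPERATURE_RESPONSE]
        y = yblock.values[keep]
        trace = backward_eliminate(x, y, alpha=0.05, components="auto",
                                   folds=7, seed=0,
                                   site_of=yblock.site_of.to_numpy(),
                                   force_keep=(TEMPERATURE_RESPONSE,))
        assert trace.iterations == []
        assert set(trace.post_elimination["retained"]) == set(keep)

    def test_null_responses_mostly_removed(self):
        sites = np.repeat(list("PFBG"), 8)
        removed_frac = []
        for seed in range(10):
            rng = np.random.default_rng(700 + seed)
            x = rng.normal(size=(32, 15))
            y = pd.DataFrame(rng.normal(size=(32, 40)),
                             columns=[f"r{j}" for j in range(40)])
            trace = backward_eliminate(x, y, alpha=0.05, components="auto",
                                       folds=7, seed=seed, site_of=sites)
            removed = 40 - len(trace.post_elimination["retained"])
            removed_frac.append(removed / 40)
        assert np.mean(removed_frac) >= 0.95

    def test_all_removable_leaves_flagged_empty_set(self):
        sites = np.repeat(list("PFBG"), 6)
        rng = np.random.default_rng(41)
        x = rng.normal(size=(24, 10))
        y = pd.DataFrame(rng.normal(size=(24, 5)),
                         columns=[f"r{j}" for j in range(5)])
        trace = backward_eliminate(x, y, alpha=1e-9, components=2,
                                   folds=6, seed=0, site_of=sites)
        if not trace.post_elimination["retained"]:
            assert trace.empty_after_elimination


class TestForwardReintroduce:
    def test_removed_active_is_recovered(self, small_study):
        """Drop one factor-driven response from the post-elimination set by
        hand; re-introduction must re-admit it."""
        x, yblock, truth, _ = study_blocks(small_study)
        keep = sorted(truth.active_contaminants) + [TEMPERATURE_RESPONSE]
        y = yblock.values[keep]
        sites = yblock.site_of.to_numpy()
        trace = backward_eliminate(x, y, alpha=0.05, components="auto",
                                   folds=7, seed=0, site_of=sites,
                                   force_keep=(TEMPERATURE_RESPONSE,))
        victim = sorted(truth.active_contaminants)[0]
        trace.post_elimination["retained"] = [
            r for r in trace.post_elimination["retained"] if r != victim]
        # recompute the baseline Q2Cum for the reduced set
        from cecselect.selection import _assess
        _, cv = _assess(x, y[trace.post_elimination["retained"]],
                        components="auto", folds=7, seed=0, site_of=sites)
        trace.post_elimination["q2cum"] = cv.q2cum
        trace = forward_reintroduce(x, y, trace, alpha=0.05,
                                    components="auto", folds=7, seed=0,
                                    site_of=sites)
        assert victim in trace.final["responses"]
        step = next(s for s in trace.reintroduction if s.candidate == victim)
        assert step.accepted and step.p < 0.05
        assert step.q2cum_with > step.q2cum_before

    def test_no_excluded_responses_is_identity(self, small_study):
        x, yblock, truth, _ = study_blocks(small_study)
        keep = sorted(truth.active_contaminants)[:5]
        y = yblock.values[keep]
        sites = yblock.site_of.to_numpy()
        trace = backward_eliminate(x, y, alpha=0.05, components="auto",
                                   folds=7, seed=0, site_of=sites)
        if set(trace.post_elimination["retained"]) == set(keep):
            trace = forward_reintroduce(x, y, trace, alpha=0.05,
                                        components="auto", folds=7, seed=0,
                                        site_of=sites)
            assert trace.reintroduction == []
            assert set(trace.final["responses"]) == set(keep)

    def test_decisions_respect_dual_criterion(self):
        sites = np.repeat(list("PFBG"), 8)
        rng = np.random.default_rng(42)
        factor = np.repeat(rng.normal(size=4), 8)
        x = np.column_stack([factor + 0.2 * rng.normal(size=32)
                             for _ in range(10)])
        strong = np.repeat(rng.normal(size=4), 8)
        y = pd.DataFrame({
            "strong": factor + 0.05 * np.repeat(rng.normal(size=4), 8),
            "noise1": np.repeat(rng.normal(size=4), 8),
            "noise2": np.repeat(rng.normal(size=4), 8),
        })
        trace = select_contaminants(x, y, alpha=0.05, components=2,
                                    folds=8, seed=0, site_of=sites)
        for step in trace.reintroduction:
            assert step.accepted == (step.p < 0.05
                                     and step.q2cum_with > step.q2cum_before)


class TestSelectContaminants:
    def test_trace_invariants_on_synthetic_study(self, small_study):
        x, yblock, truth, filt = study_blocks(small_study)
        trace = select_contaminants(x, yblock, alpha=0.05,
                                    components="auto", folds=7, seed=3)
        trace.check_invariants()
        sizes = [len(s.retained) for s in trace.iterations]
        assert sizes == sorted(sizes, reverse=True)
        assert TEMPERATURE_RESPONSE in trace.final["responses"]
        post = trace.post_elimination["q2cum"]
        assert trace.final["q2cum"] >= post - 1e-12

    def test_ranked_table_sorted_by_q2y(self, small_study):
        x, yblock, *_ = study_blocks(small_study)
        trace = select_contaminants(x, yblock, alpha=0.05,
                                    components="auto", folds=7, seed=3)
        q2 = trace.ranked["Q2Y"].to_numpy()
        assert all(q2[i] >= q2[i + 1] for i in range(len(q2) - 1))
        assert set(trace.ranked.index) == set(trace.final["responses"])

    def test_deterministic_given_seed(self, small_study):
        x, yblock, *_ = study_blocks(small_study)
        a = select_contaminants(x, yblock, alpha=0.05, components="auto",
                                folds=7, seed=9)
        b = select_contaminants(x, yblock, alpha=0.05, components="auto",
                                folds=7, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_single_significant_response(self, small_study):
        x, yblock, truth, _ = study_blocks(small_study)
        name = sorted(truth.active_contaminants)[0]
        y = yblock.values[[name]]
        trace = select_contaminants(x, y, alpha=0.05, components=2,
                                    folds=7, seed=0,
                                    site_of=yblock.site_of.to_numpy())
        assert trace.final["responses"] == [name]

    def test_empty_response_block_rejected(self, small_study):
        x, yblock, *_ = study_blocks(small_study)
        with pytest.raises(ValidationError, match="response"):
            select_contaminants(x, yblock.values[[]], alpha=0.05,
                                components=2, folds=7, seed=0)

    def test_unknown_force_keep_rejected(self, small_study):
        x, yblock, *_ = study_blocks(small_study)
        with pytest.raises(ValidationError, match="absent"):
            select_contaminants(x, yblock.values, alpha=0.05, components=2,
                                folds=7, seed=0, force_keep=("nonexistent",))
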