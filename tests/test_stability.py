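"""Selection-frequency ranking, step-forward size scan, full StaVarSel."""

import numpy as np
import pandas as pd
import pytest

from stavarsel import (
    SimulationDesign,
    StandardNestedCV,
    StaVarSelCV,
    build_ratios,
    generate_cohort,
    selection_frequency_table,
    step_forward_size_selection,
)
from tests.conftest import FAST_CV


class TestFrequencyTable:
    def test_counting_and_threshold(self):
        sels = [["a", "b"]] * 20 + [["a"]] * 15  # a: 35/35, b: 20/35
        table = selection_frequency_table(sels, frequency_threshold=0.5)
        assert table.loc[table["ratio_id"] == "a", "fraction"].iloc[0] == 1.0
        assert table.loc[table["ratio_id"] == "b", "fraction"].iloc[0] == pytest.approx(20 / 35)
        assert list(table["ratio_id"]) == ["a", "b"]

    def test_just_below_threshold_excluded(self):
        sels = [["a", "b"]] * 17 + [["a"]] * 18  # b: 17/35 = 0.486
        table = selection_frequency_table(sels, frequency_threshold=0.5)
        assert "b" not in set(table["ratio_id"])

    def test_tie_break_by_coefficient_then_id(self):
        sels = [["x", "y", "z"]] * 10
        coefs = [{"x": 1.0, "y": 5.0, "z": 1.0}] * 10
        table = selection_frequency_table(sels, coefs)
        assert list(table["ratio_id"]) == ["y", "x", "z"]  # coef, then lexical

    def test_empty_table_is_error(self):
        sels = [["a"], ["b"], ["c"], ["d"]]
        with pytest.raises(ValueError, match="lowering the threshold"):
            selection_frequency_table(sels, frequency_threshold=0.5)


class TestStepForward:
    def _cohort(self, rng, n=20, n_noise=6):
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X = rng.normal(size=(n, 2 + n_noise))
        X[y == 1, 0] += 2.5
        X[y == 1, 1] -= 2.2
        cols = [f"r{j}" for j in range(X.shape[1])]
        return pd.DataFrame(X, columns=cols), y, cols

    def test_two_informative_ratios_recovered(self):
        """Two complementary informative ratios ranked first: the scan
        keeps at least both in nearly all replicates and k = 2 is the
        modal choice (the LOOCV error curve is noisy at small n, so the
        exact argmin occasionally drifts above 2)."""
        chosen = []
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 30
            y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
            X = rng.normal(size=(n, 8))
            X[y == 1, 0] += 1.6
            X[y == 1, 1] -= 1.6
            cols = [f"r{j}" for j in range(8)]
            curve = step_forward_size_selection(pd.DataFrame(X, columns=cols), y, cols, max_model_size=8)
            chosen.append(curve.attrs["chosen_k"])
        assert sum(k >= 2 for k in chosen) / n_rep >= 0.75  # both informative kept
        assert sum(k == 2 for k in chosen) / n_rep >= 0.5  # modal size is exact

    def test_tie_chooses_smallest_k(self, rng):
        """With one perfectly separating ratio first in the ranking, every
        k achieves zero error: the scan must return k = 1."""
        y = np.r_[np.zeros(8), np.ones(8)].astype(int)
        X = pd.DataFrame(
            {"good": np.r_[np.zeros(8), np.ones(8) * 9] + 0.1,
             "noise1": rng.normal(size=16),
             "noise2": rng.normal(size=16)}
        )
        curve = step_forward_size_selection(X, y, ["good", "noise1", "noise2"])
        errors = dict(zip(curve["k"], curve["error"]))
        assert errors[1] == min(errors.values())
        assert curve.attrs["chosen_k"] == 1

    def test_conservative_error_dominates_point(self):
        for seed in [0, 1, 2]:
            X, y, cols = self._cohort(np.random.default_rng(seed), n=16, n_noise=4)
            point = step_forward_size_selection(X, y, cols, max_model_size=4, mode="point")
            cons = step_forward_size_selection(X, y, cols, max_model_size=4, mode="conservative")
            merged = point.merge(cons, on="k", suffixes=("_pt", "_cons"))
            assert (merged["error_cons"] >= merged["error_pt"] - 1e-12).all()

    def test_oversized_k_skipped(self, rng):
        X, y, cols = self._cohort(rng, n=10, n_noise=8)
        curve = step_forward_size_selection(X, y, cols, max_model_size=10)
        assert curve["k"].max() <= 7  # inner training sets have n-2 = 8 samples

    def test_empty_ranking_is_error(self, rng):
        X, y, cols = self._cohort(rng)
        with pytest.raises(ValueError, match="empty"):
            step_forward_size_selection(X, y, [])


def test_final_sets_more_stable_than_per_split_selections():
    """The motivating claim: StaVarSel's final feature set varies less
    across reruns (different inner-CV fold draws) than the per-split Lasso
    selections vary across training sets within one standard nested CV.
    Measured as mean pairwise Jaccard similarity, averaged over cohorts."""

    def jaccard(a, b):
        a, b = set(a), set(b)
        return len(a & b) / len(a | b) if a | b else 1.0

    def mean_pairwise(sets):
        pairs = [(i, j) for i in range(len(sets)) for j in range(i + 1, len(sets))]
        return np.mean([jaccard(sets[i], sets[j]) for i, j in pairs])

    sv_stab, split_stab = [], []
    for gen_seed in range(3):
        d = SimulationDesign(
            n_per_group=(10, 10), n_features=15,
            informative_pairs=[(0, 1, 1.5), (2, 3, 1.2)], seed=gen_seed,
        )
        expr, meta, _ = generate_cohort(d)
        ratios = build_ratios(expr)
        y = (meta["group"] == "B").astype(int).to_numpy()
        finals = []
        for rerun_seed in range(3):
            std = StandardNestedCV(random_state=rerun_seed, **FAST_CV).fit(ratios, y)
            if rerun_seed == 0:
                split_stab.append(mean_pairwise([list(s) for s in std.per_split_selected_]))
            try:
                finals.append(
                    list(StaVarSelCV(random_state=rerun_seed, **FAST_CV)
                         .fit(ratios, y, standard=std).final_feature_ids_)
                )
            except ValueError:
                finals.append([])  # no ratio reached the stability threshold
        sv_stab.append(mean_pairwise(finals))
    assert np.mean(sv_stab) >= np.mean(split_stab)


class TestStaVarSelCV:
    def test_bundle_bookkeeping(self, worked_ratios, fitted_standard_cv):
        ratios, y, truth = worked_ratios
        sv = StaVarSelCV(random_state=1, **FAST_CV).fit(ratios, y, standard=fitted_standard_cv)
        assert len(sv.final_feature_ids_) == sv.chosen_k_
        assert sv.chosen_k_ == sv.step_forward_curve_.attrs["chosen_k"]
        assert len(sv.records_) == len(y)
        # the planted ratios top the frequency ranking on this cohort
        top2 = set(sv.frequency_table_["ratio_id"].head(2))
        assert top2 == set(truth["informative_ratios"])
        # predict on the training cohort agrees with the final model
        proba = sv.predict_proba(ratios)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_heldout_sample_cannot_touch_own_frequency_entries(
        self, worked_ratios, fitted_standard_cv
    ):
        """The frequency table entry attributed to a split's training set is
        computed without the held-out sample: mutating that sample (at a
        fixed shared penalty) leaves its split's selection unchanged."""
        from stavarsel import StandardNestedCV

        ratios, y, _ = worked_ratios
        lam = fitted_standard_cv.lambda_average_
        base = StandardNestedCV(random_state=2, fixed_lambda=lam, **FAST_CV).fit(ratios, y)
        mutated = ratios.copy()
        mutated.iloc[5] = mutated.iloc[5].to_numpy() * 31.7
        alt = StandardNestedCV(random_state=2, fixed_lambda=lam, **FAST_CV).fit(mutated, y)
        assert list(base.splits_[5].selected_names) == list(alt.splits_[5].selected_names)
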