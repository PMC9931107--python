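"""Cohen's kappa: exhaustive oracles, null calibration, group averaging."""
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocemo import (band_strength, cohen_kappa, group_kappa,
                    kernel_from_accuracy, per_emotion_kappa, simulate_responses)
from vocemo.errors import InvalidSpecError, UndefinedKappaError


def kappa_by_contingency(a, b):
    """Independent oracle: explicit contingency table and marginal products."""
    cats = sorted(set(a) | set(b))
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_identical_raters_kappa_one(self):
        ratings = ["joy", "neutral", "sadness", "anger", "joy"]
        assert cohen_kappa(ratings, ratings) == pytest.approx(1.0)

    def test_worked_example_against_oracle(self):
        a = ["J", "J", "N", "S", "A"]
        b = ["J", "N", "N", "S", "A"]
        k = cohen_kappa(a, b)
        assert k == pytest.approx(kappa_by_contingency(a, b))
        assert k == pytest.approx((0.8 - 0.24) / 0.76)

    def test_exhaustive_two_category_oracle(self):
        """All label-vector pairs of length <= 6 over two emotions match the
        brute-force contingency computation exactly."""
        cats = ("joy", "sadness")
        for length in range(2, 7):
            for a in product(cats, repeat=length):
                for b in product(cats, repeat=length):
                    expected = kappa_by_contingency(list(a), list(b))
                    if expected is None:
                        with pytest.raises(UndefinedKappaError):
                            cohen_kappa(list(a), list(b))
                    else:
                        assert cohen_kappa(list(a), list(b)) == pytest.approx(expected)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(25):
            a = list(rng.choice(["joy", "neutral", "sadness", "anger"], size=40))
            b = list(rng.choice(["joy", "neutral", "sadness", "anger"], size=40))
            assert cohen_kappa(a, b) == pytest.approx(
                sklearn_metrics.cohen_kappa_score(a, b))

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(1)
        a = list(rng.choice(["joy", "neutral", "sadness", "anger"], size=10_000))
        b = list(rng.choice(["joy", "neutral", "sadness", "anger"], size=10_000))
        assert abs(cohen_kappa(a, b)) <= 0.03

    @given(st.lists(st.sampled_from(["joy", "neutral", "sadness", "anger"]),
                    min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_relabel_invariance(self, a):
        rng = np.random.default_rng(len(a))
        b = list(rng.permutation(a))
        relabel = {"joy": "anger", "anger": "joy",
                   "neutral": "sadness", "sadness": "neutral"}
        try:
            k_ab = cohen_kappa(a, b)
        except UndefinedKappaError:
            return
        assert cohen_kappa(b, a) == pytest.approx(k_ab)
        assert cohen_kappa([relabel[x] for x in a],
                           [relabel[x] for x in b]) == pytest.approx(k_ab)


class TestPerEmotionKappa:
    def test_perfect_binarized_agreement(self):
        a = ["joy", "neutral", "joy", "sadness"]
        b = ["joy", "sadness", "joy", "neutral"]  # agree exactly on joy-vs-other
        assert per_emotion_kappa(a, b, "joy") == pytest.approx(1.0)

    def test_one_rater_never_uses_emotion(self):
        a = ["joy", "joy", "neutral", "sadness", "neutral", "sadness"]
        b = ["neutral", "sadness", "neutral", "sadness", "sadness", "neutral"]
        k = per_emotion_kappa(a, b, "joy")
        # 2x2 brute force: b never says joy, so observed joy-agreement is 0
        assert k <= 0.0
        a_bin = ["joy" if x == "joy" else "other" for x in a]
        b_bin = ["joy" if x == "joy" else "other" for x in b]
        assert k == pytest.approx(kappa_by_contingency(a_bin, b_bin))

    def test_emotion_absent_from_both_is_undefined(self):
        a = ["neutral", "sadness", "neutral"]
        b = ["sadness", "neutral", "neutral"]
        with pytest.raises(UndefinedKappaError):
            per_emotion_kappa(a, b, "anger")


class TestBands:
    @pytest.mark.parametrize("kappa,band", [
        (0.418, "moderate"),
        (0.812, "almost_perfect"),
        (0.20, "slight"),       # closed upper bound
        (0.21, "fair"),
        (0.61, "substantial"),
        (1.0, "almost_perfect"),
        (-0.1, "slight"),
        (0.0, "slight"),
    ])
    def test_band_mapping(self, kappa, band):
        assert band_strength(kappa) == band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            band_strength(1.2)


class TestGroupKappa:
    @staticmethod
    def _panel_table(diag_a, diag_b, n_stimuli=60, seed=0):
        stimuli = [(f"s{i}_{e}", e) for i in range(n_stimuli // 4)
                   for e in ("joy", "neutral", "sadness", "anger")]
        ta = simulate_responses(stimuli, kernel_from_accuracy(diag_a, group_label="A"),
                                6, seed=seed)
        tb = simulate_responses(stimuli, kernel_from_accuracy(diag_b, group_label="B"),
                                6, seed=seed + 999)
        return pd.concat([ta, tb], ignore_index=True)

    def test_identical_experts_full_agreement(self):
        stimuli = [("s1", "joy"), ("s2", "neutral"), ("s3", "sadness")]
        rows = [(f"{g}_e{i}", g, s, e, e)
                for g in ("A", "B") for i in range(3) for s, e in stimuli]
        table = pd.DataFrame(rows, columns=["expert_id", "expert_group",
                                            "stimulus_id", "true_emotion", "response"])
        assert group_kappa(table, "A").kappa == pytest.approx(1.0)
        assert group_kappa(table, "A", "B").kappa == pytest.approx(1.0)

    def test_independent_groups_near_zero(self):
        table = self._panel_table((0.25,) * 4, (0.25,) * 4, n_stimuli=4000, seed=3)
        res = group_kappa(table, "A", "B")
        assert res.scope == "between_group"
        assert abs(res.kappa) <= 0.03

    def test_within_exceeds_between_in_most_replicates(self):
        """In-group agreement from a sharp kernel beats cross-group agreement
        against a diffuse kernel in nearly all replicates."""
        wins = 0
        for seed in range(40):
            table = self._panel_table((0.85,) * 4, (0.45,) * 4, seed=seed)
            within = group_kappa(table, "A").kappa
            between = group_kappa(table, "A", "B").kappa
            wins += within > between
        assert wins >= 36  # >= 90%

    def test_min_experts_enforced(self):
        table = self._panel_table((0.8,) * 4, (0.8,) * 4)
        solo = table[table["expert_id"].isin(["A_e00"])]
        with pytest.raises(InvalidSpecError):
            group_kappa(solo, "A")

    def test_undefined_pairs_skipped_and_counted(self):
        # two experts constant on the same single emotion -> undefined pair
        stimuli = [("s1", "joy"), ("s2", "joy")]
        rows = [(f"A_e{i}", "A", s, e, "joy") for i in range(2) for s, e in stimuli]
        rows += [(f"A_e2", "A", s, e, "neutral") for s, e in stimuli]
        table = pd.DataFrame(rows, columns=["expert_id", "expert_group",
                                            "stimulus_id", "true_emotion", "response"])
        res = group_kappa(table, "A")
        assert res.n_pairs_undefined == 1  # the two all-joy experts
        assert res.n_pairs_averaged == 2

    def test_all_pairs_undefined_raises(self):
        stimuli = [("s1", "joy"), ("s2", "joy")]
        rows = [(f"A_e{i}", "A", s, e, "joy") for i in range(3) for s, e in stimuli]
        table = pd.DataFrame(rows, columns=["expert_id", "expert_group",
                                            "stimulus_id", "true_emotion", "response"])
        with pytest.raises(UndefinedKappaError):
            group_kappa(table, "A")
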