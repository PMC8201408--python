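from itertools import product

import numpy as np
import pytest
from scipy import stats

from elastoselect.evaluation import (
    BENIGN,
    MALIGNANT,
    ConfusionMatrix,
    cv_per_lesion,
    diagnostics,
    dichotomize,
    friedman,
    paired_t,
    roc,
    round_pct,
    wilcoxon_signed_rank,
)


def bruteforce_auc(values, labels):
    """Pairwise Mann–Whitney comparison; ties count 1/2."""
    pos = [v for v, l in zip(values, labels) if l == MALIGNANT]
    neg = [v for v, l in zip(values, labels) if l == BENIGN]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDichotomize:
    @pytest.mark.parametrize("score,expected", [(1, BENIGN), (3, BENIGN), (4, MALIGNANT), (5, MALIGNANT)])
    def test_three_benign_four_malignant(self, score, expected):
        assert dichotomize(score) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(6)


class TestDiagnostics:
    def test_worked_example_confusion_matrix(self):
        d = diagnostics(ConfusionMatrix(tp=45, fn=8, tn=30, fp=8)).as_percentages()
        assert d["acc"] == 82.42
        assert d["sen"] == 84.91
        assert d["spe"] == 78.95

    def test_empty_positive_class_flags_sen(self):
        d = diagnostics(ConfusionMatrix(tp=0, fn=0, tn=10, fp=0))
        assert d.spe == 1.0 and d.sen is None and d.fnr is None

    def test_accuracy_prevalence_identity_on_random_matrices(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0 or tp + fn == 0 or tn + fp == 0:
                continue
            d = diagnostics(ConfusionMatrix(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn)))
            total = tp + fp + tn + fn
            pi = (tp + fn) / total
            assert d.acc == pytest.approx(d.sen * pi + d.spe * (1 - pi), abs=1e-12)

    def test_round_pct_half_away_from_zero(self):
        assert round_pct(82.425) == 82.43
        assert round_pct(82.4249) == 82.42


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 4], [BENIGN, BENIGN, MALIGNANT, MALIGNANT])
        assert r.auc == 1.0
        assert 2 < r.cutoff < 3
        assert r.sens_at_cutoff == 1.0 and r.spec_at_cutoff == 1.0

    def test_chance_level_example(self):
        r = roc([2, 4, 1, 3], [MALIGNANT, BENIGN, BENIGN, MALIGNANT])
        assert r.auc == pytest.approx(0.5)

    def test_all_tied_values_give_half(self):
        r = roc([5, 5, 5, 5], [BENIGN, MALIGNANT, BENIGN, MALIGNANT])
        assert r.auc == pytest.approx(0.5)

    def test_auc_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = np.array([BENIGN, MALIGNANT] + list(rng.choice([BENIGN, MALIGNANT], n - 2)))
            values = rng.integers(0, 10, n).astype(float)  # integer grid forces ties
            auc = bruteforce_auc(values, labels)
            r = roc(values, labels)
            assert r.auc == pytest.approx(max(auc, 1 - auc), abs=1e-12)

    def test_cutoff_reapplied_reproduces_operating_point(self, rng):
        values = rng.normal(size=30)
        labels = np.array([MALIGNANT] * 15 + [BENIGN] * 15)
        values[:15] += 1.0
        r = roc(values, labels)
        pos, neg = values[:15], values[15:]
        if r.direction == "higher=>malignant":
            assert r.sens_at_cutoff == pytest.approx((pos >= r.cutoff).mean())
            assert r.spec_at_cutoff == pytest.approx((neg < r.cutoff).mean())
        else:
            assert r.sens_at_cutoff == pytest.approx((pos <= r.cutoff).mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2], [BENIGN, BENIGN])


class TestCV:
    def test_no_variation(self):
        assert cv_per_lesion(2, 2, 2).cv == 0.0

    def test_hand_computed(self):
        assert cv_per_lesion(1, 2, 3).cv == pytest.approx(0.5)

    def test_continuity_near_constant(self):
        assert cv_per_lesion(5, 5, 5 + 1e-9).cv == pytest.approx(0.0, abs=1e-9)

    def test_zero_mean_flagged(self):
        rec = cv_per_lesion(-1, 0, 1)
        assert not rec.defined and rec.cv is None


class TestCVSummary:
    def test_groupwise_mean_sd_of_per_lesion_cvs(self):
        import pandas as pd

        from elastoselect.evaluation import cv_summary

        rows = []
        for lesion, vals in (("L0", (1, 2, 3)), ("L1", (2, 2, 2))):
            for image_no, v in enumerate(vals, 1):
                rows.append({"lesion_id": lesion, "group": "ml", "image_no": image_no, "sar": v})
        out = cv_summary(pd.DataFrame(rows), metrics=("sar",))
        row = out.set_index(["group", "metric"]).loc[("ml", "sar")]
        # per-lesion CVs are 0.5 and 0.0
        assert row["cv_mean"] == pytest.approx(0.25)
        assert row["cv_sd"] == pytest.approx(np.std([0.5, 0.0], ddof=1))
        assert row["n_lesions"] == 2

    def test_incomplete_lesions_skipped(self):
        import pandas as pd

        from elastoselect.evaluation import cv_summary

        df = pd.DataFrame(
            [{"lesion_id": "L0", "group": "ml", "image_no": 1, "sar": 1.0}]
        )
        with pytest.raises(ValueError):
            cv_summary(df, metrics=("sar",))


class TestPairedT:
    def test_identical_samples_degenerate_p_one(self):
        with pytest.warns(UserWarning):
            r = paired_t([1, 2, 3], [1, 2, 3])
        assert r.degenerate and r.pvalue == 1.0 and r.statistic == 0.0

    def test_constant_nonzero_differences_flagged(self):
        r = paired_t([2, 3, 4, 5], [1, 2, 3, 4])
        assert r.degenerate

    def test_closed_form_t_and_p(self):
        r = paired_t([2, 3, 4], [1, 1, 1])
        assert r.statistic == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-6)
        # two-sided p from the t(2) distribution
        assert r.pvalue == pytest.approx(2 * stats.t.sf(3.4641016, df=2), abs=1e-6)


class TestFriedman:
    def test_constant_rank_pattern_closed_form(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))
        r = friedman(X)
        assert r.statistic == pytest.approx(20.0)  # 12n/(k(k+1)) * sum (Rbar - 2)^2
        assert r.pvalue < 1e-3

    def test_all_equal_rows_statistic_zero(self):
        r = friedman(np.full((5, 3), 7.0))
        assert r.statistic == 0.0 and r.pvalue == 1.0 and r.degenerate

    def test_column_permutation_invariance(self, rng):
        X = rng.normal(size=(12, 3))
        r1 = friedman(X)
        r2 = friedman(X[:, [2, 0, 1]])
        assert r1.statistic == pytest.approx(r2.statistic)


def exact_wilcoxon_p(diffs):
    """Full 2^n sign enumeration of the signed-rank null (no ties)."""
    d = np.asarray(diffs, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d < 0].sum()
    w_all = np.array([ranks[list(signs)].sum() for signs in product([False, True], repeat=len(d))])
    cdf = np.mean(w_all <= observed)
    sf = np.mean(w_all >= observed)
    return min(1.0, 2 * min(cdf, sf))


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        r = wilcoxon_signed_rank([1, 2], [1, 2])
        assert r.degenerate

    def test_all_positive_small_sample(self):
        r = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(0.25)  # 2 * 1/8 sign patterns

    def test_sign_flip_leaves_p_unchanged(self, rng):
        a = rng.normal(size=12)
        b = np.zeros(12)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_exact_p_matches_full_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 11))
            d = rng.normal(size=n)
            while len(np.unique(np.abs(d))) < n or (d == 0).any():
                d = rng.normal(size=n)
            r = wilcoxon_signed_rank(d, np.zeros(n))
            assert r.pvalue == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)
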