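import numpy as np
import pytest

from motera import (auc, choose_cutoff, classify, confusion_metrics, delong_ci,
                    roc_curve)


def auc_pairwise(scores, labels):
    """Exhaustive Mann–Whitney: average over all (positive, negative) pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


def cutoff_brute(scores, labels):
    """Best midpoint threshold by direct enumeration (J, then spec, then -t)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    u = np.unique(s)
    mids = (u[:-1] + u[1:]) / 2 if u.size > 1 else u
    best_key, best_t = None, None
    for t in mids:
        pred = s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        key = (sens + spec - 1.0, spec, -t)
        if best_key is None or key > best_key:
            best_key, best_t = key, t
    return best_t


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_pure_tie(self):
        assert auc([0.6, 0.6], [1, 0]) == pytest.approx(0.5)

    def test_worked_pair_count(self):
        # pairs (0.9,0.5)=1 (0.9,0.1)=1 (0.4,0.5)=0 (0.4,0.1)=1 -> 3/4
        assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pairwise(self):
        """Rank-form AUC equals the pairwise statistic on all small instances."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            n = rng.integers(2, 13)
            y = np.zeros(n, bool)
            y[: rng.integers(1, n)] = True
            rng.shuffle(y)
            s = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert auc(s, y) == pytest.approx(auc_pairwise(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.random(50)
        y = rng.random(50) > 0.5
        y[0], y[1] = True, False
        assert auc(s, y) == pytest.approx(auc(np.exp(3 * s) + 2, y))

    def test_relabel_symmetry(self):
        rng = np.random.default_rng(4)
        s = rng.random(30)
        y = rng.random(30) > 0.4
        y[0], y[1] = True, False
        assert auc(s, y) + auc(s, ~y) == pytest.approx(1.0)


class TestROCCurve:
    def test_perfect_separation_reaches_corner(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ((roc.sens == 1.0) & (roc.spec == 1.0)).any()

    def test_sens_spec_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        roc = roc_curve(rng.random(40), rng.random(40) > 0.5)
        assert (np.diff(roc.sens) <= 1e-12).all()
        assert (np.diff(roc.spec) >= -1e-12).all()

    def test_auc_equals_trapezoidal_area(self):
        rng = np.random.default_rng(9)
        for scores in (rng.random(60), rng.integers(0, 6, size=60).astype(float)):
            y = rng.random(60) > 0.5
            y[0], y[1] = True, False
            roc = roc_curve(scores, y)
            fpr = 1.0 - roc.spec
            area = -np.trapezoid(roc.sens, fpr)  # fpr decreases with threshold
            assert roc.auc == pytest.approx(area, abs=1e-12)

    def test_delong_ci_overlaps_bootstrap(self):
        """DeLong interval agrees with a seeded percentile bootstrap."""
        rng = np.random.default_rng(21)
        pos = rng.normal(0.62, 0.15, 100)
        neg = rng.normal(0.42, 0.15, 100)
        s = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(100, bool), np.zeros(100, bool)])
        a, lo, hi = delong_ci(s, y)
        boots = []
        for _ in range(2000):
            ip = rng.integers(0, 100, 100)
            ineg = rng.integers(0, 100, 100)
            boots.append(auc(np.concatenate([pos[ip], neg[ineg]]), y))
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        assert lo <= a <= hi
        assert max(lo, blo) < min(hi, bhi)  # intervals overlap
        assert abs(lo - blo) < 0.05 and abs(hi - bhi) < 0.05


class TestChooseCutoff:
    def test_perfect_separation_midpoint(self):
        roc = roc_curve([0.8, 0.9, 0.3, 0.2], [1, 1, 0, 0])
        assert choose_cutoff(roc) == pytest.approx(0.55)

    def test_degenerate_identical_scores_warns(self):
        roc = roc_curve([0.4, 0.4, 0.4], [1, 0, 1])
        with pytest.warns(UserWarning, match="degenerate"):
            cutoff = choose_cutoff(roc)
        assert np.isfinite(cutoff)

    @pytest.mark.filterwarnings("ignore:degenerate ROC")
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            n = rng.integers(4, 25)
            y = np.zeros(n, bool)
            y[: rng.integers(1, n)] = True
            rng.shuffle(y)
            s = np.round(rng.random(n), 2)
            assert choose_cutoff(roc_curve(s, y)) == pytest.approx(cutoff_brute(s, y))

    def test_training_cohort_separation(self, training_cohort):
        """On a planted-effect cohort the Youden cutoff should separate classes well."""
        from motera import SignatureDefinition, signature_score

        c = training_cohort
        sig = SignatureDefinition("planted", c.program_genes,
                                  {g: "estrogen_response" for g in c.program_genes})
        scores = signature_score(c.matrix, sig).scores
        ids = c.samples.select(e2="minus_E2")
        truth = c.samples.truth_labels(ids)
        roc = roc_curve(scores.loc[ids].to_numpy(), truth)
        cutoff = choose_cutoff(roc)
        i = int(np.argmin(np.abs(roc.thresholds - cutoff)))
        assert roc.sens[i] + roc.spec[i] - 1.0 >= 0.8


class TestClassify:
    def test_score_at_cutoff_is_active(self):
        assert classify(np.array([0.3283]), 0.3283)[0]

    def test_all_below_cutoff_inactive(self):
        assert not classify(np.array([0.1, 0.2]), 0.5).any()

    def test_weakly_active_below_cutoff_called_inactive(self):
        # a weak driver scoring just under the cutoff is predicted inactive
        scores = np.array([0.9, 0.85, 0.3280, 0.2])
        pred = classify(scores, 0.3283)
        assert list(pred) == [True, True, False, False]

    def test_infinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([0.5]), np.inf)


class TestConfusionMetrics:
    def test_validation_panel_counts(self):
        pred = [True] * 7 + [False] + [False, False]
        truth = [True] * 8 + [False, False]
        rep = confusion_metrics(pred, truth)
        assert (rep.confusion.tp, rep.confusion.tn, rep.confusion.fp, rep.confusion.fn) == (7, 2, 0, 1)
        assert rep.accuracy == pytest.approx(0.900)
        assert rep.sensitivity == pytest.approx(0.875)
        assert rep.specificity == pytest.approx(1.000)

    def test_pdx_panel_counts(self):
        pred = [True] * 11 + [True] + [False] * 8
        truth = [True] * 11 + [False] * 9
        rep = confusion_metrics(pred, truth)
        assert rep.accuracy == pytest.approx(0.950)
        assert rep.sensitivity == pytest.approx(1.000)
        assert rep.specificity == pytest.approx(8 / 9)

    def test_balanced_unit_counts(self):
        rep = confusion_metrics([True, True, False, False], [True, False, True, False])
        assert rep.accuracy == rep.sensitivity == rep.specificity == 0.5

    def test_single_class_truth_reports_none_not_zero(self):
        rep = confusion_metrics([True, False], [True, True])
        assert rep.specificity is None
        assert rep.sensitivity == pytest.approx(0.5)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_metrics([True], [True, False])

    def test_relabel_swaps_sensitivity_and_specificity(self):
        rng = np.random.default_rng(30)
        pred = rng.random(40) > 0.5
        truth = rng.random(40) > 0.5
        truth[0], truth[1] = True, False
        a = confusion_metrics(pred, truth)
        b = confusion_metrics(~pred, ~truth)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
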