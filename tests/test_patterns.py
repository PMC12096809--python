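"""Pattern classifier: smoothing, distances, confusion engine, SI."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import batvoc as bv
from batvoc.calls import InputError
from batvoc.patterns import confusion_from_patterns, gaussian_kernel


def _trial_psth(spike_bins, n_bins=400):
    counts = np.zeros(n_bins)
    for b in spike_bins:
        counts[b] += 1
    return bv.PSTH(1.0, 0.0, counts, n_trials=1)


class TestSmoothing:
    def test_kernel_unit_area(self):
        for w in (2.0, 20.0, 200.0):
            assert gaussian_kernel(w).sum() == pytest.approx(1.0)

    def test_single_spike_bump(self):
        pat = bv.smooth_pattern(_trial_psth([100]), bv.ResponseWindow(50.0, 350.0), 2.0)
        assert pat.values.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.argmax(pat.values) == 100 - 50
        # unimodal: one sign change in the difference
        d = np.sign(np.diff(pat.values[pat.values > 0]))
        assert np.sum(np.diff(d) != 0) <= 1

    def test_empty_trial_all_zero(self):
        pat = bv.smooth_pattern(_trial_psth([]), bv.ResponseWindow(50.0, 350.0), 2.0)
        assert not np.any(pat.values)

    def test_integration_window_merges_peaks(self):
        """Close spikes stay separable at 2-ms smoothing but merge at 200 ms.

        With the sigma = window/6 parameterization two equal Gaussians merge
        into a single maximum once their separation drops below 2 sigma
        (66.7 ms for the 200-ms window): 60-ms-apart spikes merge, while the
        2-ms window resolves them — and both windows resolve 100-ms spacing.
        """
        win = bv.ResponseWindow(50.0, 350.0)

        def n_maxima(v):
            v = np.round(v, 12)
            return int(np.sum((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])))

        close = _trial_psth([170, 230])  # 60 ms apart
        assert n_maxima(bv.smooth_pattern(close, win, 2.0).values) == 2
        assert n_maxima(bv.smooth_pattern(close, win, 200.0).values) == 1
        far = _trial_psth([150, 250])  # 100 ms apart: > 2 sigma even at 200 ms
        assert n_maxima(bv.smooth_pattern(far, win, 200.0).values) == 2

    def test_short_trial_zero_padded(self):
        psth = bv.PSTH(1.0, 0.0, np.ones(100), n_trials=1)
        pat = bv.smooth_pattern(psth, bv.ResponseWindow(50.0, 350.0), 2.0)
        assert len(pat.values) == 300


class TestClassifyTrial:
    def test_identical_template_wins(self):
        rng = np.random.default_rng(0)
        t = bv.SmoothedPattern(np.array([1.0, 0, 2, 0, 1]), 1.0, 2.0)
        templates = {
            "match": bv.SmoothedPattern(t.values.copy(), 1.0, 2.0),
            "other": bv.SmoothedPattern(np.array([0.0, 5, 0, 5, 0]), 1.0, 2.0),
        }
        assert bv.classify_trial(t, templates, rng) == "match"

    def test_forced_choice_uniform_on_ties(self):
        rng = np.random.default_rng(1)
        test = bv.SmoothedPattern(np.zeros(5), 1.0, 2.0)
        same = np.array([1.0, 0, 0, 0, 0])
        templates = {k: bv.SmoothedPattern(np.roll(same, i), 1.0, 2.0)
                     for i, k in enumerate("abc")}
        picks = [bv.classify_trial(test, templates, rng) for _ in range(3000)]
        freqs = np.array([picks.count(k) for k in "abc"]) / 3000
        assert np.all(np.abs(freqs - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 3000))

    def test_hand_computed_distances(self):
        """Assignment must match exhaustive hand-computed distances."""
        test = bv.SmoothedPattern(np.array([1.0, 2, 0, 0, 1]), 1.0, 2.0)
        tmpl = {
            "a": np.array([1.0, 2, 0, 0, 0]),   # d = 1
            "b": np.array([0.0, 2, 0, 0, 1]),   # d = 1
            "c": np.array([1.0, 2, 1, 0, 1]),   # d = 1  -> three-way tie
            "d": np.array([4.0, 2, 0, 0, 1]),   # d = 3
        }
        dists = {k: np.linalg.norm(test.values - v) for k, v in tmpl.items()}
        assert dists == {"a": 1.0, "b": 1.0, "c": 1.0, "d": 3.0}
        rng = np.random.default_rng(2)
        picks = {bv.classify_trial(
            test, {k: bv.SmoothedPattern(v, 1.0, 2.0) for k, v in tmpl.items()}, rng)
            for _ in range(200)}
        assert picks == {"a", "b", "c"}

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InputError):
            bv.classify_trial(
                bv.SmoothedPattern(np.zeros(5), 1.0, 2.0),
                {"a": bv.SmoothedPattern(np.zeros(6), 1.0, 2.0)},
                rng,
            )


def enumerate_confusion(patterns, call_classes):
    """Exhaustive oracle: average assignment over every (test trial,
    template tuple) combination, with fractional credit on distance ties."""
    patterns = np.asarray(patterns, float)
    n_calls, n_trials, _ = patterns.shape
    classes = list(dict.fromkeys(call_classes))
    cls = [classes.index(c) for c in call_classes]
    K = len(classes)
    probs = np.zeros((K, K))
    row_weight = np.zeros(K)
    for i in range(n_calls):
        for t in range(n_trials):
            test = patterns[i, t]
            pools = [
                [s for s in range(n_trials) if not (j == i and s == t)]
                for j in range(n_calls)
            ]
            total = 0
            acc = np.zeros(K)
            for combo in itertools.product(*pools):
                d = np.array(
                    [np.linalg.norm(test - patterns[j, combo[j]]) for j in range(n_calls)]
                )
                tied = np.nonzero(np.isclose(d, d.min(), rtol=0, atol=1e-12))[0]
                tied_classes = sorted({cls[j] for j in tied})
                for c in tied_classes:
                    acc[c] += 1.0 / len(tied_classes)
                total += 1
            probs[cls[i]] += acc / total
            row_weight[cls[i]] += 1
    return probs / row_weight[:, None]


class TestConfusionEngine:
    def test_rows_sum_to_one_and_deterministic(self, dac_call_data, categories):
        cm1 = bv.confusion_matrix(dac_call_data, categories, "category", 2.0,
                                  n_resamples=1500, seed=42)
        cm2 = bv.confusion_matrix(dac_call_data, categories, "category", 2.0,
                                  n_resamples=1500, seed=42)
        assert np.allclose(cm1.probs.sum(axis=1), 1.0)
        assert np.array_equal(cm1.counts, cm2.counts)
        assert np.all((cm1.probs >= 0) & (cm1.probs <= 1))

    def test_disjoint_patterns_identity(self):
        """Deterministic patterns with disjoint support give the identity."""
        pats = np.zeros((6, 4, 30))
        for call in range(6):
            pats[call, :, 5 * call : 5 * call + 3] = 1.0
        classes = ["A", "A", "B", "B", "C", "C"]
        cm = confusion_from_patterns(pats, classes, n_resamples=3000, seed=0)
        assert np.array_equal(cm.probs, np.eye(3))

    def test_engine_matches_exhaustive_enumeration(self):
        """Resampling converges to the exhaustive oracle (tiny problem)."""
        rng = np.random.default_rng(3)
        pats = rng.poisson(0.8, size=(3, 4, 6)).astype(float)
        classes = ["x", "y", "z"]
        oracle = enumerate_confusion(pats, classes)
        n = 60_000
        cm = confusion_from_patterns(pats, classes, n_resamples=n, seed=5)
        se = np.sqrt(np.clip(oracle * (1 - oracle), 1e-4, None) / (n / 3))
        assert np.all(np.abs(cm.probs - oracle) < 2.5 * se)

    def test_within_category_level(self, dac_call_data, categories):
        cm = bv.confusion_matrix(dac_call_data, categories, "within:aggression",
                                 2.0, n_resamples=1000, seed=7)
        assert len(cm.labels) == 5
        assert all(categories[lab] == "aggression" for lab in cm.labels)

    def test_too_few_trials_rejected(self):
        with pytest.raises(InputError):
            confusion_from_patterns(np.zeros((3, 1, 5)), ["a", "b", "c"], 10, 0)


class TestSelectivityIndex:
    def test_perfect_row_is_one(self):
        assert bv.selectivity_index(np.array([1.0, 0.0, 0.0])).si == 1.0

    def test_chance_row_is_zero(self):
        assert bv.selectivity_index(np.array([1, 1, 1]) / 3).si == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # rest = {0.3, 0.2}: mean 0.25, sample SD 0.05/sqrt(2)*2 = 0.0707
        si = bv.selectivity_index(np.array([0.5, 0.3, 0.2]))
        assert si.si == pytest.approx(0.5 - (0.25 + np.std([0.3, 0.2], ddof=1)))
        assert si.best_class == "0"

    @given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=6))
    @settings(max_examples=100, derandomize=True)
    def test_si_never_exceeds_one(self, vals):
        row = np.asarray(vals)
        if row.sum() == 0:
            row = row + 1.0
        row = row / row.sum()
        assert bv.selectivity_index(row).si <= 1.0 + 1e-12

    def test_si_decreases_toward_chance(self):
        """Equalizing off-diagonal mass upward toward chance lowers the SI."""
        sis = [bv.selectivity_index(np.array([1 - 2 * q, q, q])).si
               for q in (0.0, 0.1, 0.2, 0.3, 1 / 3)]
        assert all(a > b for a, b in zip(sis, sis[1:]))
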