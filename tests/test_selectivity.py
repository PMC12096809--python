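"""Response-strength selectivity: windows, strengths, PIcat/PIcall."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import batvoc as bv
from batvoc.calls import InputError
from batvoc.psth import NonResponsiveError


def _psth_from_counts(counts, bin_ms=2.0, t0=0.0):
    return bv.PSTH(bin_ms, t0, np.asarray(counts), n_trials=20)


class TestSharedWindow:
    def test_longest_epoch_sets_length(self):
        """One call evoking [55, 150] ms and a later/shorter one: the shared
        window starts at the earliest onset and spans the longest duration."""
        n = 150  # 2-ms bins over [0, 300)
        base = np.ones(n)
        a = base.copy()
        a[int(55 / 2): int(150 / 2)] = 12.0   # epoch 55..150
        b = base.copy()
        b[int(70 / 2): int(100 / 2)] = 12.0   # epoch 70..100
        win = bv.shared_response_window(
            {"a": _psth_from_counts(a), "b": _psth_from_counts(b)}
        )
        assert win.start_ms == pytest.approx(54.0, abs=2.0)
        assert win.length_ms == pytest.approx(96.0, abs=2.0)

    def test_all_baseline_raises(self):
        flat = {"a": _psth_from_counts(np.ones(150))}
        with pytest.raises(NonResponsiveError):
            bv.shared_response_window(flat)

    def test_simulated_faf_window_length(self, faf_call_data, categories):
        """FAF-like window must be close to the programmed response duration."""
        pref = bv.preference_result(faf_call_data, categories)
        programmed = 95.0
        assert pref.window.length_ms == pytest.approx(programmed, rel=0.35)


class TestResponseStrength:
    def test_max_bin_in_window(self):
        psth = _psth_from_counts([0, 3, 7, 2, 9])
        # window covering bins 0..3 only: max is 7, the 9 outside is ignored
        assert bv.call_response_strength(psth, bv.ResponseWindow(0.0, 8.0)) == 7.0

    def test_spikes_outside_window_do_not_matter(self):
        a = _psth_from_counts([5, 1, 1, 0, 0])
        b = _psth_from_counts([5, 1, 1, 99, 99])
        w = bv.ResponseWindow(0.0, 6.0)
        assert bv.call_response_strength(a, w) == bv.call_response_strength(b, w)

    def test_window_outside_psth_rejected(self):
        with pytest.raises(InputError):
            bv.call_response_strength(_psth_from_counts([1, 2]), bv.ResponseWindow(0.0, 100.0))


class TestPreferenceIndices:
    @pytest.mark.parametrize(
        "responses,expected",
        [((100.0, 40.0, 10.0), 1), ((100.0, 100.0, 100.0), 3), ((100.0, 50.0, 49.0), 2)],
    )
    def test_pi_cat_examples(self, responses, expected):
        assert bv.pi_cat(np.asarray(responses)) == expected

    @pytest.mark.parametrize(
        "responses,expected",
        [((10, 1, 1, 1, 1), 1), ((10, 10, 10, 10, 10), 5), ((10, 5, 4, 4, 4), 2)],
    )
    def test_pi_call_examples(self, responses, expected):
        assert bv.pi_call(np.asarray(responses, float)) == expected

    def test_all_zero_raises(self):
        with pytest.raises(NonResponsiveError):
            bv.pi_cat(np.zeros(3))

    @given(
        vals=st.lists(st.floats(0.1, 1e6), min_size=3, max_size=3),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, derandomize=True)
    def test_pi_cat_scale_invariant(self, vals, scale):
        v = np.asarray(vals)
        assert bv.pi_cat(v) == bv.pi_cat(v * scale)

    @given(st.data())
    @settings(max_examples=50, derandomize=True)
    def test_raising_subthreshold_response_never_decreases_pi_cat(self, data):
        v = np.array(data.draw(st.lists(st.floats(1.0, 100.0), min_size=3, max_size=3)))
        before = bv.pi_cat(v)
        i = int(np.argmin(v))
        v2 = v.copy()
        v2[i] = 0.5 * v2.max()  # lift the weakest to exactly 50% of max
        assert bv.pi_cat(v2) >= before


def test_preference_result_weighted_unit(library, categories, call_protocol):
    """A unit strongly weighted to aggression calls must yield PIcat = 1."""
    prof = bv.UnitProfile(
        unit_id="sel", response_kernel="tonic", latency_ms=10.0,
        response_duration_ms=80.0, baseline_rate_hz=2.0, driven_gain_hz=250.0,
        jitter_ms=1.0,
        category_weights={"echolocation": 0.1, "appeasement": 0.1, "aggression": 1.0},
    )
    data = {c.call_id: bv.simulate_call_response(prof, c, call_protocol) for c in library}
    pref = bv.preference_result(data, categories)
    assert pref.pi_cat == 1
    assert max(pref.per_category_response, key=pref.per_category_response.get) == "aggression"


def test_population_pi_cat_weighted_vs_unweighted(library, categories, call_protocol):
    """Cohort with 1:0.3:0.3 category weights shows more PIcat=1 units than
    an unweighted cohort.

    Tonic units are used so that max-bin response strength reflects the
    programmed category weight rather than call-envelope geometry."""
    import dataclasses

    base = bv.UnitProfile(
        unit_id="pi", response_kernel="tonic", latency_ms=10.0,
        response_duration_ms=80.0, baseline_rate_hz=2.0, driven_gain_hz=250.0,
        jitter_ms=1.0,
    )
    selective = dataclasses.replace(
        base, unit_id="sel",
        category_weights={"echolocation": 1.0, "appeasement": 0.3, "aggression": 0.3},
    )
    flat = dataclasses.replace(base, unit_id="flat")
    n = 8
    frac = {}
    for name, template in (("sel", selective), ("flat", flat)):
        pop = bv.make_population([(template, n)], seed=21)
        hits = 0
        for prof in pop:
            data = {c.call_id: bv.simulate_call_response(prof, c, call_protocol) for c in library}
            try:
                hits += bv.preference_result(data, categories).pi_cat == 1
            except NonResponsiveError:
                pass
        frac[name] = hits / n
    assert frac["sel"] > frac["flat"]
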