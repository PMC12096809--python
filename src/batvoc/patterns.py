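"""Single-trial spike-pattern classification and the selectivity index.

The core computation: each single-trial response (1-ms PSTH, smoothed
with a Gaussian integration window of 2 or 200 ms, restricted to the
shared response window) is assigned to the call — and hence category —
whose randomly drawn template trial lies at the smallest Euclidean
distance.  Repeating this 10,000 times builds a row-stochastic confusion
matrix; the selectivity index summarises how concentrated a row is:

    SI = max(row) − (mean + SD of the remaining entries)

with an upper bound of 1 for a perfectly selective row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .calls import CATEGORIES, InputError
from .psth import PSTH, ResponseWindow, single_trial_psths
from .selectivity import shared_response_window
from .units import SpikeTrainSet, _stream
from .psth import build_psth

PATTERN_BIN_MS = 1.0
DEFAULT_N_RESAMPLES = 10_000


@dataclass(frozen=True)
class SmoothedPattern:
    """A smoothed single-trial PSTH restricted to the shared window."""

    values: np.ndarray
    bin_width_ms: float
    integration_window_ms: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


@dataclass
class ConfusionMatrix:
    """Row-stochastic assignment-probability matrix.

    Rows are the true class of the test trial, columns the assigned
    class; ``counts`` holds the raw assignment tallies.
    """

    labels: list[str]
    probs: np.ndarray
    counts: np.ndarray
    n_resamples: int

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.probs)

    def row(self, label: str) -> np.ndarray:
        return self.probs[self.labels.index(label)]


@dataclass(frozen=True)
class SelectivityIndex:
    si: float
    best_class: str


def gaussian_kernel(integration_window_ms: float, bin_width_ms: float = 1.0) -> np.ndarray:
    """Unit-area Gaussian kernel with sigma = window/6, truncated at ±3 sigma."""
    if integration_window_ms <= 0:
        raise InputError("integration window must be positive")
    sigma_bins = (integration_window_ms / 6.0) / bin_width_ms
    half = max(1, int(round(3.0 * sigma_bins)))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma_bins**2))
    return k / k.sum()


def _window_slice(window: ResponseWindow, t0_ms: float, bin_width_ms: float) -> tuple[int, int]:
    i0 = int(round((window.start_ms - t0_ms) / bin_width_ms))
    n = int(round(window.length_ms / bin_width_ms))
    return i0, i0 + n


def smooth_pattern(
    trial_psth: PSTH, window: ResponseWindow, integration_window_ms: float
) -> SmoothedPattern:
    """Convolve a single-trial 1-ms PSTH and restrict it to the window.

    The convolution uses 'same'-length output; patterns from trials
    shorter than the window are zero-padded so all patterns of a unit
    share one dimension.
    """
    if abs(trial_psth.bin_width_ms - PATTERN_BIN_MS) > 1e-9:
        raise InputError("pattern classification expects 1-ms PSTH bins")
    if window.start_ms < trial_psth.t0_ms - 1e-9:
        raise InputError("window starts before the PSTH")
    kernel = gaussian_kernel(integration_window_ms, trial_psth.bin_width_ms)
    smoothed = np.convolve(trial_psth.counts.astype(float), kernel, mode="same")
    i0, i1 = _window_slice(window, trial_psth.t0_ms, trial_psth.bin_width_ms)
    if i1 > len(smoothed):
        smoothed = np.pad(smoothed, (0, i1 - len(smoothed)))
    return SmoothedPattern(
        values=smoothed[i0:i1],
        bin_width_ms=trial_psth.bin_width_ms,
        integration_window_ms=integration_window_ms,
    )


def classify_trial(
    test: SmoothedPattern,
    templates: dict[str, SmoothedPattern],
    rng: np.random.Generator,
) -> str:
    """Nearest-template assignment with uniform forced choice on exact ties."""
    lengths = {len(t.values) for t in templates.values()} | {len(test.values)}
    if len(lengths) != 1:
        raise InputError("all patterns must share one length")
    labels = list(templates)
    d = np.array([np.linalg.norm(test.values - templates[c].values) for c in labels])
    tied = np.nonzero(d == d.min())[0]
    if len(tied) == 1:
        return labels[tied[0]]
    return labels[rng.choice(tied)]


def _smoothed_trial_matrix(
    unit_data: dict[str, SpikeTrainSet],
    call_ids: list[str],
    window: ResponseWindow,
    integration_window_ms: float,
) -> np.ndarray:
    """(n_calls, n_trials, n_bins) smoothed window-restricted patterns."""
    kernel = gaussian_kernel(integration_window_ms, PATTERN_BIN_MS)
    n_trials = min(unit_data[c].n_trials for c in call_ids)
    if n_trials < 2:
        raise InputError("need at least 2 trials per call")
    i0, i1 = _window_slice(window, 0.0, PATTERN_BIN_MS)
    mats = []
    for cid in call_ids:
        sts = unit_data[cid]
        raw = single_trial_psths(
            sts.trials[:n_trials], PATTERN_BIN_MS, 0.0, sts.protocol.trial_length_ms
        )
        pad = max(0, i1 - raw.shape[1])
        if pad:
            raw = np.pad(raw, ((0, 0), (0, pad)))
        sm = np.array([np.convolve(r, kernel, mode="same") for r in raw])
        mats.append(sm[:, i0:i1])
    return np.stack(mats)


def confusion_from_patterns(
    patterns: np.ndarray,
    call_classes: list[str],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> ConfusionMatrix:
    """Resampling classification engine on precomputed patterns.

    ``patterns`` has shape (n_calls, n_trials, n_bins); ``call_classes``
    gives each call's class label (its category, or its own id for
    within-category classification).  Per resample a stratified test
    (call, trial) is drawn — calls take turns as test call so every call
    is tested equally often — plus one random template trial per
    candidate call, excluding the test trial for the test call itself.
    Assignment goes to the class of the nearest template; exact distance
    ties are resolved uniformly among the tied classes (forced choice).
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    n_calls, n_trials, _ = patterns.shape
    if n_trials < 2:
        raise InputError("need at least 2 trials per call")
    classes = list(dict.fromkeys(call_classes))
    class_idx = np.array([classes.index(c) for c in call_classes])
    K = len(classes)

    flat = patterns.reshape(n_calls * n_trials, -1)
    D = cdist(flat, flat, metric="euclidean")

    rng = _stream(seed, "confusion")
    test_calls = np.arange(n_resamples) % n_calls
    test_trials = rng.integers(0, n_trials, n_resamples)
    tmpl = rng.integers(0, n_trials, (n_resamples, n_calls))
    # the test call's template must come from a different trial
    excl = rng.integers(0, n_trials - 1, n_resamples)
    excl = excl + (excl >= test_trials)
    tmpl[np.arange(n_resamples), test_calls] = excl

    rows = test_calls * n_trials + test_trials
    cols = np.arange(n_calls)[None, :] * n_trials + tmpl
    d = D[rows[:, None], cols]  # (n_resamples, n_calls)

    dmin = d.min(axis=1)
    tie_mask = d == dmin[:, None]
    n_tied = tie_mask.sum(axis=1)
    assigned_call = np.argmin(d, axis=1)
    assigned_class = class_idx[assigned_call]
    for r in np.nonzero(n_tied > 1)[0]:
        tied_classes = np.unique(class_idx[np.nonzero(tie_mask[r])[0]])
        assigned_class[r] = tied_classes[rng.integers(len(tied_classes))]

    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (class_idx[test_calls], assigned_class), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, row_sums, out=np.zeros_like(counts, dtype=float), where=row_sums > 0)
    return ConfusionMatrix(labels=classes, probs=probs, counts=counts, n_resamples=n_resamples)


def confusion_matrix(
    unit_data: dict[str, SpikeTrainSet],
    categories: dict[str, str],
    level: str = "category",
    integration_window_ms: float = 2.0,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    window: ResponseWindow | None = None,
    pre_ms: float = 50.0,
) -> ConfusionMatrix:
    """Category-level (3x3) or within-category (5x5) confusion matrix.

    ``level`` is ``"category"`` or ``"within:<category>"``.  At category
    level the classifier compares the test trial against one template per
    each of the 15 calls and assigns the winning call's category; within a
    category it compares against that category's 5 calls only.  If
    ``window`` is None the shared response window is derived from 2-ms
    trial-summed PSTHs of all supplied calls.
    """
    if window is None:
        psths = {
            cid: build_psth(s.trials, 2.0, 0.0, s.protocol.trial_length_ms)
            for cid, s in unit_data.items()
        }
        window = shared_response_window(psths, pre_ms=pre_ms)

    if level == "category":
        call_ids = [c for cat in CATEGORIES for c in sorted(unit_data) if categories[c] == cat]
        call_classes = [categories[c] for c in call_ids]
    elif level.startswith("within:"):
        cat = level.split(":", 1)[1]
        if cat not in CATEGORIES:
            raise InputError(f"unknown category {cat!r}")
        call_ids = sorted(c for c in unit_data if categories[c] == cat)
        call_classes = list(call_ids)
    else:
        raise InputError(f"unknown level {level!r}")
    if not call_ids:
        raise InputError("no calls to classify")

    patterns = _smoothed_trial_matrix(unit_data, call_ids, window, integration_window_ms)
    return confusion_from_patterns(patterns, call_classes, n_resamples=n_resamples, seed=seed)


def selectivity_index(probs_row: np.ndarray, labels: list[str] | None = None, ddof: int = 1) -> SelectivityIndex:
    """SI = max probability − (mean + SD of the remaining probabilities).

    The SD uses the sample (n−1) convention by default; with a single
    remaining value the SD term is 0.  The highest possible value is 1
    (a perfectly selective row).
    """
    row = np.asarray(probs_row, dtype=float)
    if row.ndim != 1 or len(row) < 2:
        raise InputError("need a probability row of length >= 2")
    i = int(np.argmax(row))
    rest = np.delete(row, i)
    sd = float(np.std(rest, ddof=ddof)) if len(rest) > 1 else 0.0
    si = float(row[i] - (np.mean(rest) + sd))
    label = labels[i] if labels is not None else str(i)
    return SelectivityIndex(si=si, best_class=label)
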