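"""Response-strength selectivity: shared window, PIcat and PIcall.

Response strength of a call is the maximum spike count per 2-ms PSTH bin
(summed over the 20 presentations) inside a response window shared across
all 15 calls.  The category preference index PIcat counts the categories
whose summed response reaches at least 50% of the maximum category
response (1 = highly selective, 3 = unselective); PIcall does the same
for the five calls within a category (1..5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import CATEGORIES, InputError
from .psth import PSTH, NonResponsiveError, ResponseWindow, build_psth, evoked_epoch
from .units import SpikeTrainSet

STRENGTH_BIN_MS = 2.0


@dataclass
class PreferenceResult:
    """Per-unit preference indices and the responses they derive from."""

    unit_id: str
    pi_cat: int
    pi_call: dict[str, int]
    per_call_response: dict[str, float]
    per_category_response: dict[str, float]
    window: ResponseWindow


def shared_response_window(
    all_call_psths: dict[str, PSTH],
    pre_ms: float = 50.0,
    n_sd: float = 2.0,
    max_gap_ms: float = 15.0,
) -> ResponseWindow:
    """Shared analysis window across the call set.

    Each call's evoked epoch is detected with the mean + 2·SD
    pre-stimulus criterion; the shared window starts at the earliest
    onset over calls and its length equals the longest per-call evoked
    duration, matching the longest response any call evokes.
    """
    onsets, durations = [], []
    for psth in all_call_psths.values():
        try:
            a, b = evoked_epoch(psth, pre_ms=pre_ms, n_sd=n_sd, max_gap_ms=max_gap_ms)
        except NonResponsiveError:
            continue
        onsets.append(a)
        durations.append(b - a)
    if not onsets:
        raise NonResponsiveError("no call evokes a response above the criterion")
    start = min(onsets)
    return ResponseWindow(start_ms=start, end_ms=start + max(durations))


def call_response_strength(psth: PSTH, window: ResponseWindow) -> float:
    """Maximum spikes per bin within the window (0 for an empty selection)."""
    centers = psth.bin_centers_ms
    if window.start_ms < psth.t0_ms - 1e-9 or window.end_ms > psth.bin_edges_ms[-1] + 1e-9:
        raise InputError("window extends outside the PSTH")
    mask = (centers >= window.start_ms) & (centers < window.end_ms)
    if not np.any(mask):
        return 0.0
    return float(np.max(psth.counts[mask]))


def pi_cat(per_category_response: dict[str, float] | np.ndarray) -> int:
    """Categories whose response is >= 50% of the maximum (1..3)."""
    vals = np.asarray(
        [per_category_response[c] for c in CATEGORIES]
        if isinstance(per_category_response, dict)
        else per_category_response,
        dtype=float,
    )
    if len(vals) != 3:
        raise InputError("expected 3 category responses")
    return _preference_count(vals)


def pi_call(per_call_response: dict[str, float] | np.ndarray) -> int:
    """Calls within one category whose response is >= 50% of the maximum (1..5)."""
    vals = np.asarray(
        list(per_call_response.values())
        if isinstance(per_call_response, dict)
        else per_call_response,
        dtype=float,
    )
    if len(vals) != 5:
        raise InputError("expected 5 per-call responses")
    return _preference_count(vals)


def _preference_count(vals: np.ndarray) -> int:
    if np.any(vals < 0):
        raise InputError("response strengths must be non-negative")
    m = np.max(vals)
    if m == 0:
        raise NonResponsiveError("all responses are zero")
    return int(np.count_nonzero(vals >= 0.5 * m))


def preference_result(
    unit_data: dict[str, SpikeTrainSet],
    categories: dict[str, str],
    pre_ms: float = 50.0,
    bin_width_ms: float = STRENGTH_BIN_MS,
    window: ResponseWindow | None = None,
) -> PreferenceResult:
    """PIcat and PIcall for one unit from its 15 call responses.

    ``unit_data`` maps call_id -> SpikeTrainSet, ``categories`` maps
    call_id -> category name.  The category response is the sum of the
    five per-call maximum-bin strengths.
    """
    psths = {
        cid: build_psth(sts.trials, bin_width_ms, 0.0, sts.protocol.trial_length_ms)
        for cid, sts in unit_data.items()
    }
    if window is None:
        window = shared_response_window(psths, pre_ms=pre_ms)
    per_call = {cid: call_response_strength(p, window) for cid, p in psths.items()}
    per_cat = {
        cat: float(sum(v for cid, v in per_call.items() if categories[cid] == cat))
        for cat in CATEGORIES
    }
    pc = pi_cat(per_cat)
    pcalls = {}
    for cat in CATEGORIES:
        vals = {cid: per_call[cid] for cid in per_call if categories[cid] == cat}
        try:
            pcalls[cat] = pi_call(vals)
        except NonResponsiveError:
            pcalls[cat] = 0  # category evoked nothing; no within-category index
    unit_id = next(iter(unit_data.values())).unit_id
    return PreferenceResult(
        unit_id=unit_id,
        pi_cat=pc,
        pi_call=pcalls,
        per_call_response=per_call,
        per_category_response=per_cat,
        window=window,
    )
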