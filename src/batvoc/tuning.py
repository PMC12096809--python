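"""Pure-tone response characterization: FRA, BF, CF, Q10dB, latency, duration.

The frequency-response area (FRA) holds the median spontaneous-subtracted
spike count per (frequency, level) cell over the tone repetitions.  A cell
counts as responsive when its median count exceeds the pre-stimulus
activity by more than twice its SD (both scaled to the counting window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import InputError
from .psth import PSTH, NonResponsiveError, build_psth, evoked_epoch
from .units import SpikeTrainSet


@dataclass
class FRA:
    """Frequency-response area.

    ``response[i, j]`` is the median spontaneous-subtracted spike count at
    ``levels_db[i]`` (ascending) and ``freqs_khz[j]`` (ascending), counted
    from stimulus onset over ``window_ms``.  ``spontaneous_rate`` is the
    mean spikes per trial in the 50-ms pre-stimulus window.
    """

    freqs_khz: np.ndarray
    levels_db: np.ndarray
    response: np.ndarray
    spontaneous_rate: float
    criterion: float  # responsive iff spont-subtracted median count > criterion
    pre_ms: float = 50.0
    window_ms: float = 100.0

    @property
    def responsive_mask(self) -> np.ndarray:
        return self.response > self.criterion

    @property
    def responsive(self) -> bool:
        return bool(np.any(self.responsive_mask))

    def main_component_mask(self) -> np.ndarray:
        """Responsive cells 4-connected to the strongest-response cell.

        Isolated suprathreshold cells elsewhere in the grid are almost
        always spontaneous-count false positives (462 cells are screened);
        CF and Q10dB are therefore read off the contiguous excitatory
        region around BF rather than the raw mask.
        """
        mask = self.responsive_mask
        if not mask.any():
            return mask
        from scipy.ndimage import label

        lab, _ = label(mask)
        best = np.unravel_index(int(np.argmax(np.where(mask, self.response, -np.inf))), mask.shape)
        return lab == lab[best]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.response, index=self.levels_db, columns=self.freqs_khz)


@dataclass
class TuningSummary:
    """Per-unit derived pure-tone metrics."""

    unit_id: str
    responsive: bool
    bf_khz: float = np.nan
    bf_threshold_db: float = np.nan
    cf_khz: float = np.nan
    cf_threshold_db: float = np.nan
    q10: float = np.nan
    q10_censored: bool = False
    latency_ms: float = np.nan
    response_duration_ms: float = np.nan


def compute_fra(
    grid_responses: dict[tuple[float, float], SpikeTrainSet],
    pre_ms: float = 50.0,
    window_ms: float = 100.0,
    n_sd: float = 2.0,
) -> FRA:
    """Build an FRA from a complete (frequency x level) grid of responses.

    The spontaneous criterion pools pre-stimulus counts from every trial of
    every grid cell; counts are scaled to the response window assuming
    Poisson-like scaling (mean linearly, SD with the square root).
    """
    if not grid_responses:
        raise InputError("empty grid")
    freqs = np.array(sorted({f for f, _ in grid_responses}))
    levels = np.array(sorted({lv for _, lv in grid_responses}))
    for f in freqs:
        for lv in levels:
            if (float(f), float(lv)) not in grid_responses:
                raise InputError(f"missing grid cell ({f} kHz, {lv} dB)")

    onset = next(iter(grid_responses.values())).protocol.pre_stimulus_ms
    pre_counts = []
    raw_median = np.zeros((len(levels), len(freqs)))
    for j, f in enumerate(freqs):
        for i, lv in enumerate(levels):
            sts = grid_responses[(float(f), float(lv))]
            pre_counts.append(sts.spike_count(onset - pre_ms, onset))
            raw_median[i, j] = float(np.median(sts.spike_count(onset, onset + window_ms)))

    pre_counts = np.concatenate(pre_counts)
    scale = window_ms / pre_ms
    mu_w = float(np.mean(pre_counts)) * scale
    sd_w = float(np.std(pre_counts, ddof=0)) * np.sqrt(scale)
    spont_rate = float(np.mean(pre_counts))

    return FRA(
        freqs_khz=freqs,
        levels_db=levels,
        response=raw_median - mu_w,
        spontaneous_rate=spont_rate,
        criterion=n_sd * sd_w,
        pre_ms=pre_ms,
        window_ms=window_ms,
    )


def best_frequency(fra: FRA) -> tuple[float, float]:
    """BF = frequency of the strongest-response cell (with its SPL).

    Ties are broken toward the lowest frequency, then the highest level.
    """
    if not fra.responsive:
        raise NonResponsiveError("no responsive FRA cell")
    best = np.max(fra.response)
    ii, jj = np.nonzero(fra.response == best)
    j = np.min(jj)
    i = np.max(ii[jj == j])
    return float(fra.freqs_khz[j]), float(fra.levels_db[i])


def characteristic_frequency(fra: FRA) -> tuple[float, float]:
    """CF = responsive frequency with the lowest threshold level.

    Ties at the minimal level are broken toward the frequency closest to
    BF (then toward the lower frequency).  Only the contiguous responsive
    region around BF is considered (see :meth:`FRA.main_component_mask`).
    """
    if not fra.responsive:
        raise NonResponsiveError("no responsive FRA cell")
    mask = fra.main_component_mask()
    ii, jj = np.nonzero(mask)
    i_min = np.min(ii)
    cand = jj[ii == i_min]
    bf, _ = best_frequency(fra)
    dist = np.abs(np.log2(fra.freqs_khz[cand] / bf))
    j = cand[np.lexsort((fra.freqs_khz[cand], dist))][0]
    return float(fra.freqs_khz[j]), float(fra.levels_db[i_min])


def q10db(fra: FRA, cf_khz: float, cf_threshold_db: float) -> tuple[float, bool]:
    """Sharpness of tuning: CF / bandwidth 10 dB above CF threshold.

    The bandwidth edges are found by linear interpolation (in log2
    frequency, against the responsiveness criterion) between the outermost
    responsive cells of the run containing CF and their non-responsive
    neighbours.  Returns ``(q10, censored)``; ``censored`` is True when the
    responsive run touches the frequency-grid edge or the required level
    row lies outside the grid.
    """
    target = cf_threshold_db + 10.0
    if target > fra.levels_db[-1] + 1e-9:
        return np.nan, True
    i = int(np.argmin(np.abs(fra.levels_db - target)))
    row = fra.response[i]
    mask = fra.main_component_mask()[i]
    j_cf = int(np.argmin(np.abs(np.log2(fra.freqs_khz / cf_khz))))
    if not mask[j_cf]:
        # CF cell itself not responsive at +10 dB: fall back to the nearest
        # responsive cell in the row, if any
        resp_idx = np.nonzero(mask)[0]
        if len(resp_idx) == 0:
            return np.nan, True
        j_cf = int(resp_idx[np.argmin(np.abs(resp_idx - j_cf))])
    lo = j_cf
    while lo - 1 >= 0 and mask[lo - 1]:
        lo -= 1
    hi = j_cf
    while hi + 1 < len(mask) and mask[hi + 1]:
        hi += 1

    logf = np.log2(fra.freqs_khz)
    censored = False
    if lo == 0:
        f_lo = fra.freqs_khz[0]
        censored = True
    else:
        frac = (row[lo] - fra.criterion) / (row[lo] - row[lo - 1])
        f_lo = float(2.0 ** (logf[lo] + frac * (logf[lo - 1] - logf[lo])))
    if hi == len(mask) - 1:
        f_hi = fra.freqs_khz[-1]
        censored = True
    else:
        frac = (row[hi] - fra.criterion) / (row[hi] - row[hi + 1])
        f_hi = float(2.0 ** (logf[hi] + frac * (logf[hi + 1] - logf[hi])))
    bw = f_hi - f_lo
    if bw <= 0:
        return np.nan, True
    return float(cf_khz / bw), censored


def latency_and_duration(
    psth: PSTH,
    pre_ms: float = 50.0,
    n_sd: float = 2.0,
    max_gap_ms: float = 15.0,
    min_consecutive: int = 3,
) -> tuple[float, float]:
    """Response latency and duration from a 1-ms PSTH covering 50 ms pre.

    Latency is the time from stimulus onset to the first run of
    ``min_consecutive`` bins above mean + ``n_sd``·SD of the pre-stimulus
    bins; duration spans from there to the end of the evoked epoch.  At
    1-ms resolution three consecutive bins are required: PSTHs pooled
    over hundreds of trials occasionally produce two adjacent
    suprathreshold baseline bins, which would register as spurious early
    onsets.  Raises :class:`NonResponsiveError` if activity never crosses
    the criterion.
    """
    onset_ms, offset_ms = evoked_epoch(
        psth, pre_ms=pre_ms, n_sd=n_sd, max_gap_ms=max_gap_ms,
        min_consecutive=min_consecutive,
    )
    return onset_ms - pre_ms, offset_ms - onset_ms


def summarize_unit(
    grid_responses: dict[tuple[float, float], SpikeTrainSet],
    unit_id: str | None = None,
    pre_ms: float = 50.0,
    window_ms: float = 100.0,
) -> TuningSummary:
    """Full per-unit tuning summary from a simulated or recorded tone grid.

    Latency and duration are measured on a 1-ms PSTH pooling the trials of
    all responsive grid cells (trial counts there are high enough for a
    stable spontaneous criterion).
    """
    first = next(iter(grid_responses.values()))
    unit_id = unit_id or first.unit_id
    fra = compute_fra(grid_responses, pre_ms=pre_ms, window_ms=window_ms)
    if not fra.responsive:
        return TuningSummary(unit_id=unit_id, responsive=False)
    bf, bf_thr = best_frequency(fra)
    cf, cf_thr = characteristic_frequency(fra)
    q10, censored = q10db(fra, cf, cf_thr)

    mask = fra.main_component_mask()
    trials: list[np.ndarray] = []
    for i, lv in enumerate(fra.levels_db):
        for j, f in enumerate(fra.freqs_khz):
            if mask[i, j]:
                trials.extend(grid_responses[(float(f), float(lv))].trials)
    onset = first.protocol.pre_stimulus_ms
    psth = build_psth(trials, 1.0, onset - pre_ms, first.protocol.trial_length_ms)
    try:
        latency, duration = latency_and_duration(psth, pre_ms=pre_ms)
    except NonResponsiveError:
        latency, duration = np.nan, np.nan
    return TuningSummary(
        unit_id=unit_id,
        responsive=True,
        bf_khz=bf,
        bf_threshold_db=bf_thr,
        cf_khz=cf,
        cf_threshold_db=cf_thr,
        q10=q10,
        q10_censored=censored,
        latency_ms=latency,
        response_duration_ms=duration,
    )
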