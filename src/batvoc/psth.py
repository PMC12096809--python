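"""Peri-stimulus time histograms and evoked-response windows.

Spike times are always in ms relative to trial start; stimulus onset sits
at the end of the pre-stimulus silent interval (50 ms by default), exactly
as trials are laid out by the simulator and the serialized CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InputError(ValueError):
    pass


class NonResponsiveError(RuntimeError):
    """Raised when a unit never exceeds its spontaneous-activity criterion."""


@dataclass(frozen=True)
class ResponseWindow:
    """Half-open analysis window [start_ms, end_ms) relative to trial start."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.end_ms > self.start_ms:
            raise InputError("window end must exceed start")

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class PSTH:
    """Binned spike counts, summed over trials unless ``n_trials == 1``.

    ``t0_ms`` is the left edge of the first bin relative to trial start,
    so bin ``i`` covers ``[t0 + i*bw, t0 + (i+1)*bw)``.
    """

    bin_width_ms: float
    t0_ms: float
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise InputError("negative bin counts")

    @property
    def bin_edges_ms(self) -> np.ndarray:
        return self.t0_ms + self.bin_width_ms * np.arange(len(self.counts) + 1)

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.t0_ms + self.bin_width_ms * (np.arange(len(self.counts)) + 0.5)


def build_psth(
    trials: list[np.ndarray] | list[list[float]],
    bin_width_ms: float,
    t_start_ms: float,
    t_end_ms: float,
) -> PSTH:
    """Histogram spike times from all trials into fixed-width bins."""
    if bin_width_ms <= 0:
        raise InputError("bin width must be positive")
    n_bins = int(round((t_end_ms - t_start_ms) / bin_width_ms))
    if n_bins <= 0:
        raise InputError("empty time range")
    edges = t_start_ms + bin_width_ms * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for tr in trials:
        tr = np.asarray(tr, dtype=float)
        counts += np.histogram(tr, bins=edges)[0]
    return PSTH(bin_width_ms=bin_width_ms, t0_ms=t_start_ms, counts=counts, n_trials=len(trials))


def single_trial_psths(
    trials: list[np.ndarray] | list[list[float]],
    bin_width_ms: float,
    t_start_ms: float,
    t_end_ms: float,
) -> np.ndarray:
    """Array of per-trial binned counts, shape (n_trials, n_bins)."""
    n_bins = int(round((t_end_ms - t_start_ms) / bin_width_ms))
    edges = t_start_ms + bin_width_ms * np.arange(n_bins + 1)
    out = np.zeros((len(trials), n_bins), dtype=np.float64)
    for i, tr in enumerate(trials):
        out[i] = np.histogram(np.asarray(tr, dtype=float), bins=edges)[0]
    return out


def spontaneous_criterion(
    psth: PSTH, pre_ms: float, n_sd: float = 2.0
) -> tuple[float, float, float]:
    """Mean, SD and (mean + n_sd*SD) threshold of the pre-stimulus bins.

    The pre-stimulus epoch is the first ``pre_ms`` of the trial; the PSTH
    must start at or before 0 and cover that epoch.
    """
    edges = psth.bin_edges_ms
    pre_mask = edges[1:] <= pre_ms + 1e-9
    pre = psth.counts[pre_mask]
    if len(pre) == 0:
        raise InputError("PSTH does not cover the pre-stimulus epoch")
    mu = float(np.mean(pre))
    sd = float(np.std(pre, ddof=0))
    return mu, sd, mu + n_sd * sd


def evoked_epoch(
    psth: PSTH,
    pre_ms: float = 50.0,
    n_sd: float = 2.0,
    min_consecutive: int = 2,
    max_gap_ms: float = 15.0,
) -> tuple[float, float]:
    """Detect the evoked epoch [onset_ms, offset_ms] after stimulus onset.

    Onset is the left edge of the first run of ``min_consecutive`` bins
    exceeding the mean + ``n_sd``·SD of the pre-stimulus bins.  The epoch
    extends over later suprathreshold runs (also of at least
    ``min_consecutive`` bins) as long as gaps between runs do not exceed
    ``max_gap_ms``; offset is the right edge of the last such run.

    Raises
    ------
    NonResponsiveError
        If no qualifying run exists after stimulus onset.
    """
    _, _, thr = spontaneous_criterion(psth, pre_ms, n_sd)
    edges = psth.bin_edges_ms
    post = edges[:-1] >= pre_ms - 1e-9
    above = (psth.counts > thr) & post

    bw = psth.bin_width_ms
    runs: list[tuple[int, int]] = []  # [start_bin, end_bin] inclusive
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if j - i + 1 >= min_consecutive:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        raise NonResponsiveError("activity never exceeds the spontaneous criterion")

    start, end = runs[0]
    for s, e in runs[1:]:
        if (s - end - 1) * bw <= max_gap_ms:
            end = e
        else:
            break
    return float(edges[start]), float(edges[end + 1])
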