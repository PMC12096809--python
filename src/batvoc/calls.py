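"""Synthesis of a 15-call *Phyllostomus discolor*-like stimulus library.

Three behavioural categories, five call variants each:

* **echolocation** — very short (<3 ms) multiharmonic downward FM sweeps,
  fundamental running from roughly 90 down to 40 kHz;
* **appeasement** — 25–46 ms harmonic stacks on a fundamental near 17 kHz
  with shallow frequency modulation;
* **aggression** — long (134–271 ms) trains of short broadband elements
  repeating every ~8 ms, element fundamental between 7.5 and 13 kHz.

All generators are pure functions of ``(seed, variant)``.  Waveforms are
peak-normalised; absolute presentation level is a property of the
simulated unit, not of the stimulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert

DEFAULT_SAMPLE_RATE = 192_000.0

CATEGORIES = ("echolocation", "appeasement", "aggression")

#: per-category duration limits in ms (printed call-library parameters)
DURATION_RANGES_MS = {
    "echolocation": (0.0, 3.0),
    "appeasement": (25.0, 46.0),
    "aggression": (134.0, 271.0),
}


class ParameterError(ValueError):
    """Invalid generator or analysis parameter."""


class InputError(ValueError):
    """Invalid input data (empty or degenerate waveform)."""


@dataclass(frozen=True)
class CallWaveform:
    """A single synthesized vocalization.

    Attributes
    ----------
    call_id : str
        Unique identifier, e.g. ``"echolocation_1"``.
    category : str
        One of :data:`CATEGORIES`.
    samples : np.ndarray
        Mono waveform, peak-normalised (max ``|sample|`` <= 1).
    sample_rate_hz : float
        Sampling rate; 192 kHz by default.
    """

    call_id: str
    category: str
    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sample_rate_hz * 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz * 1000.0


@dataclass(frozen=True)
class AcousticFeatures:
    """The four summary features used to compare call categories."""

    spectral_centroid_hz: float
    temporal_centroid_ms: float
    duration_ms: float
    harmonic_ratio: float


@dataclass
class CallLibrary:
    """Ordered collection of 15 calls, 3 categories x 5 variants."""

    calls: list[CallWaveform] = field(default_factory=list)

    def __iter__(self) -> Iterator[CallWaveform]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __getitem__(self, call_id: str) -> CallWaveform:
        for c in self.calls:
            if c.call_id == call_id:
                return c
        raise KeyError(call_id)

    @property
    def categories(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
        for c in self.calls:
            out[c.category].append(c.call_id)
        return out

    def validate(self) -> None:
        ids = [c.call_id for c in self.calls]
        if len(ids) != len(set(ids)):
            raise ParameterError("call_ids must be unique")
        cats = self.categories
        if sorted(cats) != sorted(CATEGORIES) or any(len(v) != 5 for v in cats.values()):
            raise ParameterError("library must hold 3 categories x 5 calls")


def _check_variant(variant: int) -> None:
    if not 1 <= int(variant) <= 5:
        raise ParameterError(f"variant must be in 1..5, got {variant}")


def _variant_rng(seed: int, category: str, variant: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, CATEGORIES.index(category), int(variant)])
    return np.random.default_rng(ss)


def _taper(n: int, fs: float, ramp_ms: float) -> np.ndarray:
    """Cosine on/off ramps to avoid spectral splatter at call edges."""
    ramp = min(int(round(ramp_ms * 1e-3 * fs)), n // 2)
    w = np.ones(n)
    if ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        w[:ramp] = r
        w[-ramp:] = r[::-1]
    return w


def _normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0:
        raise InputError("generated silent waveform")
    return x / peak


def _harmonic_sweep(
    f0_inst_hz: np.ndarray,
    fs: float,
    n_harmonics: int,
    harmonic_rolloff: float,
) -> np.ndarray:
    """Sum of harmonics of a time-varying fundamental, alias-gated.

    Harmonic ``h`` is silenced wherever ``h * f0(t)`` exceeds 95% of the
    Nyquist frequency, so fast high sweeps never alias.
    """
    dt = 1.0 / fs
    phase0 = 2.0 * np.pi * np.cumsum(f0_inst_hz) * dt
    nyq = 0.95 * fs / 2.0
    x = np.zeros_like(f0_inst_hz)
    for h in range(1, n_harmonics + 1):
        amp = harmonic_rolloff ** (h - 1)
        gate = (h * f0_inst_hz) < nyq
        x += amp * gate * np.sin(h * phase0)
    return x


def gen_echolocation_call(
    seed: int, variant: int, sample_rate_hz: float = DEFAULT_SAMPLE_RATE
) -> CallWaveform:
    """Short multiharmonic downward FM sweep (<3 ms), fundamental ~90→40 kHz."""
    _check_variant(variant)
    rng = _variant_rng(seed, "echolocation", variant)
    duration_ms = 1.6 + 0.24 * (variant - 1) + rng.uniform(-0.05, 0.05)  # 1.55..2.65 ms
    f_start = 90_000.0 * (1.0 + 0.04 * rng.uniform(-1, 1))
    f_end = 40_000.0 * (1.0 + 0.04 * rng.uniform(-1, 1)) + 1500.0 * (variant - 3)
    n = int(round(duration_ms * 1e-3 * sample_rate_hz))
    t = np.arange(n) / n
    # hyperbolic-flavoured sweep: spends relatively more time at low frequencies
    f_inst = f_start * (f_end / f_start) ** (t**0.8)
    x = _harmonic_sweep(f_inst, sample_rate_hz, n_harmonics=3, harmonic_rolloff=0.45)
    x *= _taper(n, sample_rate_hz, 0.2)
    return CallWaveform(
        call_id=f"echolocation_{variant}",
        category="echolocation",
        samples=_normalize(x),
        sample_rate_hz=sample_rate_hz,
    )


def gen_appeasement_call(
    seed: int, variant: int, sample_rate_hz: float = DEFAULT_SAMPLE_RATE
) -> CallWaveform:
    """25–46 ms strongly harmonic call, F0 ≈ 17 kHz, shallow FM."""
    _check_variant(variant)
    rng = _variant_rng(seed, "appeasement", variant)
    duration_ms = 27.0 + 4.2 * (variant - 1) + rng.uniform(-1.0, 1.0)  # ~26..44 ms
    f0 = 17_000.0 * (1.0 + 0.06 * (variant - 3) / 2.0 + 0.01 * rng.uniform(-1, 1))
    n = int(round(duration_ms * 1e-3 * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    # shallow FM: <2 slow cycles over the call, depth a few percent of F0
    fm_depth = 0.03 + 0.01 * (variant - 1) / 4.0
    fm_rate_hz = 40.0 + 8.0 * (variant - 1)
    fm_phase = rng.uniform(0, 2 * np.pi)
    f_inst = f0 * (1.0 + fm_depth * np.sin(2 * np.pi * fm_rate_hz * t + fm_phase))
    x = _harmonic_sweep(f_inst, sample_rate_hz, n_harmonics=5, harmonic_rolloff=0.55)
    # gentle amplitude arch typical of tonal communication calls
    x *= np.sin(np.pi * np.arange(n) / n) ** 0.35
    x *= _taper(n, sample_rate_hz, 2.0)
    return CallWaveform(
        call_id=f"appeasement_{variant}",
        category="appeasement",
        samples=_normalize(x),
        sample_rate_hz=sample_rate_hz,
    )


def gen_aggression_call(
    seed: int, variant: int, sample_rate_hz: float = DEFAULT_SAMPLE_RATE
) -> CallWaveform:
    """134–271 ms train of short broadband elements, ~8 ms apart, F0 7.5–13 kHz."""
    _check_variant(variant)
    rng = _variant_rng(seed, "aggression", variant)
    duration_ms = 140.0 + 30.0 * (variant - 1) + rng.uniform(-4.0, 4.0)  # ~136..264 ms
    inter_element_ms = 8.0
    element_ms = 3.5
    f0 = 7_500.0 + 1_300.0 * (variant - 1) + rng.uniform(-200, 200)  # 7.5..13 kHz
    n = int(round(duration_ms * 1e-3 * sample_rate_hz))
    x = np.zeros(n)
    n_el = int(duration_ms // inter_element_ms)
    el_n = int(round(element_ms * 1e-3 * sample_rate_hz))
    t_el = np.arange(el_n) / sample_rate_hz
    for k in range(n_el):
        start = int(round(k * inter_element_ms * 1e-3 * sample_rate_hz))
        if start + el_n > n:
            break
        # broadband element: dense harmonic stack plus a noise floor
        el = _harmonic_sweep(
            np.full(el_n, f0 * (1.0 + 0.02 * rng.uniform(-1, 1))),
            sample_rate_hz,
            n_harmonics=9,
            harmonic_rolloff=0.82,
        )
        el += 0.35 * rng.standard_normal(el_n)
        el *= np.sin(np.pi * t_el / (element_ms * 1e-3)) ** 0.8
        x[start : start + el_n] += el * (0.8 + 0.2 * rng.random())
    x *= _taper(n, sample_rate_hz, 1.0)
    return CallWaveform(
        call_id=f"aggression_{variant}",
        category="aggression",
        samples=_normalize(x),
        sample_rate_hz=sample_rate_hz,
    )


_GENERATORS = {
    "echolocation": gen_echolocation_call,
    "appeasement": gen_appeasement_call,
    "aggression": gen_aggression_call,
}


def make_call_library(seed: int = 0, sample_rate_hz: float = DEFAULT_SAMPLE_RATE) -> CallLibrary:
    """Build the full 15-call library (3 categories x 5 variants)."""
    lib = CallLibrary(
        [
            _GENERATORS[cat](seed, v, sample_rate_hz)
            for cat in CATEGORIES
            for v in range(1, 6)
        ]
    )
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# envelope and acoustic features
# ---------------------------------------------------------------------------


def envelope(w: CallWaveform, smoothing_ms: float = 0.5) -> np.ndarray:
    """Temporal envelope: |analytic signal| smoothed by a moving average.

    Parameters
    ----------
    smoothing_ms : float
        Length of the moving-average window; 0 disables smoothing.
    """
    if len(w.samples) == 0:
        raise InputError("empty waveform")
    if smoothing_ms < 0:
        raise ParameterError("smoothing_ms must be >= 0")
    env = np.abs(hilbert(w.samples))
    k = int(round(smoothing_ms * 1e-3 * w.sample_rate_hz))
    if k > 1:
        env = np.convolve(env, np.ones(k) / k, mode="same")
    return env


def estimate_f0(w: CallWaveform, fmin_hz: float = 4_000.0, fmax_hz: float = 30_000.0) -> float:
    """Fundamental-frequency estimate via the autocorrelation peak."""
    x = w.samples - np.mean(w.samples)
    if not np.any(x):
        raise InputError("all-zero waveform")
    ac = np.correlate(x, x, mode="full")[len(x) - 1 :]
    lag_min = max(1, int(w.sample_rate_hz / fmax_hz))
    lag_max = min(len(ac) - 1, int(w.sample_rate_hz / fmin_hz))
    if lag_max <= lag_min:
        raise InputError("waveform too short for F0 search range")
    lag = lag_min + int(np.argmax(ac[lag_min : lag_max + 1]))
    # parabolic refinement around the peak
    if 1 <= lag < len(ac) - 1:
        a, b, c = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = a - 2 * b + c
        if denom != 0:
            lag = lag + 0.5 * (a - c) / denom
    return float(w.sample_rate_hz / lag)


def acoustic_features(w: CallWaveform) -> AcousticFeatures:
    """Spectral centroid, temporal centroid, duration, harmonic ratio.

    The harmonic ratio is the fraction of spectral energy falling within
    ±3% bands around the estimated F0 and its first 10 integer multiples.
    """
    x = w.samples
    if len(x) == 0 or not np.any(x):
        raise InputError("all-zero or empty waveform")
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / w.sample_rate_hz)
    spectral_centroid = float(np.sum(freqs * spec) / np.sum(spec))

    env = envelope(w, smoothing_ms=0.5)
    e2 = env**2
    t_ms = w.times_ms
    temporal_centroid = float(np.sum(t_ms * e2) / np.sum(e2))

    f0 = estimate_f0(w)
    harm_mask = np.zeros(len(freqs), dtype=bool)
    for h in range(1, 11):
        fc = h * f0
        harm_mask |= np.abs(freqs - fc) <= 0.03 * fc
    harmonic_ratio = float(np.sum(spec[harm_mask]) / np.sum(spec))

    return AcousticFeatures(
        spectral_centroid_hz=spectral_centroid,
        temporal_centroid_ms=temporal_centroid,
        duration_ms=w.duration_ms,
        harmonic_ratio=harmonic_ratio,
    )


# ---------------------------------------------------------------------------
# WAV + manifest I/O
# ---------------------------------------------------------------------------


def write_wav(w: CallWaveform, path: str | Path) -> None:
    """Write a call as mono float32 WAV at its native sample rate."""
    wavfile.write(str(path), int(w.sample_rate_hz), w.samples.astype(np.float32))


def read_wav(path: str | Path, call_id: str, category: str) -> CallWaveform:
    """Read a mono WAV back into a :class:`CallWaveform`."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim != 1:
        raise InputError("expected mono WAV")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    return CallWaveform(call_id=call_id, category=category, samples=data, sample_rate_hz=float(rate))


def export_library(lib: CallLibrary, out_dir: str | Path) -> Path:
    """Write all WAVs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Mapping[str, object]] = {}
    for call in lib:
        wav_path = out / f"{call.call_id}.wav"
        write_wav(call, wav_path)
        manifest[call.call_id] = {
            "category": call.category,
            "wav": wav_path.name,
            "duration_ms": call.duration_ms,
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def import_library(manifest_path: str | Path) -> CallLibrary:
    """Rebuild a :class:`CallLibrary` from a manifest written by :func:`export_library`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    calls = [
        read_wav(manifest_path.parent / str(meta["wav"]), call_id, str(meta["category"]))
        for call_id, meta in manifest.items()
    ]
    return CallLibrary(calls)
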