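"""Formant measurement by linear predictive coding, and vowel synthesis.

LPC fits an all-pole (autoregressive) model to each analysis frame; the
complex roots of the prediction polynomial give candidate resonances.  A
root at angle theta and radius r on fs-sampled data corresponds to a
resonance at

    f = theta * fs / (2 pi)        (Hz)
    B = -(fs / pi) * ln r          (bandwidth, Hz)

Candidates are filtered by a minimum frequency and maximum bandwidth and
aggregated across frames (median) to yield average formant frequencies
for a whole vowel-like region — the long-window, region-average style of
measurement appropriate when vocal tract length rather than rapid formant
transitions is the target.  `synthesize_vowel` runs the inverse mapping
(poles -> resonators) so measurement can be verified by round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz

from .tube import TubeConfig, estimate_vtl

__all__ = [
    "AudioSegment",
    "LPCSettings",
    "FormantCandidate",
    "default_lpc_order",
    "lpc_coefficients",
    "formants_from_lpc",
    "measure_formants",
    "synthesize_vowel",
    "auto_f0",
]


class DegenerateInputError(ValueError):
    """Raised when a frame carries no signal (all zeros)."""


@dataclass
class AudioSegment:
    """Mono audio: samples (float, arbitrary units) at sample_rate Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("samples must be a non-empty 1-d array")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @classmethod
    def read_wav(cls, path) -> "AudioSegment":
        """Read a WAV file (PCM int or float); multichannel is downmixed."""
        fs, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim == 2:
            warnings.warn(f"{path}: multichannel audio downmixed by averaging")
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        return cls(data.astype(float), int(fs))

    def write_wav(self, path, dtype: str = "float32") -> None:
        if dtype == "float32":
            wavfile.write(path, self.sample_rate, self.samples.astype(np.float32))
        elif dtype == "int16":
            peak = np.max(np.abs(self.samples)) or 1.0
            scaled = np.clip(self.samples / peak, -1, 1) * 32767
            wavfile.write(path, self.sample_rate, scaled.astype(np.int16))
        else:
            raise ValueError("dtype must be 'float32' or 'int16'")


@dataclass
class LPCSettings:
    """Analysis settings.

    window_ms / step_ms
        Frame length and hop.  50 ms is deliberately long: it averages
        over several glottal cycles and keeps the fit from locking onto
        individual harmonics, which matters when the target is the
        long-term average formant pattern rather than fast transitions.
    preemphasis
        First-order high-pass coefficient applied once per frame.
    n_coeff
        LPC order; None = two coefficients per kHz below Nyquist plus
        three (see :func:`default_lpc_order`).
    min_formant_hz / max_bandwidth_hz
        Candidate filters; raise/lower for animals much larger or smaller
        than humans.
    """

    window_ms: float = 50.0
    step_ms: float = 25.0
    preemphasis: float = 0.97
    n_coeff: int | None = None
    min_formant_hz: float = 200.0
    max_bandwidth_hz: float = 600.0

    def __post_init__(self):
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window_ms and step_ms must be positive")
        if not (0 <= self.preemphasis < 1):
            raise ValueError("preemphasis must be in [0, 1)")
        if self.n_coeff is not None and self.n_coeff < 2:
            raise ValueError("n_coeff must be >= 2")


@dataclass(frozen=True)
class FormantCandidate:
    frequency_hz: float
    bandwidth_hz: float


def default_lpc_order(sample_rate: float) -> int:
    """Two coefficients per kHz below the Nyquist frequency, plus three."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return int(np.floor(2.0 * (sample_rate / 2.0) / 1000.0)) + 3


def lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """Autoregressive coefficients a_k of an all-pole fit to one frame.

    Autocorrelation method (Toeplitz normal equations, i.e. the
    Levinson-Durbin solution): x[n] ~ sum_k a_k x[n-k].  The caller is
    expected to window and preemphasize the frame.
    """
    x = np.asarray(frame, dtype=float)
    if x.ndim != 1 or len(x) <= order:
        raise ValueError("frame must be 1-d and longer than the LPC order")
    if not np.any(x):
        raise DegenerateInputError("all-zero frame")
    full = np.correlate(x, x, mode="full")
    r = full[len(x) - 1 : len(x) + order]
    if r[0] <= 0:
        raise DegenerateInputError("zero-energy frame")
    a = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    return np.asarray(a, dtype=float)


def prediction_error_energy(frame: np.ndarray, a: np.ndarray) -> float:
    """Residual energy of the AR fit (non-negative up to rounding)."""
    x = np.asarray(frame, dtype=float)
    err = signal.lfilter(np.concatenate(([1.0], -a)), [1.0], x)
    return float(np.sum(err**2))


def formants_from_lpc(
    coeffs: np.ndarray,
    sample_rate: float,
    settings: LPCSettings | None = None,
) -> list[FormantCandidate]:
    """Formant candidates from the roots of the prediction polynomial.

    Only roots in the upper half plane are kept; candidates outside
    (min_formant_hz, Nyquist) or broader than max_bandwidth_hz are
    dropped.  Sorted ascending in frequency; may be empty.
    """
    settings = settings or LPCSettings()
    a = np.asarray(coeffs, dtype=float)
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 1e-9]
    nyquist = sample_rate / 2.0
    out = []
    for r in roots:
        mag = np.abs(r)
        if mag >= 1.0 or mag <= 0.0:
            continue  # unstable or origin pole: no resonance
        f = float(np.angle(r) * sample_rate / (2.0 * np.pi))
        bw = float(-(sample_rate / np.pi) * np.log(mag))
        if f <= settings.min_formant_hz or f >= nyquist:
            continue
        if bw >= settings.max_bandwidth_hz or bw <= 0:
            continue
        out.append(FormantCandidate(f, bw))
    out.sort(key=lambda c: c.frequency_hz)
    return out


def measure_formants(
    segment: AudioSegment,
    settings: LPCSettings | None = None,
    n_formants: int = 4,
) -> list[float]:
    """Average formant frequencies F1..Fn over a vowel-like region.

    Each frame is preemphasized, Gaussian-windowed and LPC-analyzed;
    candidates are assigned to formant slots in ascending order and each
    slot is summarized by the median across frames.  A slot supported by
    fewer than half of the analyzed frames is returned as NaN (missing),
    as is everything when the region is silent.
    """
    settings = settings or LPCSettings()
    fs = segment.sample_rate
    x = segment.samples
    n_win = int(round(settings.window_ms / 1000.0 * fs))
    n_step = max(1, int(round(settings.step_ms / 1000.0 * fs)))
    if len(x) < n_win:
        raise ValueError(
            f"segment ({len(x)} samples) shorter than one window ({n_win})"
        )
    order = settings.n_coeff or default_lpc_order(fs)
    window = signal.windows.gaussian(n_win, std=n_win / 6.0)
    slots: list[list[float]] = [[] for _ in range(n_formants)]
    n_frames = 0
    for start in range(0, len(x) - n_win + 1, n_step):
        fr = x[start : start + n_win].copy()
        fr[1:] -= settings.preemphasis * fr[:-1]
        fr *= window
        if not np.any(np.abs(fr) > 1e-12):
            continue  # silent frame
        try:
            a = lpc_coefficients(fr, order)
        except DegenerateInputError:
            continue
        cands = formants_from_lpc(a, fs, settings)
        n_frames += 1
        for i, c in enumerate(cands[:n_formants]):
            slots[i].append(c.frequency_hz)
    if n_frames == 0:
        return [float("nan")] * n_formants
    return [
        float(np.median(s)) if len(s) >= 0.5 * n_frames else float("nan")
        for s in slots
    ]


def auto_f0(formants, tube: TubeConfig | None = None, ratio: float = 0.1) -> float:
    """Fundamental proportional to the formant spacing implied by the
    supplied formants (i.e. inversely proportional to apparent VTL), used
    when synthesizing auditory-feedback vowels: a gross formant error then
    becomes audible as an implausible pitch."""
    est = estimate_vtl(list(formants), tube or TubeConfig())
    return ratio * est.dF_hz


def synthesize_vowel(
    formants,
    bandwidths=None,
    duration_s: float = 0.5,
    f0: float | None = None,
    sample_rate: int = 16000,
    use_auto_f0: bool = False,
    seed: int | None = None,
    source_tilt: float = 0.97,
) -> AudioSegment:
    """Synthesize a vowel with the given formant frequencies.

    The source (an impulse train at ``f0``, or white noise when ``f0`` is
    None and ``use_auto_f0`` is False) is given a glottal-like falling
    spectrum by a first-order integrator with coefficient ``source_tilt``
    and passed through a cascade of two-pole resonators with the same
    pole mapping used for analysis.  With ``source_tilt`` equal to the
    analysis preemphasis (both default 0.97) the tilt and the
    preemphasis cancel exactly, so measurement and synthesis are exact
    inverses of each other.  Output is peak-normalized to 0.9.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    f = np.asarray(list(formants), dtype=float)
    nyquist = sample_rate / 2.0
    if len(f):
        if np.any(np.diff(f) <= 0):
            raise ValueError("formants must be strictly ascending")
        if np.any(f >= nyquist) or np.any(f <= 0):
            raise ValueError("formants must lie in (0, Nyquist)")
    if bandwidths is None:
        bw = 80.0 + 40.0 * np.arange(len(f))
    else:
        bw = np.asarray(list(bandwidths), dtype=float)
        if len(bw) != len(f):
            raise ValueError("need one bandwidth per formant")
    n = int(round(duration_s * sample_rate))
    if f0 is None and use_auto_f0:
        if not len(f):
            raise ValueError("auto f0 needs at least one formant")
        f0 = auto_f0(f)
    if f0 is not None:
        src = np.zeros(n)
        period = max(1, int(round(sample_rate / f0)))
        src[::period] = 1.0
    else:
        rng = np.random.default_rng(seed)
        src = rng.standard_normal(n)
    if source_tilt > 0:
        src = signal.lfilter([1.0], [1.0, -source_tilt], src)
    y = src
    for fi, bwi in zip(f, bw):
        r = np.exp(-np.pi * bwi / sample_rate)
        theta = 2.0 * np.pi * fi / sample_rate
        y = signal.lfilter([1.0], [1.0, -2.0 * r * np.cos(theta), r * r], y)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.9 * y / peak
    return AudioSegment(y, sample_rate)
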