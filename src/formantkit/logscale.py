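"""Logarithmic-scale formant representations and log-mean normalization.

On a log2 (musical) scale a vowel's formants form a chord whose shape
encodes vowel quality and whose transposition along the frequency axis
encodes vocal tract length.  Subtracting the mean log-formant (log-mean /
Nearey / sliding-template normalization) removes the transposition; this
is equivalent to dividing each formant in Hz by the geometric mean of all
measured formants.  All logs here are base 2, so 1 unit = 1 octave and
1/12 unit = 1 semitone.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np

from .table import FormantTable

__all__ = [
    "NormalizedToken",
    "interval",
    "log_ratios",
    "nearey_normalize",
    "mean_log2_per_token",
    "scale_correct",
]


def interval(f_low: float, f_high: float, unit: str = "octaves") -> float:
    """Musical interval log2(f_high / f_low), in octaves or semitones.

    The sign follows the argument order: interval(1500, 500) < 0.
    """
    if f_low <= 0 or f_high <= 0:
        raise ValueError("frequencies must be positive")
    oct_ = float(np.log2(f_high / f_low))
    if unit == "octaves":
        return oct_
    if unit == "semitones":
        return 12.0 * oct_
    raise ValueError(f"unit must be 'octaves' or 'semitones', got {unit!r}")


def log_ratios(formants: Sequence[float | None]) -> np.ndarray:
    """log2 ratios of adjacent formants: (F2/F1, F3/F2, ...), length n-1.

    A pair involving a missing value yields NaN for that ratio.
    """
    f = np.asarray(
        [np.nan if v is None else float(v) for v in formants], dtype=float
    )
    if np.sum(~np.isnan(f)) < 2:
        raise ValueError("need at least two present formants")
    if np.any(f[~np.isnan(f)] <= 0):
        raise ValueError("frequencies must be positive")
    with np.errstate(invalid="ignore"):
        return np.diff(np.log2(f))


@dataclass
class NormalizedToken:
    """Log-mean normalized representation of one token.

    mean_log2 is the token's scale measure (log2 of the geometric mean of
    its formants); log2_deviations sum to zero and are scale-invariant.
    """

    mean_log2: float
    log2_deviations: np.ndarray
    log_ratios: np.ndarray
    complete: bool


def nearey_normalize(formants: Sequence[float]) -> NormalizedToken:
    """Log-mean (Nearey) normalization of one complete token.

    Requires a complete set of formants: scale measures computed over
    different formant subsets are not commensurate across tokens, so a
    missing value is an error rather than silently renormalizing.
    """
    f = np.asarray(
        [np.nan if v is None else float(v) for v in formants], dtype=float
    )
    if len(f) == 0:
        raise ValueError("empty formant list")
    if np.any(np.isnan(f)):
        raise ValueError(
            "log-mean normalization requires the same, complete set of "
            "formants in every token (no missing values)"
        )
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    logf = np.log2(f)
    mean = float(logf.mean())
    return NormalizedToken(
        mean_log2=mean,
        log2_deviations=logf - mean,
        log_ratios=np.diff(logf),
        complete=True,
    )


def mean_log2_per_token(table: FormantTable, indices: Sequence[int] | None = None) -> dict:
    """Per-token mean log2 frequency over the given formant indices.

    Tokens missing any of the requested formants raise, mirroring
    :func:`nearey_normalize`.
    """
    wide = table.to_wide()
    if indices is None:
        indices = sorted(
            int(c[1:]) for c in wide.columns if c.startswith("f") and c[1:].isdigit()
        )
    cols = [f"f{i}" for i in indices]
    missing_cols = [c for c in cols if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"table has no formants {missing_cols}")
    block = wide[cols].astype(float)
    if block.isna().any().any():
        bad = block.index[block.isna().any(axis=1)].tolist()
        raise ValueError(f"tokens with missing formants in {cols}: {bad}")
    return dict(np.log2(block).mean(axis=1))


def scale_correct(table: FormantTable, scale_per_token: Mapping) -> FormantTable:
    """Remove between-token scale differences, keeping frequencies in Hz.

    Each token's frequencies are divided by 2**(s_t - mean(s)), where s_t
    is that token's scale measure in log2 units (e.g. its mean
    log-formant, or a speaker scale factor broadcast to tokens).  After
    correction every token's scale measure equals the grand mean; ratios
    within a token are untouched.
    """
    tokens = table.tokens
    missing = [t for t in tokens if t not in scale_per_token]
    if missing:
        raise ValueError(f"no scale given for tokens: {missing}")
    scales = np.asarray([float(scale_per_token[t]) for t in tokens])
    ref = scales.mean()
    corr = {t: 2.0 ** (s - ref) for t, s in zip(tokens, scales)}
    factors = table.data["token"].map(corr).to_numpy(dtype=float)
    return table.with_frequencies(table.data["frequency_hz"].to_numpy() / factors)
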