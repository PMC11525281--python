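"""Apparent vocal tract length from formant spacing under a uniform tube.

A vocal tract closed at the glottis and open at the lips behaves as a
quarter-wave resonator: resonances sit at odd multiples of half the
formant spacing dF (F1 = 0.5 dF, F2 = 1.5 dF, ...).  A closed-closed (or
open-open) tract is a half-wave resonator with F_n = n dF.  Either way the
spacing is inversely proportional to tube length,

    VTL = c / (2 dF),

with c the speed of sound in the vocal tract.  dF is estimated by linear
regression of measured formant frequencies on their tube positions,
usually with the intercept forced through the origin so that the highly
variable lower formants carry little weight.  The dF-normalized residuals
— how far each formant sits from the equal spacing of a neutral schwa-like
tract of the same length — are a scale-invariant measure of vowel quality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from .table import FormantTable, FormantValidationError

__all__ = [
    "TubeConfig",
    "RegressionPoint",
    "VTLEstimate",
    "SchwaResult",
    "VTLRegression",
    "tube_positions",
    "fit_dF",
    "estimate_vtl",
    "schwa",
    "vtl_per_token",
    "vtl_per_speaker",
]

#: speed of sound in warm humid air inside the vocal tract, cm/s
SPEED_OF_SOUND_CM_S = 35_400.0

_TUBE_ALIASES = {
    "closed_open": "closed_open",
    "closed-open": "closed_open",
    "closed_closed": "closed_closed",
    "closed-closed": "closed_closed",
}


@dataclass(frozen=True)
class TubeConfig:
    """Single-tube resonator configuration.

    tube_type
        ``closed_open`` (quarter-wave, the default: open-mouth
        vocalization) or ``closed_closed`` (half-wave: closed-mouth *mmm*).
    speed_of_sound
        cm/s; default 35,400.
    intercept_zero
        Force the dF regression through the origin (default True).
    """

    tube_type: str = "closed_open"
    speed_of_sound: float = SPEED_OF_SOUND_CM_S
    intercept_zero: bool = True

    def __post_init__(self):
        t = _TUBE_ALIASES.get(self.tube_type)
        if t is None:
            raise ValueError(
                f"tube_type must be closed_open or closed_closed, got {self.tube_type!r}"
            )
        object.__setattr__(self, "tube_type", t)
        if self.speed_of_sound <= 0:
            raise ValueError("speed_of_sound must be positive")


@dataclass(frozen=True)
class RegressionPoint:
    """One (tube position, frequency) pair entering the dF regression."""

    position: float
    frequency_hz: float


def tube_positions(indices: Sequence[int], tube: TubeConfig | None = None) -> np.ndarray:
    """Tube position x_n for each formant index n (F_n = x_n * dF).

    Quarter-wave (closed-open): x_n = n - 0.5.  Half-wave (closed-closed):
    x_n = n.
    """
    tube = tube or TubeConfig()
    idx = np.asarray(indices, dtype=float)
    if np.any(idx < 1):
        raise ValueError("formant indices must be >= 1")
    if tube.tube_type == "closed_open":
        return idx - 0.5
    return idx


def fit_dF(
    positions: Sequence[float],
    frequencies: Sequence[float],
    intercept_zero: bool = True,
) -> tuple[float, float, float]:
    """Least-squares estimate of formant spacing dF.

    Returns ``(dF_hz, dF_se_hz, intercept_hz)``.

    Zero intercept: dF = sum(x F) / sum(x^2), with
    SE = sqrt(SSR / (n - 1) / sum(x^2)) — one fitted parameter, so n - 1
    residual degrees of freedom.  A single point gives dF = F/x with SE
    reported as 0.  Free intercept: ordinary least squares; SE is the
    standard error of the slope.
    """
    x = np.asarray(positions, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    if x.shape != f.shape or x.ndim != 1:
        raise ValueError("positions and frequencies must be 1-d and equally long")
    n = len(x)
    if intercept_zero:
        if n < 1:
            raise ValueError("zero-intercept fit needs at least one point")
        if np.any(x <= 0):
            raise ValueError("tube positions must be positive for zero-intercept fits")
        sxx = float(np.sum(x * x))
        dF = float(np.sum(x * f) / sxx)
        if n == 1:
            return dF, 0.0, 0.0
        ssr = float(np.sum((f - dF * x) ** 2))
        se = float(np.sqrt(ssr / (n - 1) / sxx))
        return dF, se, 0.0
    if n < 2:
        raise ValueError("free-intercept fit needs at least two points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("singular design: all positions identical")
    slope = float(np.sum((x - x.mean()) * (f - f.mean())) / sxx)
    intercept = float(f.mean() - slope * x.mean())
    if n == 2:
        return slope, 0.0, intercept
    ssr = float(np.sum((f - intercept - slope * x) ** 2))
    se = float(np.sqrt(ssr / (n - 2) / sxx))
    return slope, se, intercept


@dataclass
class VTLEstimate:
    """Results of a tube-model dF regression.

    ``residuals_dF`` are per-point deviations from the regression line in
    dF units; ``ci95_cm`` is the 95% interval on VTL obtained by mapping
    dF +/- 1.96 SE through VTL = c / (2 dF) (bounds swap so low < high).
    """

    dF_hz: float
    dF_se_hz: float
    intercept_hz: float
    vtl_cm: float
    ci95_cm: tuple[float, float]
    n_points: int
    residuals_dF: np.ndarray
    tube: TubeConfig = field(default_factory=TubeConfig)
    positions: np.ndarray | None = None
    frequencies: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "Apparent vocal tract length (uniform-tube regression)",
            "=" * 54,
            f"tube model      : {self.tube.tube_type}"
            + ("" if self.tube.intercept_zero else " (free intercept; tube ignored)"),
            f"n points        : {self.n_points}",
            f"dF (Hz)         : {self.dF_hz:.2f}  (SE {self.dF_se_hz:.2f})",
        ]
        if not self.tube.intercept_zero:
            lines.append(f"intercept (Hz)  : {self.intercept_hz:.2f}")
        lines += [
            f"VTL (cm)        : {self.vtl_cm:.2f}",
            f"95% CI (cm)     : [{self.ci95_cm[0]:.2f}, {self.ci95_cm[1]:.2f}]",
        ]
        return "\n".join(lines)


@dataclass
class SchwaResult:
    """VTL-normalized formant pattern of one token.

    ``ff_relative_dF[i]`` is (F_i - x_i dF) / dF for formant index i+1:
    how many dF units formant i sits above the schwa position of a
    uniform tube with the same apparent length.  Scale-invariant.
    """

    dF_hz: float
    vtl_apparent_cm: float
    schwa_formants_hz: np.ndarray
    ff_relative_dF: np.ndarray
    ff_relative_semitones: np.ndarray
    tube: TubeConfig = field(default_factory=TubeConfig)


class VTLRegression:
    """Model object for the tube regression: build from data, then fit().

    ``data`` is either a sequence of optional frequencies (F1..Fn of one
    token, None/NaN = missing; interior gaps must be explicit) or a
    :class:`FormantTable`, whose present (index, frequency) pairs across
    all tokens are pooled into one regression.
    """

    def __init__(
        self,
        data: Sequence[float | None] | FormantTable,
        tube: TubeConfig | None = None,
        offset: int = 0,
    ):
        self.tube = tube or TubeConfig()
        if isinstance(data, FormantTable):
            sub = data.data[data.data["frequency_hz"].notna()]
            idx = sub["formant_index"].to_numpy()
            freq = sub["frequency_hz"].to_numpy(dtype=float)
        else:
            seq = [np.nan if v is None else float(v) for v in data]
            freq = np.asarray(seq, dtype=float)
            idx = np.arange(1 + offset, len(freq) + 1 + offset)
            present = ~np.isnan(freq)
            pf = freq[present]
            if len(pf) > 1 and not np.all(np.diff(pf) > 0):
                raise FormantValidationError(
                    "present formants must increase strictly with index"
                )
            idx, freq = idx[present], freq[present]
        if len(freq) == 0:
            raise ValueError("no present formants to fit")
        self.positions = tube_positions(idx, self.tube)
        self.frequencies = freq
        self.formant_indices = np.asarray(idx, dtype=int)

    @property
    def points(self) -> list[RegressionPoint]:
        return [
            RegressionPoint(float(x), float(f))
            for x, f in zip(self.positions, self.frequencies)
        ]

    def fit(self) -> VTLEstimate:
        tube = self.tube
        if tube.intercept_zero:
            dF, se, intercept = fit_dF(self.positions, self.frequencies, True)
        else:
            # the slope is invariant to a constant shift of positions, so
            # the tube type genuinely does not matter here
            dF, se, intercept = fit_dF(self.positions, self.frequencies, False)
        if dF <= 0:
            raise ValueError(f"fitted dF is non-positive ({dF:.1f} Hz)")
        c = tube.speed_of_sound
        vtl = c / (2.0 * dF)
        lo_dF, hi_dF = dF - 1.96 * se, dF + 1.96 * se
        hi_vtl = c / (2.0 * lo_dF) if lo_dF > 0 else np.inf
        lo_vtl = c / (2.0 * hi_dF)
        resid = (self.frequencies - intercept - dF * self.positions) / dF
        return VTLEstimate(
            dF_hz=dF,
            dF_se_hz=se,
            intercept_hz=intercept,
            vtl_cm=vtl,
            ci95_cm=(lo_vtl, hi_vtl),
            n_points=len(self.frequencies),
            residuals_dF=resid,
            tube=tube,
            positions=self.positions,
            frequencies=self.frequencies,
        )


def estimate_vtl(
    formants: Sequence[float | None] | FormantTable,
    tube: TubeConfig | None = None,
    intercept_zero: bool | None = None,
    offset: int = 0,
) -> VTLEstimate:
    """Apparent VTL from one token's formants or a pooled table.

    ``intercept_zero`` overrides the tube config when given.
    """
    tube = tube or TubeConfig()
    if intercept_zero is not None and intercept_zero != tube.intercept_zero:
        tube = TubeConfig(tube.tube_type, tube.speed_of_sound, intercept_zero)
    return VTLRegression(formants, tube, offset=offset).fit()


def schwa(
    formants: Sequence[float | None],
    tube: TubeConfig | None = None,
    offset: int = 0,
) -> SchwaResult:
    """Scale-invariant deviations of each formant from its schwa position."""
    tube = tube or TubeConfig()
    if not tube.intercept_zero:
        tube = TubeConfig(tube.tube_type, tube.speed_of_sound, True)
    model = VTLRegression(formants, tube, offset=offset)
    est = model.fit()
    n = len(formants)
    idx = np.arange(1 + offset, n + 1 + offset)
    pos = tube_positions(idx, tube)
    pred = pos * est.dF_hz
    freq = np.asarray(
        [np.nan if v is None else float(v) for v in formants], dtype=float
    )
    rel_dF = (freq - pred) / est.dF_hz
    with np.errstate(invalid="ignore", divide="ignore"):
        rel_st = 12.0 * np.log2(freq / pred)
    return SchwaResult(
        dF_hz=est.dF_hz,
        vtl_apparent_cm=est.vtl_cm,
        schwa_formants_hz=pred,
        ff_relative_dF=rel_dF,
        ff_relative_semitones=rel_st,
        tube=tube,
    )


def _estimate_or_none(sub: FormantTable, tube: TubeConfig, what: str):
    try:
        return estimate_vtl(sub, tube)
    except (ValueError, FormantValidationError) as exc:
        warnings.warn(f"could not estimate VTL for {what}: {exc}", stacklevel=3)
        return None


def vtl_per_token(table: FormantTable, tube: TubeConfig | None = None) -> dict:
    """One VTLEstimate per token (None, with a warning, where it fails)."""
    tube = tube or TubeConfig()
    return {
        tok: _estimate_or_none(table.subset(table.data["token"] == tok), tube, f"token {tok!r}")
        for tok in table.tokens
    }


def vtl_per_speaker(table: FormantTable, tube: TubeConfig | None = None) -> dict:
    """One VTLEstimate per speaker, pooling all of the speaker's tokens."""
    tube = tube or TubeConfig()
    out = {}
    for sp in table.speakers:
        out[sp] = _estimate_or_none(table.for_speaker(sp), tube, f"speaker {sp!r}")
    return out
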