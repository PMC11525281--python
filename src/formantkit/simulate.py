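"""Synthetic formant tables with the structure the estimators assume.

Each speaker is a uniform tube of length VTL drawn from a configured
range; its formant spacing is dF = c / (2 VTL).  Vowels are deviation
templates in dF units added to the tube positions (a schwa template is
all zeros), optionally with a per-vowel log2 scale shift (articulatory
lengthening/shortening).  Measurement noise is log-normal — multiplicative
on Hz, Gaussian on the log2 scale on which the downstream models operate —
with a per-formant SD that by default decreases with formant index,
because the lower formants are much more variable than the upper ones.
Entries can be masked missing independently per formant.

Truth tables (speaker VTL, dF and centered scale factor k; per-vowel
shifts) are returned alongside the data so parameter-recovery tests need
no re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .table import FormantTable
from .tube import TubeConfig, tube_positions

__all__ = ["SyntheticConfig", "default_vowel_templates", "generate_population"]


def default_vowel_templates() -> dict[str, tuple]:
    """Eight fixture vowel templates: per-formant deviations in dF units.

    "schwa" is exact equal spacing; the others are plausible open /
    close-front / close-back / mid / rhotic-like shapes.  All remain
    strictly ascending at any tract length (deviations are in dF units,
    so validity is scale-free).  These are fixture constants for testing,
    not estimates from any speech corpus.
    """
    return {
        "schwa": (0.0, 0.0, 0.0, 0.0),
        "a": (0.25, -0.30, 0.00, -0.05),
        "i": (-0.16, 0.48, -0.10, -0.11),
        "u": (-0.20, -0.45, -0.10, -0.05),
        "e": (-0.08, 0.25, 0.00, -0.03),
        "o": (0.05, -0.35, -0.05, -0.02),
        "ae": (0.30, 0.05, 0.00, 0.00),
        "er": (-0.05, -0.10, -0.35, 0.00),
    }


@dataclass
class SyntheticConfig:
    """Generative parameters.

    vtl_range_cm
        Speaker VTL is uniform on this range.  The default (13.4, 17.0)
        spans typical adult human tracts and gives SD(log2 VTL) ~ 0.10,
        i.e. a between-speaker scale factor spread tau of about 0.10.
    noise_sd_log2
        Per-formant measurement noise SD on the log2 scale; defaults
        (0.06, 0.04, 0.03, 0.02) shrink with formant index.
    missing_rate
        Independent per-formant missingness probabilities.
    """

    n_speakers: int = 30
    vtl_range_cm: tuple[float, float] = (13.4, 17.0)
    tube: TubeConfig = field(default_factory=TubeConfig)
    vowel_templates: dict | None = None
    vowel_scale_shift: dict | None = None
    noise_sd_log2: tuple = (0.06, 0.04, 0.03, 0.02)
    missing_rate: tuple = (0.0, 0.0, 0.0, 0.0)
    n_formants: int = 4
    seed: int = 0
    group: str | None = None
    speaker_prefix: str = "spk"

    def __post_init__(self):
        lo, hi = self.vtl_range_cm
        if not (0 < lo < hi):
            raise ValueError("vtl_range_cm must satisfy 0 < low < high")
        if self.vowel_templates is None:
            self.vowel_templates = default_vowel_templates()
        self.vowel_templates = {
            v: tuple(t)[: self.n_formants] for v, t in self.vowel_templates.items()
        }
        if self.vowel_scale_shift is None:
            self.vowel_scale_shift = {}
        self.noise_sd_log2 = tuple(self.noise_sd_log2)[: self.n_formants]
        self.missing_rate = tuple(self.missing_rate)[: self.n_formants]
        if len(self.noise_sd_log2) < self.n_formants:
            self.noise_sd_log2 += (self.noise_sd_log2 or (0.03,))[-1:] * (
                self.n_formants - len(self.noise_sd_log2)
            )
        if len(self.missing_rate) < self.n_formants:
            self.missing_rate += (0.0,) * (self.n_formants - len(self.missing_rate))
        if any(not (0 <= p <= 1) for p in self.missing_rate):
            raise ValueError("missing_rate entries must be probabilities")
        if any(s < 0 for s in self.noise_sd_log2):
            raise ValueError("noise_sd_log2 entries must be non-negative")
        pos = tube_positions(np.arange(1, self.n_formants + 1), self.tube)
        for v, dev in self.vowel_templates.items():
            if len(dev) != self.n_formants:
                raise ValueError(f"template {v!r} must have {self.n_formants} deviations")
            eff = pos + np.asarray(dev, dtype=float)
            if np.any(eff <= 0) or np.any(np.diff(eff) <= 0):
                raise ValueError(
                    f"template {v!r} produces non-ascending or non-positive formants"
                )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        tube_raw = raw.pop("tube", None)
        if tube_raw is not None:
            raw["tube"] = TubeConfig(**tube_raw)
        for key in ("vtl_range_cm", "noise_sd_log2", "missing_rate"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "vowel_templates" in raw and raw["vowel_templates"] is not None:
            raw["vowel_templates"] = {
                v: tuple(t) for v, t in raw["vowel_templates"].items()
            }
        raw.update(overrides)
        return cls(**raw)


def generate_population(config: SyntheticConfig):
    """Generate a formant table plus truth tables.

    Returns ``(table, truth)`` where ``truth`` has keys ``"speakers"``
    (DataFrame: speaker, vtl_cm, dF_hz, k) and ``"vowels"`` (DataFrame:
    vowel, scale_shift_log2, per-formant template deviations).  The true
    scale factor k is the centered log2 formant spacing, matching the
    convention of the scale-factor model.  Reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    c = config.tube.speed_of_sound
    lo, hi = config.vtl_range_cm
    vtl = rng.uniform(lo, hi, size=config.n_speakers)
    dF = c / (2.0 * vtl)
    k_true = np.log2(dF) - np.log2(dF).mean()
    width = len(str(config.n_speakers))
    speakers = [f"{config.speaker_prefix}{i + 1:0{width}d}" for i in range(config.n_speakers)]

    pos = tube_positions(np.arange(1, config.n_formants + 1), config.tube)
    recs = []
    for s_id, dF_s in zip(speakers, dF):
        for vowel, dev in config.vowel_templates.items():
            shift = float(config.vowel_scale_shift.get(vowel, 0.0))
            eps = rng.normal(0.0, config.noise_sd_log2)
            freqs = dF_s * (pos + np.asarray(dev)) * 2.0 ** (shift + eps)
            miss = rng.random(config.n_formants) < np.asarray(config.missing_rate)
            for i in range(config.n_formants):
                recs.append(
                    {
                        "token": f"{s_id}_{vowel}",
                        "speaker": s_id,
                        "group": config.group,
                        "vowel": vowel,
                        "formant_index": i + 1,
                        "frequency_hz": np.nan if miss[i] else freqs[i],
                    }
                )
    table = FormantTable(pd.DataFrame(recs))
    truth_speakers = pd.DataFrame(
        {"speaker": speakers, "vtl_cm": vtl, "dF_hz": dF, "k": k_true}
    )
    truth_vowels = pd.DataFrame(
        [
            {
                "vowel": v,
                "scale_shift_log2": float(config.vowel_scale_shift.get(v, 0.0)),
                **{f"dev_f{i + 1}": d for i, d in enumerate(dev)},
            }
            for v, dev in config.vowel_templates.items()
        ]
    )
    return table, {"speakers": truth_speakers, "vowels": truth_vowels}
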