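"""Hierarchical scale-factor model: recovery, invariances, normalization."""

import numpy as np
import pytest

from formantkit import (
    FormantTable,
    SyntheticConfig,
    concat_tables,
    fit_k_model,
    generate_population,
    kvtl,
    normalize_by_k,
    vowel_scale,
)
from formantkit.scalefactor import ScaleFactorModel


def k_arrays(fit, truth):
    order = truth["speakers"]["speaker"]
    k_hat = np.array([fit.speaker_k[s] for s in order])
    return k_hat, truth["speakers"]["k"].to_numpy()


class TestFit:
    def test_parameter_recovery(self, recovery_population):
        table, truth = recovery_population
        fit = fit_k_model(table)
        k_hat, k_true = k_arrays(fit, truth)
        assert np.corrcoef(k_hat, k_true)[0, 1] > 0.95
        assert abs(fit.tau - 0.10) / 0.10 < 0.25
        # residual SDs recovered in decreasing order, near the generator's
        sig = [fit.sigma_by_formant[i] for i in (1, 2, 3, 4)]
        np.testing.assert_allclose(sig, [0.06, 0.04, 0.03, 0.02], rtol=0.35)

    def test_doubled_speaker_k_difference_one(self, two_speaker_doubled):
        fit = fit_k_model(two_speaker_doubled)
        assert fit.speaker_k["s2"] - fit.speaker_k["s1"] == pytest.approx(1.0, abs=0.01)

    def test_identical_speakers_collapse(self):
        parts = [
            FormantTable.from_formants(
                [m * f for f in (500, 1500, 2500, 3500)],
                token=f"{sp}_{v}", speaker=sp, vowel=v,
            )
            for sp in ("s1", "s2", "s3")
            for v, m in (("a", 1.0), ("e", 1.12))
        ]
        fit = fit_k_model(concat_tables(parts))
        assert fit.tau < 1e-3
        assert max(abs(k) for k in fit.speaker_k.values()) < 1e-6

    def test_sum_to_zero_constraints(self, recovery_population):
        table, _ = recovery_population
        fit = fit_k_model(table)
        assert abs(sum(fit.formant_effects.values())) < 1e-8
        assert abs(sum(fit.vowel_effects.values())) < 1e-8
        for v in fit.vowel_effects:
            assert abs(sum(fit.interaction[(i, v)] for i in fit.formant_effects)) < 1e-8
        for i in fit.formant_effects:
            assert abs(sum(fit.interaction[(i, v)] for v in fit.vowel_effects)) < 1e-8
        assert abs(np.mean(list(fit.speaker_k.values()))) < 0.02

    def test_shift_equivariance(self, recovery_population):
        """Scaling all frequencies moves only the grand mean."""
        table, _ = recovery_population
        fit_a = fit_k_model(table)
        shifted = table.with_frequencies(table.data["frequency_hz"].to_numpy() * 2.0)
        fit_b = fit_k_model(shifted)
        assert fit_b.grand_mean == pytest.approx(fit_a.grand_mean + 1.0, abs=1e-5)
        for s in fit_a.speaker_k:
            assert fit_b.speaker_k[s] == pytest.approx(fit_a.speaker_k[s], abs=1e-5)
        assert fit_b.tau == pytest.approx(fit_a.tau, rel=1e-3)

    def test_missing_values_tolerated(self):
        table, truth = generate_population(
            SyntheticConfig(seed=77, missing_rate=(0.3, 0.1, 0.1, 0.1))
        )
        fit = fit_k_model(table)
        k_hat, k_true = k_arrays(fit, truth)
        assert np.corrcoef(k_hat, k_true)[0, 1] > 0.95

    def test_vowel_free_variant(self):
        table, truth = generate_population(SyntheticConfig(seed=13))
        df = table.data.copy()
        df["vowel"] = None
        fit = fit_k_model(FormantTable(df))
        assert fit.vowel_effects == {}
        k_hat = np.array(
            [fit.speaker_k[s] for s in truth["speakers"]["speaker"]]
        )
        assert np.corrcoef(k_hat, truth["speakers"]["k"].to_numpy())[0, 1] > 0.9

    def test_partial_vowel_labels_rejected(self):
        table, _ = generate_population(SyntheticConfig(seed=13, n_speakers=3))
        df = table.data.copy()
        df.loc[0, "vowel"] = None
        with pytest.raises(ValueError, match="vowel"):
            ScaleFactorModel(FormantTable(df, validate=False))

    def test_too_few_speakers_rejected(self):
        t = FormantTable.from_formants([500, 1500], speaker="s1", vowel="a")
        with pytest.raises(ValueError, match="speakers"):
            ScaleFactorModel(t)

    def test_deterministic_given_data(self, recovery_population):
        table, _ = recovery_population
        a, b = fit_k_model(table), fit_k_model(table)
        assert a.loglik == b.loglik
        assert a.speaker_k == b.speaker_k

    def test_equal_sigma_matches_centered_mean_log(self, recovery_population):
        """Homoscedastic fit on balanced data ~ mean log-formant."""
        table, _ = recovery_population
        fit = fit_k_model(table, equal_sigma=True)
        wide = table.to_wide()
        ml = np.log2(wide[["f1", "f2", "f3", "f4"]].astype(float)).mean(axis=1)
        sp_mean = ml.groupby(wide["speaker"]).mean()
        centered = sp_mean - sp_mean.mean()
        for s, v in centered.items():
            assert fit.speaker_k[s] == pytest.approx(v, abs=0.01)

    def test_summary_mentions_key_quantities(self, recovery_population):
        table, _ = recovery_population
        s = fit_k_model(table).summary()
        assert "tau" in s and "sigma" in s and "speaker k" in s


class TestVowelScale:
    def test_null_recovery(self):
        table, _ = generate_population(
            SyntheticConfig(
                seed=31,
                vowel_templates={f"v{j}": (0, 0, 0, 0) for j in range(8)},
            )
        )
        b = vowel_scale(fit_k_model(table))
        assert max(abs(x) for x in b.values()) < 0.02

    def test_injected_shift_recovered(self):
        templates = {f"v{j}": (0, 0, 0, 0) for j in range(8)}
        table, _ = generate_population(
            SyntheticConfig(
                seed=32, vowel_templates=templates,
                vowel_scale_shift={"v0": 0.1},
            )
        )
        b = vowel_scale(fit_k_model(table))
        others = np.mean([b[v] for v in b if v != "v0"])
        assert b["v0"] - others == pytest.approx(0.1, abs=0.02)


class TestKVTL:
    @pytest.mark.parametrize("k,ref,expected", [(1, 17, 8.5), (0, 12.3, 12.3), (-1, 17, 34)])
    def test_projection(self, k, ref, expected):
        assert kvtl(k, ref) == pytest.approx(expected)

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            kvtl(0.5, -1)


class TestNormalizeByK:
    def test_refit_collapses_speaker_variation(self, recovery_population):
        table, _ = recovery_population
        fit = fit_k_model(table)
        refit = fit_k_model(normalize_by_k(table, fit))
        assert max(abs(k) for k in refit.speaker_k.values()) < 0.02
        assert refit.tau < 0.02

    def test_doubled_speakers_coincide(self, two_speaker_doubled):
        fit = fit_k_model(two_speaker_doubled)
        norm = normalize_by_k(two_speaker_doubled, fit)
        wide = norm.to_wide()
        for v in ("a", "e", "o"):
            a = wide.loc[f"s1_{v}", [f"f{i}" for i in range(1, 5)]].astype(float)
            b = wide.loc[f"s2_{v}", [f"f{i}" for i in range(1, 5)]].astype(float)
            np.testing.assert_allclose(a, b, rtol=0.02)

    def test_unseen_speaker_rejected(self, two_speaker_doubled):
        fit = fit_k_model(two_speaker_doubled)
        extra = FormantTable.from_formants(
            [400, 1200, 2000, 2800], token="x", speaker="s9", vowel="a"
        )
        with pytest.raises(ValueError, match="s9"):
            normalize_by_k(extra, fit)
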