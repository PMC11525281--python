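"""Tube-model dF regression, apparent VTL, schwa residuals, pooling."""

import warnings

import numpy as np
import pytest

from formantkit import (
    FormantTable,
    FormantValidationError,
    TubeConfig,
    VTLRegression,
    concat_tables,
    estimate_vtl,
    fit_dF,
    schwa,
    tube_positions,
    vtl_per_speaker,
    vtl_per_token,
)

CO = TubeConfig("closed_open")
CC = TubeConfig("closed_closed")


class TestFitDF:
    def test_zero_intercept_closed_form(self):
        # sum(xF)/sum(x^2) = 24362.5 / 21
        dF, se, b = fit_dF([0.5, 1.5, 2.5, 3.5], [567, 1672, 2789, 4171])
        assert dF == pytest.approx(24362.5 / 21, rel=1e-12)
        assert b == 0.0

    def test_zero_intercept_half_wave_positions(self):
        dF, _, _ = fit_dF([2, 3, 4, 5], [1800, 2400, 3800, 5500])
        assert dF == pytest.approx(53500 / 54, rel=1e-12)

    def test_single_point(self):
        dF, se, _ = fit_dF([2.5], [2500])
        assert dF == pytest.approx(1000.0)
        assert se == 0.0

    def test_free_intercept_singular_design(self):
        with pytest.raises(ValueError, match="singular"):
            fit_dF([1, 1, 1], [500, 600, 700], intercept_zero=False)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_dF([], [])
        with pytest.raises(ValueError):
            fit_dF([1], [500], intercept_zero=False)

    def test_grid_oracle_zero_intercept(self):
        """Closed-form dF matches a dense-grid SSE minimization."""
        rng = np.random.default_rng(123)
        pos = np.array([0.5, 1.5, 2.5, 3.5])
        for _ in range(50):
            dF_true = rng.uniform(500, 2000)
            f = dF_true * pos * np.exp(rng.normal(0, 0.05, 4))
            f.sort()
            dF_hat, _, _ = fit_dF(pos, f)
            grid = np.linspace(0.5 * dF_true, 2 * dF_true, 20001)
            sse = ((f[None, :] - grid[:, None] * pos[None, :]) ** 2).sum(axis=1)
            dF_grid = grid[np.argmin(sse)]
            assert dF_hat == pytest.approx(dF_grid, abs=grid[1] - grid[0])


class TestEstimateVTL:
    def test_closed_closed_with_leading_missing(self):
        est = estimate_vtl([None, 1800, 2400, 3800, 5500], CC)
        assert est.vtl_cm == pytest.approx(17.9, abs=0.05)
        assert est.n_points == 4

    def test_free_intercept(self):
        est = estimate_vtl([1800, 2400, 3800, 5500], intercept_zero=False)
        assert est.vtl_cm == pytest.approx(14.2, abs=0.05)

    def test_speaker_means_point_and_interval(self):
        est = estimate_vtl([567, 1672, 2789, 4171], CO)
        assert est.vtl_cm == pytest.approx(15.26, abs=0.05)
        assert est.ci95_cm[0] == pytest.approx(14.7, abs=0.05)
        assert est.ci95_cm[1] == pytest.approx(15.8, abs=0.05)
        assert est.ci95_cm[0] < est.vtl_cm < est.ci95_cm[1]

    def test_scaling_formants_halves_vtl(self):
        f = [567, 1672, 2789, 4171]
        a = estimate_vtl(f, CO)
        b = estimate_vtl([2 * x for x in f], CO)
        assert b.vtl_cm == pytest.approx(a.vtl_cm / 2, rel=1e-12)
        assert b.dF_hz == pytest.approx(a.dF_hz * 2, rel=1e-12)

    def test_no_present_formants_errors(self):
        with pytest.raises(ValueError):
            estimate_vtl([None, None])

    def test_non_ascending_rejected(self):
        with pytest.raises(FormantValidationError):
            estimate_vtl([1500, 500, 2500])

    def test_free_intercept_slope_same_for_both_tubes(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            f = np.sort(rng.uniform(300, 5000, 4))
            a = estimate_vtl(list(f), TubeConfig("closed_open", intercept_zero=False))
            b = estimate_vtl(list(f), TubeConfig("closed_closed", intercept_zero=False))
            assert a.dF_hz == pytest.approx(b.dF_hz, rel=1e-12)
            assert a.vtl_cm == pytest.approx(b.vtl_cm, rel=1e-12)

    def test_model_object_exposes_points(self):
        model = VTLRegression([None, 1800, 2400], CC)
        assert [p.position for p in model.points] == [2.0, 3.0]
        est = model.fit()
        assert "VTL" in est.summary()


class TestSchwa:
    def test_printed_i_vowel(self):
        res = schwa([436, 2559, 3104, 4375], CO)
        assert res.dF_hz == pytest.approx(1291.86, abs=1.0)
        assert res.vtl_apparent_cm == pytest.approx(13.7, abs=0.05)
        np.testing.assert_allclose(
            res.ff_relative_dF, [-0.16, 0.48, -0.10, -0.11], atol=0.005
        )

    def test_perfect_cylinder_zero_deviations(self):
        dF = 1100.0
        f = [0.5 * dF, 1.5 * dF, 2.5 * dF, 3.5 * dF]
        res = schwa(f, CO)
        np.testing.assert_allclose(res.ff_relative_dF, 0, atol=1e-12)
        np.testing.assert_allclose(res.schwa_formants_hz, f, rtol=1e-12)

    def test_scale_invariance_of_deviations(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            dF = rng.uniform(400, 2000)
            f = dF * (np.array([0.5, 1.5, 2.5, 3.5]) + rng.uniform(-0.2, 0.2, 4))
            f.sort()
            s = rng.uniform(0.1, 10)
            a = schwa(list(f), CO).ff_relative_dF
            b = schwa(list(f * s), CO).ff_relative_dF
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_missing_formant_gives_missing_deviation(self):
        res = schwa([436, None, 3104, 4375], CO)
        assert np.isnan(res.ff_relative_dF[1])
        assert np.isfinite(res.ff_relative_dF[[0, 2, 3]]).all()

    def test_semitone_deviations_consistent(self):
        res = schwa([436, 2559, 3104, 4375], CO)
        pred = res.schwa_formants_hz
        np.testing.assert_allclose(
            res.ff_relative_semitones,
            12 * np.log2(np.array([436, 2559, 3104, 4375]) / pred),
        )


class TestPooling:
    def test_per_token_with_all_missing_token(self):
        t1 = FormantTable.from_formants([564, 2442, None, 4038], token="had")
        t2 = FormantTable.from_formants([None, None, None, None], token="void")
        table = concat_tables([t1, t2])
        with pytest.warns(UserWarning, match="void"):
            out = vtl_per_token(table)
        assert out["had"] is not None and out["void"] is None

    def test_per_token_printed_rows(self, printed_token_wide):
        table = FormantTable.read_csv(printed_token_wide, "wide")
        out = vtl_per_token(table)
        assert len(out) == 2
        assert all(e is not None and np.isfinite(e.vtl_cm) for e in out.values())

    def test_per_speaker_pools_all_tokens(self):
        parts = [
            FormantTable.from_formants(
                [500 * m, 1500 * m, 2500 * m, 3500 * m],
                token=f"t{i}", speaker="sp1",
            )
            for i, m in enumerate([0.95, 1.0, 1.05])
        ]
        est = vtl_per_speaker(concat_tables(parts))["sp1"]
        assert est.n_points == 12

    def test_one_token_speaker_matches_per_token(self):
        table = FormantTable.from_formants(
            [564, 2442, None, 4038], token="had", speaker="w39"
        )
        by_tok = vtl_per_token(table)["had"]
        by_sp = vtl_per_speaker(table)["w39"]
        assert by_sp.vtl_cm == pytest.approx(by_tok.vtl_cm, rel=1e-12)

    def test_balanced_pooled_equals_means_fit(self):
        """On a complete balanced table, pooled dF = dF from formant means."""
        rng = np.random.default_rng(21)
        base = np.array([0.5, 1.5, 2.5, 3.5]) * 1200
        rows = []
        for i in range(12):
            f = np.sort(base * np.exp(rng.normal(0, 0.03, 4)))
            rows.append(
                FormantTable.from_formants(list(f), token=f"t{i}", speaker="sp")
            )
        table = concat_tables(rows)
        pooled = vtl_per_speaker(table)["sp"].dF_hz
        means = table.to_wide()[["f1", "f2", "f3", "f4"]].astype(float).mean()
        from_means = estimate_vtl(list(means), CO).dF_hz
        assert pooled == pytest.approx(from_means, rel=1e-12)
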