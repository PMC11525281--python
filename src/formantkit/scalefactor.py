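"""Hierarchical scale-factor model for multi-speaker formant tables.

Each measured formant is one observation of its log2 frequency:

    log2 F = mu + a_i + b_v + g_iv + k_s + eps,
    eps ~ N(0, sigma_i^2),   k_s ~ N(0, tau^2),

with formant-index effects a_i, vowel effects b_v, their interaction
g_iv (different formants may shift independently in different vowels), a
per-speaker scale factor k_s, and a residual SD that differs by formant
(lower formants are far more variable than upper ones, so a
heteroscedastic residual makes the model lean on the stable upper
formants — a homoscedastic fit degenerates to the mean log-formant).

k is in binary-log units: k = 1 means a speaker's formants sit one octave
above the sample average, i.e. a vocal tract half as long.  Because the
unit of analysis is a single formant, missing values never force a whole
token out of the data.

Estimation is deterministic maximum marginal likelihood: the Gaussian
random effect is integrated out in closed form per speaker block
(rank-one Woodbury identities), fixed effects are profiled by GLS, and a
quasi-Newton search runs over (log tau, log sigma_i) from fixed starting
values.  Speaker scale factors are reported as posterior means (BLUPs),
centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .table import FormantTable

__all__ = [
    "ScaleFactorModel",
    "ScaleFactorResults",
    "fit_k_model",
    "kvtl",
    "vowel_scale",
    "normalize_by_k",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails to converge."""


def _sum_code(levels: list) -> dict:
    """Sum-to-zero contrast codes: level -> row of length len(levels)-1."""
    L = len(levels)
    codes = {}
    for j, lev in enumerate(levels):
        row = np.zeros(L - 1)
        if j < L - 1:
            row[j] = 1.0
        else:
            row[:] = -1.0
        codes[lev] = row
    return codes


@dataclass
class ScaleFactorResults:
    """Fitted scale-factor model.

    All effects are in log2 units and sum-to-zero coded; ``speaker_k`` is
    centered so its mean is ~0 on balanced data.
    """

    grand_mean: float
    formant_effects: dict
    vowel_effects: dict
    interaction: dict
    speaker_k: dict
    tau: float
    sigma_by_formant: dict
    loglik: float
    n_obs: int
    converged: bool
    model: "ScaleFactorModel" = field(repr=False, default=None)

    def kvtl_per_speaker(self, reference_vtl_cm: float) -> dict:
        return {s: kvtl(k, reference_vtl_cm) for s, k in self.speaker_k.items()}

    def summary(self) -> str:
        lines = [
            "Hierarchical scale-factor model (max marginal likelihood)",
            "=" * 58,
            f"observations      : {self.n_obs}",
            f"speakers          : {len(self.speaker_k)}",
            f"log-likelihood    : {self.loglik:.3f}",
            f"tau (SD of k)     : {self.tau:.4f} log2 units",
            "residual SD by formant:",
        ]
        for i, s in sorted(self.sigma_by_formant.items()):
            lines.append(f"  F{i}: sigma = {s:.4f}")
        if self.vowel_effects:
            lines.append("vowel scale effects b_v (log2):")
            for v, b in sorted(self.vowel_effects.items()):
                lines.append(f"  {v}: {b:+.4f}")
        ks = np.array(list(self.speaker_k.values()))
        lines.append(
            f"speaker k         : mean {ks.mean():+.4f}, "
            f"range [{ks.min():+.3f}, {ks.max():+.3f}]"
        )
        return "\n".join(lines)


class ScaleFactorModel:
    """Build the model from a long-format table, then :meth:`fit`.

    Requires >= 2 speakers and >= 2 formant indices.  Vowel labels are
    used when present on every row; a table with no vowel labels at all
    is fitted without the b_v and g_iv terms; partially labeled tables
    are rejected.
    """

    def __init__(self, table: FormantTable, equal_sigma: bool = False):
        df = table.data.dropna(subset=["frequency_hz", "speaker"]).copy()
        if df.empty:
            raise ValueError("no usable observations (need speaker labels)")
        n_vowel = df["vowel"].notna().sum()
        if 0 < n_vowel < len(df):
            raise ValueError("vowel labels must be present on all rows or none")
        self.has_vowel = n_vowel == len(df)
        self.speakers = sorted(df["speaker"].unique().tolist())
        self.findices = sorted(df["formant_index"].unique().tolist())
        if len(self.speakers) < 2:
            raise ValueError("need at least 2 speakers")
        if len(self.findices) < 2:
            raise ValueError("need at least 2 formant indices")
        self.vlevels = sorted(df["vowel"].unique().tolist()) if self.has_vowel else []
        self.equal_sigma = equal_sigma

        self.y = np.log2(df["frequency_hz"].to_numpy(dtype=float))
        self.sp_code = pd.Categorical(
            df["speaker"], categories=self.speakers
        ).codes.astype(int)
        self.f_code = pd.Categorical(
            df["formant_index"], categories=self.findices
        ).codes.astype(int)
        self.n = len(self.y)
        self.n_speakers = len(self.speakers)

        fc = _sum_code(self.findices)
        Xf = np.stack([fc[i] for i in df["formant_index"]])
        blocks = [np.ones((self.n, 1)), Xf]
        if self.has_vowel:
            vc = _sum_code(self.vlevels)
            Xv = np.stack([vc[v] for v in df["vowel"]])
            Xint = np.einsum("ni,nj->nij", Xf, Xv).reshape(self.n, -1)
            blocks += [Xv, Xint]
        self.X = np.concatenate(blocks, axis=1)
        self._fcode_mat = np.stack([fc[i] for i in self.findices])  # I x (I-1)
        if self.has_vowel:
            self._vcode_mat = np.stack([vc[v] for v in self.vlevels])  # V x (V-1)

    # ------------------------------------------------------------------ #

    def _variances(self, theta: np.ndarray):
        tau = float(np.exp(theta[0]))
        if self.equal_sigma:
            sig = np.full(len(self.findices), np.exp(theta[1]))
        else:
            sig = np.exp(theta[1:])
        return tau, sig

    def _profile(self, theta: np.ndarray):
        """GLS fixed effects and profiled quantities at given (tau, sigma)."""
        tau, sig = self._variances(theta)
        w = 1.0 / sig[self.f_code] ** 2
        S = np.bincount(self.sp_code, weights=w, minlength=self.n_speakers)
        c = tau**2 / (1.0 + tau**2 * S)
        Xw = self.X * w[:, None]
        XtWX = self.X.T @ Xw
        XtWy = Xw.T @ self.y
        p = self.X.shape[1]
        U = np.zeros((self.n_speakers, p))
        np.add.at(U, self.sp_code, Xw)
        v = np.bincount(self.sp_code, weights=w * self.y, minlength=self.n_speakers)
        XtViX = XtWX - (U.T * c) @ U
        XtViy = XtWy - U.T @ (c * v)
        beta = np.linalg.solve(XtViX, XtViy)
        r = self.y - self.X @ beta
        rw = np.bincount(self.sp_code, weights=w * r, minlength=self.n_speakers)
        quad = float(np.sum(w * r * r) - np.sum(c * rw * rw))
        logdet = float(
            np.sum(np.log(sig[self.f_code] ** 2)) + np.sum(np.log1p(tau**2 * S))
        )
        ll = -0.5 * (self.n * np.log(2.0 * np.pi) + logdet + quad)
        return beta, r, rw, S, c, tau, sig, ll

    def _nll(self, theta: np.ndarray) -> float:
        try:
            return -self._profile(theta)[-1]
        except np.linalg.LinAlgError:
            return 1e12

    def fit(
        self,
        start_tau: float = 0.1,
        start_sigma: float = 0.05,
        tol: float = 1e-8,
    ) -> ScaleFactorResults:
        n_sig = 1 if self.equal_sigma else len(self.findices)
        theta0 = np.concatenate(
            ([np.log(start_tau)], np.full(n_sig, np.log(start_sigma)))
        )
        bounds = [(np.log(1e-8), np.log(10.0))] + [
            (np.log(1e-6), np.log(10.0))
        ] * n_sig
        res = minimize(
            self._nll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if not res.success:
            # degenerate (near noise-free) data pins sigma at its lower
            # bound, where the likelihood keeps rising and line searches
            # stall; polish with a bounded simplex search and accept a
            # finite boundary optimum
            res = minimize(
                self._nll,
                res.x,
                method="Nelder-Mead",
                bounds=bounds,
                options={"fatol": 1e-9, "xatol": 1e-7, "maxiter": 5000},
            )
        if not np.isfinite(res.fun) or res.fun > self._nll(theta0) + 1e-6:
            raise ConvergenceError(
                f"optimizer failed after {res.nit} iterations: {res.message} "
                f"(final nll {res.fun:.6g})"
            )
        beta, r, rw, S, c, tau, sig, ll = self._profile(res.x)

        # BLUPs: posterior mean of k_s given the data
        k_raw = tau**2 * rw / (1.0 + tau**2 * S)
        k = k_raw - k_raw.mean()

        # unpack sum-to-zero effects
        pos = 0
        grand_mean = float(beta[pos]); pos += 1
        nf = len(self.findices) - 1
        a = self._fcode_mat @ beta[pos : pos + nf]; pos += nf
        formant_effects = dict(zip(self.findices, a))
        vowel_effects, interaction = {}, {}
        if self.has_vowel:
            nv = len(self.vlevels) - 1
            b = self._vcode_mat @ beta[pos : pos + nv]; pos += nv
            vowel_effects = dict(zip(self.vlevels, b))
            B = beta[pos : pos + nf * nv].reshape(nf, nv)
            G = self._fcode_mat @ B @ self._vcode_mat.T
            interaction = {
                (i, v): float(G[ii, vv])
                for ii, i in enumerate(self.findices)
                for vv, v in enumerate(self.vlevels)
            }
        return ScaleFactorResults(
            grand_mean=grand_mean,
            formant_effects={i: float(x) for i, x in formant_effects.items()},
            vowel_effects={v: float(x) for v, x in vowel_effects.items()},
            interaction=interaction,
            speaker_k=dict(zip(self.speakers, k.astype(float))),
            tau=tau,
            sigma_by_formant=dict(zip(self.findices, sig.astype(float))),
            loglik=float(ll),
            n_obs=self.n,
            converged=bool(res.success),
            model=self,
        )


def fit_k_model(table: FormantTable, equal_sigma: bool = False) -> ScaleFactorResults:
    """Fit the scale-factor model; see :class:`ScaleFactorModel`."""
    return ScaleFactorModel(table, equal_sigma=equal_sigma).fit()


def kvtl(k: float, reference_vtl_cm: float) -> float:
    """Project a scale factor k onto a length scale: ref / 2**k.

    k = 1 (formants one octave high) maps a 17 cm reference to 8.5 cm.
    Not an anatomical measure — just k on a more intuitive scale.
    """
    if reference_vtl_cm <= 0:
        raise ValueError("reference VTL must be positive")
    return reference_vtl_cm / 2.0**k


def vowel_scale(fit: ScaleFactorResults) -> dict:
    """Per-vowel scale shift b_v (log2): the main effect of vowel,
    averaging across all formants."""
    return dict(fit.vowel_effects)


def normalize_by_k(table: FormantTable, fit: ScaleFactorResults) -> FormantTable:
    """Divide each speaker's frequencies by 2**(k_s - mean k); Hz kept.

    Refitting the model on the output drives all speaker k toward 0.
    """
    k = fit.speaker_k
    speakers = table.data["speaker"]
    unseen = sorted(set(speakers.dropna()) - set(k))
    if unseen:
        raise ValueError(f"speakers not present in the fit: {unseen}")
    kbar = float(np.mean(list(k.values())))
    corr = speakers.map(lambda s: 2.0 ** (k[s] - kbar) if pd.notna(s) else 1.0)
    return table.with_frequencies(
        table.data["frequency_hz"].to_numpy() / corr.to_numpy(dtype=float)
    )
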