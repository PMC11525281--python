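"""Comparing normalization methods by vowel separation.

Two yardsticks: *cluster purity* — k-means with as many clusters as vowel
categories; each cluster takes its majority label, and purity is the
fraction of tokens whose cluster's majority label matches their own — and
*balanced accuracy* of a multinomial logistic classifier (mean per-class
recall).  The transfer protocol trains the classifier on one group of
speakers and tests on a disjoint group with a non-overlapping vocal tract
length range; raw formant frequencies collapse under this transfer while
scale-invariant representations barely move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score

from .table import FormantTable
from .tube import TubeConfig, estimate_vtl, tube_positions
from .scalefactor import ScaleFactorResults, fit_k_model

__all__ = [
    "FeatureSpec",
    "EvalResult",
    "build_features",
    "cluster_purity",
    "balanced_accuracy",
    "transfer_experiment",
]

logger = logging.getLogger(__name__)

METHODS = ("raw_log", "log_ratios", "mean_log_formant", "schwa_dev", "k_normalized")


@dataclass(frozen=True)
class FeatureSpec:
    """One normalization method applied to a contiguous formant subset.

    ``formant_subset`` must be contiguous from F1 (F1-F2, F1-F3, F1-F4);
    ``extrinsic`` pools information across a speaker's tokens (speaker
    mean log-formant, speaker-pooled dF, or the scale-factor model) where
    the method supports it.
    """

    method: str
    formant_subset: tuple = (1, 2, 3, 4)
    extrinsic: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        subset = tuple(sorted(self.formant_subset))
        object.__setattr__(self, "formant_subset", subset)
        if subset != tuple(range(1, len(subset) + 1)):
            raise ValueError("formant_subset must be contiguous starting at F1")

    def label(self) -> str:
        hi = max(self.formant_subset)
        kind = "extrinsic" if self.extrinsic else "intrinsic"
        return f"{self.method}/F1-F{hi}/{kind}"


@dataclass
class EvalResult:
    cluster_purity: float
    balanced_accuracy: float
    n_tokens: int
    feature: FeatureSpec
    split: str = "within"
    n_dropped: int = 0


def build_features(
    table: FormantTable,
    spec: FeatureSpec,
    fit: ScaleFactorResults | None = None,
    tube: TubeConfig | None = None,
) -> pd.DataFrame:
    """Token-by-feature matrix for one spec (index = token id).

    Tokens missing any formant in the requested subset are dropped (the
    drop count is logged).  ``fit`` is required for ``k_normalized``.
    """
    tube = tube or TubeConfig()
    wide = table.to_wide()
    cols = [f"f{i}" for i in spec.formant_subset]
    missing_cols = [c for c in cols if c not in wide.columns]
    if missing_cols:
        raise ValueError(f"table lacks formants {missing_cols}")
    ok = wide[cols].notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("%s: dropped %d tokens with missing formants", spec.label(), dropped)
    sub = wide.loc[ok]
    if sub.empty:
        raise ValueError(f"no tokens left after dropping missing formants for {spec.label()}")
    F = sub[cols].to_numpy(dtype=float)
    logF = np.log2(F)
    m = spec.method

    if m == "raw_log":
        feats = logF
        names = [f"log2_{c}" for c in cols]
    elif m == "log_ratios":
        if len(cols) < 2:
            raise ValueError("log_ratios needs at least two formants")
        feats = np.diff(logF, axis=1)
        names = [f"ratio_{i}_{i + 1}" for i in spec.formant_subset[:-1]]
    elif m == "mean_log_formant":
        if spec.extrinsic:
            token_mean = logF.mean(axis=1)
            sp_mean = (
                pd.Series(token_mean, index=sub.index)
                .groupby(sub["speaker"])
                .transform("mean")
                .to_numpy()
            )
            feats = logF - sp_mean[:, None]
        else:
            feats = logF - logF.mean(axis=1, keepdims=True)
        names = [f"dev_{c}" for c in cols]
    elif m == "schwa_dev":
        pos = tube_positions(np.array(spec.formant_subset), tube)
        if spec.extrinsic:
            dF_by_speaker = {}
            for sp, grp in sub.groupby("speaker"):
                pooled = np.concatenate([grp[c].to_numpy(dtype=float) for c in cols])
                pooled_pos = np.concatenate([np.full(len(grp), p) for p in pos])
                dF_by_speaker[sp] = float(
                    np.sum(pooled_pos * pooled) / np.sum(pooled_pos**2)
                )
            dF = sub["speaker"].map(dF_by_speaker).to_numpy(dtype=float)
        else:
            sxx = float(np.sum(pos**2))
            dF = (F @ pos) / sxx
        feats = F / dF[:, None] - pos[None, :]
        names = [f"rel_{c}" for c in cols]
    elif m == "k_normalized":
        if fit is None:
            raise ValueError("k_normalized features require a scale-factor fit")
        k = fit.speaker_k
        unseen = sorted(set(sub["speaker"].dropna()) - set(k))
        if unseen:
            raise ValueError(f"speakers not in the scale-factor fit: {unseen}")
        kbar = float(np.mean(list(k.values())))
        ks = sub["speaker"].map(k).to_numpy(dtype=float) - kbar
        feats = logF - ks[:, None]
        names = [f"knorm_log2_{c}" for c in cols]
    else:  # pragma: no cover - guarded by FeatureSpec
        raise ValueError(m)

    out = pd.DataFrame(feats, index=sub.index, columns=names)
    out.attrs["n_dropped"] = dropped
    return out


def _standardize(X: np.ndarray, ref: np.ndarray | None = None):
    ref = X if ref is None else ref
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, (mu, sd)


def cluster_purity(
    features: np.ndarray,
    labels,
    n_clusters: int | None = None,
    seed: int = 0,
) -> float:
    """Majority-label purity of a k-means clustering.

    ``n_clusters`` defaults to the number of label categories.  Features
    are standardized to unit variance before clustering.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if n_clusters is None:
        n_clusters = len(np.unique(y))
    if len(X) < n_clusters:
        raise ValueError(f"{len(X)} tokens < {n_clusters} clusters")
    Xs, _ = _standardize(X)
    km = KMeans(n_clusters=n_clusters, n_init=25, random_state=seed)
    assign = km.fit_predict(Xs)
    correct = 0
    for cl in range(n_clusters):
        members = y[assign == cl]
        if len(members) == 0:
            continue
        _, counts = np.unique(members, return_counts=True)
        correct += counts.max()
    return correct / len(y)


def balanced_accuracy(
    features_train: np.ndarray,
    labels_train,
    features_test: np.ndarray,
    labels_test,
    seed: int = 0,
    C: float = 10.0,
) -> float:
    """Mean per-class recall of a regularized multinomial logistic fit."""
    ytr = np.asarray(labels_train)
    yte = np.asarray(labels_test)
    absent = sorted(set(yte) - set(ytr))
    if absent:
        raise ValueError(f"test classes absent from training: {absent}")
    Xtr = np.asarray(features_train, dtype=float)
    Xte = np.asarray(features_test, dtype=float)
    Xtr_s, (mu, sd) = _standardize(Xtr)
    Xte_s = (Xte - mu) / sd
    clf = LogisticRegression(C=C, max_iter=5000, random_state=seed)
    clf.fit(Xtr_s, ytr)
    return float(balanced_accuracy_score(yte, clf.predict(Xte_s)))


def transfer_experiment(
    table: FormantTable,
    train_group,
    test_group,
    specs,
    seed: int = 0,
    tube: TubeConfig | None = None,
) -> list[EvalResult]:
    """Train-on-one-group, test-on-the-other vowel classification.

    For each feature spec, any extrinsic normalization is computed per
    speaker from that speaker's own tokens (the scale-factor model is
    fitted once on both groups, so every speaker's k is relative to the
    same global mean); the classifier itself sees only the training
    group.  Purity is reported for the test-group features.
    """
    if train_group == test_group:
        raise ValueError("train and test groups must differ")
    tr = table.for_group(train_group)
    te = table.for_group(test_group)
    if tr.n_tokens == 0 or te.n_tokens == 0:
        raise ValueError("both groups must be non-empty")
    overlap = set(tr.speakers) & set(te.speakers)
    if overlap:
        raise ValueError(f"groups share speakers: {sorted(overlap)}")
    fit_cache: list = []

    def pooled_fit():
        if not fit_cache:
            both = table.subset(table.data["group"].isin([train_group, test_group]))
            fit_cache.append(fit_k_model(both))
        return fit_cache[0]

    results = []
    for spec in specs:
        fit = pooled_fit() if spec.method == "k_normalized" else None
        ftr = build_features(tr, spec, fit=fit, tube=tube)
        fte = build_features(te, spec, fit=fit, tube=tube)
        wide_tr = tr.to_wide().loc[ftr.index]
        wide_te = te.to_wide().loc[fte.index]
        ytr = wide_tr["vowel"].to_numpy()
        yte = wide_te["vowel"].to_numpy()
        ba = balanced_accuracy(ftr.to_numpy(), ytr, fte.to_numpy(), yte, seed=seed)
        purity = cluster_purity(fte.to_numpy(), yte, seed=seed)
        results.append(
            EvalResult(
                cluster_purity=purity,
                balanced_accuracy=ba,
                n_tokens=len(fte),
                feature=spec,
                split=f"train={train_group}/test={test_group}",
                n_dropped=ftr.attrs.get("n_dropped", 0) + fte.attrs.get("n_dropped", 0),
            )
        )
    return results
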