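"""Binary and tissue-of-origin classifiers, fusion, and evaluation metrics.

Binary per-modality models are logistic regressions (entropy, URA) or an
elastic-net logistic on PCA scores (fragmentation).  The fused
cancer-signal model stacks per-modality scores with a logistic regression;
to avoid leakage the stacker is trained on out-of-fold sub-model scores
(internal stratified 5-fold).  Tissue-of-origin models produce per-sample
probability vectors over the seven cancer types per modality, fused by
arithmetic probability averaging; TOP1/TOP2 are read off the fused ranking.
All fitting uses training samples only, with per-feature training-median
imputation and training-statistics standardization baked into each bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

ELASTIC_NET_GRID = {"C": (0.1, 1.0), "l1_ratio": (0.5,)}


@dataclass
class ModelBundle:
    """A self-contained fitted binary scorer (no refit needed at predict)."""

    kind: str  # logistic | elastic_net
    modality: str
    feature_ids: list[str]
    model: LogisticRegression
    impute_values: pd.Series
    center: np.ndarray
    scale: np.ndarray
    seed: int
    threshold: float
    train_scores: pd.Series = field(repr=False, default=None)  # type: ignore


def _make_estimator(kind: str, seed: int, cv_labels=None, x=None):
    if kind == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if kind == "elastic_net":
        # small internal CV over the documented grid
        best, best_auc = None, -np.inf
        for c in ELASTIC_NET_GRID["C"]:
            for l1 in ELASTIC_NET_GRID["l1_ratio"]:
                est = LogisticRegression(
                    solver="saga", l1_ratio=l1, C=c,
                    max_iter=5000, random_state=seed,
                )
                if x is None or cv_labels is None or len(np.unique(cv_labels)) < 2:
                    return est
                aucs = []
                skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
                for tr, te in skf.split(x, cv_labels):
                    est.fit(x[tr], cv_labels[tr])
                    s = est.predict_proba(x[te])[:, 1]
                    if len(np.unique(cv_labels[te])) == 2:
                        aucs.append(roc_auc_score(cv_labels[te], s))
                score = float(np.mean(aucs)) if aucs else 0.0
                if score > best_auc:
                    best, best_auc = est, score
        return best
    raise ValueError(f"unknown model kind {kind!r}")


def _prepare(x: pd.DataFrame, impute: pd.Series, center, scale) -> np.ndarray:
    z = x.fillna(impute).to_numpy(dtype=float)
    return (z - center) / scale


def train_binary(
    features: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    kind: str = "logistic",
    modality: str = "entropy",
    seed: int = 0,
) -> ModelBundle:
    """Fit a binary classifier on training features (1 = cancer).

    NA cells are imputed with the per-feature training median, features are
    standardized on training statistics, and the decision threshold is
    chosen on the training scores by Youden's J.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    impute = features.median(axis=0).fillna(0.0)
    z = features.fillna(impute).to_numpy(dtype=float)
    center = z.mean(axis=0)
    scale = z.std(axis=0)
    scale[scale == 0] = 1.0
    zs = (z - center) / scale
    est = _make_estimator(kind, seed, cv_labels=y, x=zs)
    est.fit(zs, y)
    scores = est.predict_proba(zs)[:, 1]
    fpr, tpr, thr = roc_curve(y, scores)
    threshold = float(thr[np.argmax(tpr - fpr)])
    bundle = ModelBundle(
        kind=kind,
        modality=modality,
        feature_ids=list(features.columns),
        model=est,
        impute_values=impute,
        center=center,
        scale=scale,
        seed=seed,
        threshold=threshold,
    )
    bundle.train_scores = pd.Series(scores, index=features.index)
    return bundle


def predict_score(bundle: ModelBundle, features: pd.DataFrame) -> pd.Series:
    """Per-sample cancer-signal score in [0, 1]; row order irrelevant."""
    missing = [f for f in bundle.feature_ids if f not in features.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    x = features[bundle.feature_ids]
    zs = _prepare(x, bundle.impute_values, bundle.center, bundle.scale)
    return pd.Series(bundle.model.predict_proba(zs)[:, 1], index=features.index)


# ---------------------------------------------------------------------------
# fusion


def oof_scores(
    features: pd.DataFrame,
    labels: Sequence[int],
    kind: str,
    modality: str,
    seed: int,
    k: int = 5,
) -> pd.Series:
    """Out-of-fold sub-model scores for stacker training (leakage guard)."""
    y = np.asarray(labels, dtype=int)
    out = pd.Series(np.nan, index=features.index)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in skf.split(features, y):
        sub = train_binary(
            features.iloc[tr], y[tr], kind=kind, modality=modality, seed=seed
        )
        out.iloc[te] = predict_score(sub, features.iloc[te]).to_numpy()
    return out


def fuse_emced(
    e_scores: pd.Series | None,
    m_scores: pd.Series | None,
    f_scores: pd.Series | None,
    labels: Sequence[int],
    seed: int = 0,
) -> ModelBundle:
    """Logistic stacking over per-modality score vectors.

    Scores must be out-of-fold predictions on training samples; absent
    modalities (None) are dropped, degenerating gracefully to fewer-modality
    fusion.  Sample indices must agree across the provided vectors.
    """
    named = {
        "entropy": e_scores,
        "methylation": m_scores,
        "fragmentation": f_scores,
    }
    present = {k: v for k, v in named.items() if v is not None}
    if not present:
        raise ValueError("no modality scores supplied")
    idx = None
    for v in present.values():
        if idx is None:
            idx = v.index
        elif not idx.equals(v.index):
            raise ValueError("misaligned sample ids across modality scores")
    x = pd.DataFrame(present)
    return train_binary(x, labels, kind="logistic", modality="fusion", seed=seed)


@dataclass
class EMCEDModel:
    """Sub-models plus the trained stacker, end to end."""

    sub_bundles: dict[str, ModelBundle]
    fusion: ModelBundle

    def predict(self, blocks: dict[str, pd.DataFrame]) -> pd.Series:
        scores = {
            name: predict_score(b, blocks[name])
            for name, b in self.sub_bundles.items()
        }
        return predict_score(self.fusion, pd.DataFrame(scores))


def fit_emced(
    blocks: dict[str, tuple[pd.DataFrame, str]],
    labels: Sequence[int],
    seed: int = 0,
) -> EMCEDModel:
    """Train sub-models on full training data and the stacker on their
    internal 5-fold out-of-fold scores.

    ``blocks`` maps modality -> (training feature frame, model kind).
    """
    y = np.asarray(labels, dtype=int)
    subs = {}
    oofs = {}
    for name, (feats, kind) in blocks.items():
        subs[name] = train_binary(feats, y, kind=kind, modality=name, seed=seed)
        oofs[name] = oof_scores(feats, y, kind, name, seed)
    fusion = fuse_emced(
        oofs.get("entropy"), oofs.get("methylation"), oofs.get("fragmentation"),
        y, seed=seed,
    )
    return EMCEDModel(sub_bundles=subs, fusion=fusion)


# ---------------------------------------------------------------------------
# tissue of origin


@dataclass
class TOOBundle:
    """Per-modality multiclass model emitting 7-type probability vectors."""

    modality: str
    types: list[str]
    per_type: dict[str, ModelBundle]  # one-vs-rest route (entropy)
    multinomial: object  # multinomial route (elastic net)
    feature_ids: list[str]
    impute_values: pd.Series
    center: np.ndarray
    scale: np.ndarray
    use_sex: str  # "none" | "ovarian_only" | "all"


def _with_sex(features: pd.DataFrame, sex: pd.Series | None) -> pd.DataFrame:
    if sex is None:
        return features
    enc = (pd.Series(sex, index=features.index) == "female").astype(float)
    out = features.copy()
    out["sex_female"] = enc
    return out


def train_too(
    features: pd.DataFrame,
    cancer_type: pd.Series,
    sex: pd.Series | None = None,
    modality: str = "entropy",
    kind: str = "logistic",
    seed: int = 0,
) -> TOOBundle:
    """Fit one modality's tissue-of-origin model on cancer training samples.

    Entropy uses one-vs-rest logistic regressions with the sex covariate in
    the ovarian sub-model only; URA and fragmentation use a multinomial
    elastic-net logistic with sex as a global feature.
    """
    y = pd.Series(cancer_type, index=features.index).astype(str)
    types = sorted(y.unique())
    if len(types) < 2:
        raise ValueError("need at least two cancer types in training data")

    if kind == "logistic":
        per_type = {}
        for t in types:
            feats_t = features
            if t == "ovarian" and sex is not None:
                feats_t = _with_sex(features, sex)
            per_type[t] = train_binary(
                feats_t, (y == t).astype(int), kind="logistic",
                modality=modality, seed=seed,
            )
        return TOOBundle(
            modality=modality, types=types, per_type=per_type,
            multinomial=None, feature_ids=list(features.columns),
            impute_values=features.median(axis=0).fillna(0.0),
            center=np.zeros(0), scale=np.ones(0),
            use_sex="ovarian_only" if sex is not None else "none",
        )

    feats = _with_sex(features, sex) if sex is not None else features
    impute = feats.median(axis=0).fillna(0.0)
    z = feats.fillna(impute).to_numpy(dtype=float)
    center = z.mean(axis=0)
    scale = z.std(axis=0)
    scale[scale == 0] = 1.0
    est = LogisticRegression(
        solver="saga", l1_ratio=0.5, C=1.0, max_iter=5000, random_state=seed,
    ).fit((z - center) / scale, y)
    return TOOBundle(
        modality=modality, types=types, per_type={}, multinomial=est,
        feature_ids=list(feats.columns), impute_values=impute,
        center=center, scale=scale,
        use_sex="all" if sex is not None else "none",
    )


def too_probabilities(
    bundle: TOOBundle, features: pd.DataFrame, sex: pd.Series | None = None
) -> pd.DataFrame:
    """Per-sample probability vector over types, rows summing to 1."""
    if bundle.multinomial is not None:
        feats = _with_sex(features, sex) if bundle.use_sex == "all" else features
        x = feats.reindex(columns=bundle.feature_ids)
        z = (x.fillna(bundle.impute_values).to_numpy(dtype=float) - bundle.center)
        z = z / bundle.scale
        probs = bundle.multinomial.predict_proba(z)
        return pd.DataFrame(
            probs, index=features.index, columns=list(bundle.multinomial.classes_)
        )[bundle.types]
    cols = {}
    for t, sub in bundle.per_type.items():
        feats_t = features
        if t == "ovarian" and bundle.use_sex == "ovarian_only":
            feats_t = _with_sex(features, sex)
        cols[t] = predict_score(sub, feats_t[sub.feature_ids])
    raw = pd.DataFrame(cols)[bundle.types]
    total = raw.sum(axis=1)
    return raw.div(total.where(total > 0, 1.0), axis=0)


def predict_too(
    bundles: dict[str, TOOBundle],
    blocks: dict[str, pd.DataFrame],
    sex: pd.Series | None = None,
    fusion: str = "e_m_f",
) -> pd.DataFrame:
    """Fused type probabilities: arithmetic mean of the requested available
    modalities, renormalized.  Ranking ties break by alphabetical type order
    (column order of the result)."""
    wanted = {
        "entropy_only": ("entropy",),
        "e_m": ("entropy", "methylation"),
        "e_m_f": ("entropy", "methylation", "fragmentation"),
    }[fusion]
    mats = []
    for name in wanted:
        if name in bundles and name in blocks:
            mats.append(too_probabilities(bundles[name], blocks[name], sex))
    if not mats:
        raise ValueError("no requested modality is available")
    types = sorted(set().union(*[m.columns for m in mats]))
    acc = sum(m.reindex(columns=types).fillna(0.0) for m in mats) / len(mats)
    return acc.div(acc.sum(axis=1), axis=0)


def rank_types(probs: pd.DataFrame) -> pd.DataFrame:
    """TOP1/TOP2 calls per sample; ties resolved by alphabetical type order."""
    probs = probs[sorted(probs.columns)]
    types = list(probs.columns)
    # stable sort: alphabetical column order breaks probability ties
    order = np.argsort(-probs.to_numpy(), axis=1, kind="stable")
    return pd.DataFrame(
        {
            "top1": [types[i] for i in order[:, 0]],
            "top2": [types[i] for i in order[:, 1]],
        },
        index=probs.index,
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    auc: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    confusion: dict[str, int]  # tp, fp, tn, fn

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "confusion": self.confusion,
        }


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return (float(lo), float(hi))


def evaluate(
    scores: pd.Series | np.ndarray,
    labels: Sequence[int],
    threshold: float = 0.5,
) -> EvalReport:
    """Binary metrics: rank-statistic AUC (ties averaged), sensitivity and
    specificity at the threshold with Clopper-Pearson 95% CIs."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalReport(
        auc=auc,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=clopper_pearson(tp, tp + fn),
        specificity_ci=clopper_pearson(tn, tn + fp),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


@dataclass
class TOOReport:
    top1_accuracy: float
    top2_accuracy: float
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "top1_accuracy": self.top1_accuracy,
            "top2_accuracy": self.top2_accuracy,
            "confusion": self.confusion.to_dict(),
        }


def evaluate_too(probs: pd.DataFrame, true_types: pd.Series) -> TOOReport:
    y = pd.Series(true_types, index=probs.index).astype(str)
    calls = rank_types(probs)
    top1 = float((calls["top1"] == y).mean())
    top2 = float(((calls["top1"] == y) | (calls["top2"] == y)).mean())
    types = sorted(set(probs.columns) | set(y.unique()))
    conf = pd.crosstab(y, calls["top1"]).reindex(
        index=types, columns=types, fill_value=0
    )
    return TOOReport(top1_accuracy=top1, top2_accuracy=top2, confusion=conf)


def crossvalidate(
    features: pd.DataFrame,
    labels: Sequence[int],
    k: int = 5,
    seed: int = 0,
    kind: str = "logistic",
) -> dict:
    """Stratified k-fold CV: per-fold AUC and a pooled out-of-fold AUC."""
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y)
    if (counts < k).any():
        raise ValueError(f"every class needs >= {k} samples for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled = pd.Series(np.nan, index=features.index)
    folds = []
    for tr, te in skf.split(features, y):
        bundle = train_binary(features.iloc[tr], y[tr], kind=kind, seed=seed)
        s = predict_score(bundle, features.iloc[te])
        pooled.iloc[te] = s.to_numpy()
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], s)))
        folds.append(list(features.index[te]))
    return {
        "fold_aucs": fold_aucs,
        "pooled_auc": float(roc_auc_score(y, pooled)),
        "folds": folds,
        "seed": seed,
    }
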