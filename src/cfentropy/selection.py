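"""Region preprocessing and the feature-selection cascade.

Binary (cancer vs non-cancer) marker discovery proceeds in two stages on
training samples only: per-region effect statistics at a fixed specificity
(delta = case mean - control mean, sensitivity of cases beyond the control
quantile cutoff, two-sided Wilcoxon rank-sum P), thresholded conjunctively
(|delta| >= 0.02, sensitivity >= 0.4 entropy / 0.5 URA, P < 0.01); then a
random-forest importance filter (impurity importance > 0.006 entropy /
0.0055 URA).  Tissue-of-origin marker discovery uses one-vs-rest stats with
Boruta refinement for entropy, and Kruskal-Wallis (BH-FDR q < 0.05) +
Dunn's pairwise post-hoc + per-type Boruta top-k for URA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from cfentropy.io import RegionFeatureMatrix


@dataclass(frozen=True)
class RegionStats:
    region_id: str
    delta: float
    sensitivity_at_spec: float
    p_value: float

    @property
    def direction(self) -> str:
        return "up" if self.delta >= 0 else "down"


@dataclass
class SelectionConfig:
    """Thresholds for preprocessing and the binary cascade.

    Defaults carry the entropy-modality values; ``for_modality`` switches
    the sensitivity and importance thresholds for URA.
    """

    specificity: float = 0.80
    min_abs_delta: float = 0.02
    min_sensitivity: float = 0.4
    max_p: float = 0.01
    importance_threshold: float = 0.006
    min_depth: int = 50
    max_na_fraction: float = 0.90
    rng_seed: int = 0

    @classmethod
    def for_modality(cls, modality: str, rng_seed: int = 0) -> "SelectionConfig":
        if modality == "entropy":
            return cls(rng_seed=rng_seed)
        if modality in ("ura", "methylation"):
            return cls(
                min_sensitivity=0.5, importance_threshold=0.0055, rng_seed=rng_seed
            )
        raise ValueError(f"unknown modality {modality!r}")


def preprocess_regions(
    matrix: RegionFeatureMatrix, cfg: SelectionConfig | None = None
) -> RegionFeatureMatrix:
    """Mask low-depth cells and drop mostly-missing regions.

    Cells with effective depth < ``min_depth`` become NA; regions missing in
    more than ``max_na_fraction`` of samples are dropped.  Applies to the
    entropy and URA matrices; fragmentation profiles are not depth-filtered.
    """
    cfg = cfg or SelectionConfig()
    values = matrix.values.mask(matrix.depths < cfg.min_depth)
    na_frac = values.isna().mean(axis=0)
    keep = na_frac.index[na_frac <= cfg.max_na_fraction]
    if len(keep) == 0:
        raise ValueError("all regions dropped by preprocessing")
    return RegionFeatureMatrix(values[keep].copy(), matrix.depths[keep].copy())


def region_stats(
    case_values: np.ndarray,
    control_values: np.ndarray,
    specificity: float = 0.80,
    region_id: str = "",
    direction: str = "auto",
) -> RegionStats | None:
    """Effect statistics for one region at a fixed specificity.

    The cutoff is the ceil(spec * n_controls)-th order statistic of the
    controls in the favorable direction; cases strictly beyond it count
    toward sensitivity.  ``direction`` is normally chosen by the sign of
    delta ("auto"); note that this adaptive choice biases null sensitivity
    slightly above 1 - specificity, while a fixed "up"/"down" direction is
    exactly exchangeable.  P from the two-sided Wilcoxon rank-sum test.
    Returns None when either group lacks >= 2 observed values.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if len(case) < 2 or len(ctrl) < 2:
        return None
    delta = float(case.mean() - ctrl.mean())
    k = math.ceil(specificity * len(ctrl))
    srt = np.sort(ctrl)
    up = delta >= 0 if direction == "auto" else direction == "up"
    if up:
        cutoff = srt[k - 1]  # k-th smallest: spec fraction of controls <= cutoff
        sens = float(np.mean(case > cutoff))
    else:
        cutoff = srt[len(ctrl) - k]  # k-th largest
        sens = float(np.mean(case < cutoff))
    p = float(stats.mannwhitneyu(case, ctrl, alternative="two-sided").pvalue)
    return RegionStats(region_id, delta, sens, p)


def matrix_region_stats(
    matrix: RegionFeatureMatrix,
    case_ids: list[str],
    control_ids: list[str],
    specificity: float = 0.80,
) -> list[RegionStats]:
    case = matrix.values.loc[case_ids]
    ctrl = matrix.values.loc[control_ids]
    out = []
    for rid in matrix.region_ids:
        st = region_stats(
            case[rid].to_numpy(), ctrl[rid].to_numpy(), specificity, rid
        )
        if st is not None:
            out.append(st)
    return out


def select_binary_features(
    stats_list: list[RegionStats], cfg: SelectionConfig
) -> list[str]:
    """Conjunction of the |delta|, sensitivity and P thresholds."""
    kept = [
        s.region_id
        for s in stats_list
        if abs(s.delta) >= cfg.min_abs_delta
        and s.sensitivity_at_spec >= cfg.min_sensitivity
        and s.p_value < cfg.max_p
    ]
    if not kept:
        warnings.warn("no regions pass the binary thresholds")
    return kept


def _impute_median(x: pd.DataFrame) -> pd.DataFrame:
    med = x.median(axis=0)
    return x.fillna(med.fillna(0.0))


def importance_filter(
    matrix: RegionFeatureMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    threshold: float,
    seed: int = 0,
    n_estimators: int = 500,
) -> tuple[list[str], pd.Series]:
    """Keep candidates whose impurity-based forest importance > threshold.

    Returns (kept region ids, per-region importances); the forest seed makes
    the selection reproducible.
    """
    x = matrix.values if isinstance(matrix, RegionFeatureMatrix) else matrix
    x = _impute_median(x)
    y = np.asarray(labels)
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    ).fit(x.to_numpy(), y)
    imp = pd.Series(rf.feature_importances_, index=x.columns)
    return list(imp.index[imp > threshold]), imp


def boruta_select(
    matrix: RegionFeatureMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    max_iter: int = 25,
    seed: int = 0,
    alpha: float = 0.01,
    n_estimators: int = 100,
) -> tuple[list[str], pd.Series]:
    """Boruta all-relevant selection via shadow features.

    Each iteration appends a column-permuted copy of every feature, fits a
    forest, and scores a 'hit' for features beating the best shadow
    importance.  Features whose hit counts are significantly above (below)
    chance under a two-sided binomial test at ``alpha`` with Bonferroni
    correction are confirmed (rejected); undecided features after
    ``max_iter`` iterations stay tentative and are excluded.

    Returns (confirmed ids, mean importance over iterations) — the mean
    importance is the ranking statistic used for top-k truncation.
    """
    x = matrix.values if isinstance(matrix, RegionFeatureMatrix) else matrix
    x = _impute_median(x)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    features = list(x.columns)
    active = list(range(len(features)))
    hits = np.zeros(len(features), dtype=int)
    trials = np.zeros(len(features), dtype=int)
    imp_sum = np.zeros(len(features))
    imp_cnt = np.zeros(len(features), dtype=int)
    confirmed: set[int] = set()
    rejected: set[int] = set()
    xv = x.to_numpy()

    for it in range(max_iter):
        undecided = [i for i in active if i not in confirmed and i not in rejected]
        if not undecided:
            break
        cols = sorted(confirmed | set(undecided))
        xa = xv[:, cols]
        shadow = xa.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        xfull = np.hstack([xa, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(xfull, y)
        imp = rf.feature_importances_
        real_imp = imp[: xa.shape[1]]
        best_shadow = imp[xa.shape[1]:].max() if shadow.shape[1] else 0.0
        for local_j, i in enumerate(cols):
            imp_sum[i] += real_imp[local_j]
            imp_cnt[i] += 1
            if i in undecided:
                trials[i] += 1
                if real_imp[local_j] > best_shadow:
                    hits[i] += 1
        # binomial decision, Bonferroni over currently undecided features
        m = max(len(undecided), 1)
        for i in undecided:
            res = stats.binomtest(int(hits[i]), int(trials[i]), 0.5)
            if res.pvalue * m < alpha:
                if hits[i] > trials[i] / 2:
                    confirmed.add(i)
                else:
                    rejected.add(i)

    mean_imp = pd.Series(
        np.divide(imp_sum, np.maximum(imp_cnt, 1)), index=features
    )
    kept = [features[i] for i in sorted(confirmed)]
    return kept, mean_imp


def kw_dunn_select(
    matrix: RegionFeatureMatrix | pd.DataFrame,
    cancer_type_labels: pd.Series,
    q: float = 0.05,
    top_k: int = 30,
    seed: int = 0,
    dunn_alpha: float = 0.05,
    boruta_max_iter: int = 20,
) -> dict[str, list[str]]:
    """Three-stage per-type marker discovery on cancer samples.

    Stage 1: Kruskal-Wallis across the cancer types with BH-FDR at ``q``.
    Stage 2: Dunn's pairwise rank z-tests; a region is attributed to a type
    when that type separates from every other type at ``dunn_alpha``.
    Stage 3: per-type Boruta; candidates ranked by mean importance and
    truncated to ``top_k`` per type.
    """
    x = matrix.values if isinstance(matrix, RegionFeatureMatrix) else matrix
    y = pd.Series(cancer_type_labels, index=x.index).astype(str)
    types = sorted(y.unique())
    counts = y.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValueError(f"cancer type {bad!r} has fewer than 2 samples")

    # stage 1: KW + BH
    pvals = {}
    for rid in x.columns:
        groups = [x.loc[y == t, rid].dropna().to_numpy() for t in types]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        try:
            pvals[rid] = stats.kruskal(*groups).pvalue
        except ValueError:  # all values identical
            continue
    if not pvals:
        return {t: [] for t in types}
    rids = list(pvals)
    rej, _, _, _ = multipletests(
        [pvals[r] for r in rids], alpha=q, method="fdr_bh"
    )
    candidates = [r for r, keep in zip(rids, rej) if keep]

    # stage 2: Dunn's post-hoc, one-vs-each-other-type separation
    per_type: dict[str, list[str]] = {t: [] for t in types}
    for rid in candidates:
        vals = x[rid]
        obs = vals.dropna()
        z = _dunn_z_matrix(obs.to_numpy(), y.loc[obs.index], types)
        crit = stats.norm.isf(dunn_alpha / 2)
        for ti, t in enumerate(types):
            if all(
                abs(z[ti, tj]) >= crit for tj in range(len(types)) if tj != ti
            ):
                per_type[t].append(rid)

    # stage 3: per-type Boruta ranking, top_k
    out: dict[str, list[str]] = {}
    for ti, t in enumerate(types):
        cand = per_type[t]
        if not cand:
            out[t] = []
            continue
        confirmed, mean_imp = boruta_select(
            x[cand], (y == t).astype(int), max_iter=boruta_max_iter,
            seed=seed + ti,
        )
        ranked = mean_imp.loc[confirmed].sort_values(ascending=False)
        out[t] = list(ranked.index[:top_k])
    return out


def _dunn_z_matrix(
    values: np.ndarray, group: pd.Series, types: list[str]
) -> np.ndarray:
    """Pairwise Dunn z statistics (rank sums with tie correction)."""
    ranks = stats.rankdata(values)
    n = len(values)
    mean_rank = {}
    sizes = {}
    g = np.asarray(group)
    for t in types:
        sel = g == t
        sizes[t] = int(sel.sum())
        mean_rank[t] = ranks[sel].mean() if sizes[t] else np.nan
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    z = np.zeros((len(types), len(types)))
    for i, ti in enumerate(types):
        for j, tj in enumerate(types):
            if i == j or sizes[ti] == 0 or sizes[tj] == 0:
                continue
            se = math.sqrt(base_var * (1 / sizes[ti] + 1 / sizes[tj]))
            z[i, j] = (mean_rank[ti] - mean_rank[tj]) / se if se > 0 else 0.0
    return z


def one_vs_rest_markers(
    matrix: RegionFeatureMatrix,
    cancer_type_labels: pd.Series,
    cfg: SelectionConfig | None = None,
    seed: int = 0,
    boruta_max_iter: int = 20,
) -> tuple[list[str], dict[str, list[str]]]:
    """Entropy-modality tissue-of-origin markers.

    For each type, a one-vs-rest binary screen at the configured specificity
    and thresholds; the union of per-type hits is refined with Boruta
    against the multiclass labels.
    """
    cfg = cfg or SelectionConfig()
    y = pd.Series(cancer_type_labels, index=matrix.values.index).astype(str)
    per_type: dict[str, list[str]] = {}
    for t in sorted(y.unique()):
        case_ids = list(y.index[y == t])
        ctrl_ids = list(y.index[y != t])
        sts = matrix_region_stats(matrix, case_ids, ctrl_ids, cfg.specificity)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_type[t] = select_binary_features(sts, cfg)
    combined = sorted(set().union(*per_type.values())) if per_type else []
    if not combined:
        return [], per_type
    confirmed, _ = boruta_select(
        matrix.values[combined], y, max_iter=boruta_max_iter, seed=seed
    )
    return confirmed, per_type
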