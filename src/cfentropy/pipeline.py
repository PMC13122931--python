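"""End-to-end orchestration: matrices -> selection -> models -> reports.

Train/test separation is enforced here: region preprocessing (NA-fraction
region drop), feature selection, PCA fitting, imputation and model fitting
see training rows only; the test split is scored with the frozen bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cfentropy import entropy as entropy_mod
from cfentropy import fragmentation as frag_mod
from cfentropy import models as models_mod
from cfentropy import selection as sel_mod
from cfentropy import ura as ura_mod
from cfentropy.io import RegionFeatureMatrix, write_matrix
from cfentropy.synthetic import TOY_CHROM_SIZES, Cohort


@dataclass
class StudyResult:
    """Everything a full run produces, in memory."""

    selected: dict[str, list[str]]
    bundles: dict[str, object]
    emced: models_mod.EMCEDModel
    scores_test: pd.DataFrame  # per-modality + fused scores on test rows
    reports: dict[str, models_mod.EvalReport]
    too_report: models_mod.TOOReport | None
    too_probs: pd.DataFrame | None
    matrices: dict[str, RegionFeatureMatrix] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)


def _preprocess_train_aware(
    matrix: RegionFeatureMatrix, train_ids: list[str], cfg: sel_mod.SelectionConfig
) -> RegionFeatureMatrix:
    """Depth-mask all cells; choose dropped regions from training rows only."""
    masked = RegionFeatureMatrix(
        matrix.values.mask(matrix.depths < cfg.min_depth),
        matrix.depths.copy(),
    )
    train_na = masked.values.loc[train_ids].isna().mean(axis=0)
    keep = list(train_na.index[train_na <= cfg.max_na_fraction])
    if not keep:
        raise ValueError("all regions dropped by preprocessing")
    return RegionFeatureMatrix(
        masked.values[keep].copy(), masked.depths[keep].copy()
    )


def run_study(
    cohort: Cohort,
    seed: int = 0,
    run_too: bool = True,
    chrom_sizes: dict[str, int] | None = None,
) -> StudyResult:
    """Run the complete classification study on one cohort."""
    labels = cohort.labels.table
    train = labels[labels["split"] == "train"]
    test = labels[labels["split"] == "test"]
    train_ids = list(train["sample_id"])
    test_ids = list(test["sample_id"])
    all_ids = list(labels["sample_id"])
    y_train = (train["group"] == "cancer").astype(int).to_numpy()
    y_test = (test["group"] == "cancer").astype(int).to_numpy()

    # --- modality matrices
    e_mat = entropy_mod.entropy_matrix(cohort.epireads, cohort.regions, all_ids)
    m_mat = ura_mod.ura_matrix(cohort.epireads, cohort.regions, all_ids)

    e_cfg = sel_mod.SelectionConfig.for_modality("entropy", rng_seed=seed)
    m_cfg = sel_mod.SelectionConfig.for_modality("ura", rng_seed=seed)
    e_mat = _preprocess_train_aware(e_mat, train_ids, e_cfg)
    m_mat = _preprocess_train_aware(m_mat, train_ids, m_cfg)

    # --- binary feature selection on the training split
    case_ids = list(train.loc[train["group"] == "cancer", "sample_id"])
    ctrl_ids = list(train.loc[train["group"] == "non_cancer", "sample_id"])
    selected: dict[str, list[str]] = {}
    for name, mat, cfg in (("entropy", e_mat, e_cfg), ("methylation", m_mat, m_cfg)):
        stats = sel_mod.matrix_region_stats(mat, case_ids, ctrl_ids, cfg.specificity)
        cand = sel_mod.select_binary_features(stats, cfg)
        if cand:
            kept, _ = sel_mod.importance_filter(
                mat.values.loc[train_ids, cand], y_train,
                cfg.importance_threshold, seed=seed,
            )
            selected[name] = kept or cand  # fall back to pre-forest candidates
        else:
            selected[name] = []

    # --- fragmentation profiles and PCA (train-fitted)
    sizes = chrom_sizes or TOY_CHROM_SIZES
    bins = frag_mod.make_bins(sizes)
    frags = cohort.fragments
    train_frags = frags[frags["sample_id"].isin(train_ids)]
    cov = _bin_coverage(train_frags, bins)
    bins = frag_mod.filter_bins(bins, cov)
    profiles = frag_mod.coverage_profile(frags, bins, samples=all_ids)
    pcs = frag_mod.pca_features(profiles.loc[train_ids])
    pc_train = pcs.train_scores
    pc_test = pcs.transform(profiles.loc[test_ids])

    # --- binary models + EMCED fusion
    blocks_train = {
        "entropy": (e_mat.values.loc[train_ids, selected["entropy"]], "logistic"),
        "methylation": (
            m_mat.values.loc[train_ids, selected["methylation"]], "logistic"
        ),
        "fragmentation": (pc_train, "elastic_net"),
    }
    blocks_train = {k: v for k, v in blocks_train.items() if v[0].shape[1] > 0}
    emced = models_mod.fit_emced(blocks_train, y_train, seed=seed)

    blocks_test = {
        "entropy": e_mat.values.loc[test_ids, selected["entropy"]],
        "methylation": m_mat.values.loc[test_ids, selected["methylation"]],
        "fragmentation": pc_test,
    }
    blocks_test = {k: blocks_test[k] for k in emced.sub_bundles}
    scores = {
        name: models_mod.predict_score(b, blocks_test[name])
        for name, b in emced.sub_bundles.items()
    }
    scores["fused"] = emced.predict(blocks_test)
    scores_test = pd.DataFrame(scores)

    reports = {}
    for name, s in scores_test.items():
        thr = (
            emced.fusion.threshold
            if name == "fused"
            else emced.sub_bundles[name].threshold
        )
        reports[name] = models_mod.evaluate(s, y_test, thr)

    # --- tissue of origin (cancer samples only)
    too_report = None
    too_probs = None
    if run_too:
        tr_cancer = train[train["group"] == "cancer"]
        te_cancer = test[test["group"] == "cancer"]
        tr_ids = list(tr_cancer["sample_id"])
        te_ids = list(te_cancer["sample_id"])
        ytr = tr_cancer.set_index("sample_id")["cancer_type"]
        sex_tr = tr_cancer.set_index("sample_id")["sex"]
        sex_te = te_cancer.set_index("sample_id")["sex"]

        e_markers, _ = sel_mod.one_vs_rest_markers(
            e_mat.subset_samples(tr_ids), ytr, e_cfg, seed=seed
        )
        per_type = sel_mod.kw_dunn_select(
            m_mat.subset_samples(tr_ids), ytr, seed=seed
        )
        m_markers = sorted(set().union(*per_type.values()))

        bundles = {}
        te_blocks = {}
        if e_markers:
            bundles["entropy"] = models_mod.train_too(
                e_mat.values.loc[tr_ids, e_markers], ytr, sex=sex_tr,
                modality="entropy", kind="logistic", seed=seed,
            )
            te_blocks["entropy"] = e_mat.values.loc[te_ids, e_markers]
        if m_markers:
            bundles["methylation"] = models_mod.train_too(
                m_mat.values.loc[tr_ids, m_markers], ytr, sex=sex_tr,
                modality="methylation", kind="elastic_net", seed=seed,
            )
            te_blocks["methylation"] = m_mat.values.loc[te_ids, m_markers]
        bundles["fragmentation"] = models_mod.train_too(
            pc_train.loc[tr_ids], ytr, sex=sex_tr,
            modality="fragmentation", kind="elastic_net", seed=seed,
        )
        te_blocks["fragmentation"] = pcs.transform(profiles.loc[te_ids])

        too_probs = models_mod.predict_too(
            bundles, te_blocks, sex=sex_te, fusion="e_m_f"
        )
        too_report = models_mod.evaluate_too(
            too_probs, te_cancer.set_index("sample_id")["cancer_type"]
        )
        selected["too_entropy"] = e_markers
        selected["too_methylation"] = m_markers

    return StudyResult(
        selected=selected,
        bundles=dict(emced.sub_bundles),
        emced=emced,
        scores_test=scores_test,
        reports=reports,
        too_report=too_report,
        too_probs=too_probs,
        matrices={"entropy": e_mat, "methylation": m_mat},
        seeds={"study": seed},
    )


def _bin_coverage(frags: pd.DataFrame, bins: frag_mod.GenomeBins) -> np.ndarray:
    """Fragment-midpoint counts per 100 kb bin (reference coverage for the
    low-coverage filter)."""
    t = bins.table
    cov = np.zeros(len(t))
    mids = (frags["start"] + frags["end"]) // 2
    for chrom, grp in frags.groupby("chrom"):
        sel = t["chrom"] == chrom
        if not sel.any():
            continue
        starts = t.loc[sel, "start"].to_numpy()
        idx = np.searchsorted(starts, mids[grp.index].to_numpy(), side="right") - 1
        idx = idx[(idx >= 0) & (idx < sel.sum())]
        counts = np.bincount(idx, minlength=int(sel.sum()))
        cov[np.flatnonzero(sel)] += counts
    return cov


def run_pipeline(cohort: Cohort, outdir: str | Path, seed: int = 0,
                 run_too: bool = True) -> StudyResult:
    """Run the study and write matrices, reports and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_study(cohort, seed=seed, run_too=run_too)
    write_matrix(result.matrices["entropy"], outdir / "entropy_matrix.tsv")
    write_matrix(result.matrices["methylation"], outdir / "ura_matrix.tsv")
    report_payload = {
        "binary": {k: v.to_dict() for k, v in result.reports.items()},
        "too": result.too_report.to_dict() if result.too_report else None,
        "selected_features": result.selected,
    }
    (outdir / "report.json").write_text(json.dumps(report_payload, indent=2))
    manifest = {
        "seeds": result.seeds,
        "outputs": {},
    }
    for f in sorted(outdir.glob("*.tsv")) + [outdir / "report.json"]:
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
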