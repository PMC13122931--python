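"""Fragment-length coverage profiles over genomic bins, DELFI-style.

Autosomes are tiled with non-overlapping 100 kb bins; bins overlapping a
blacklist and the 10% of remaining bins with the lowest reference coverage
are dropped; survivors are aggregated into 1 Mb bins.  Fragments are
classed by length — short [100,150), middle [150,260), long [260,320] bp —
and each classed fragment increments exactly one 1 Mb bin (by midpoint).
nfrags is the per-bin sum of the three class coverages.  The per-sample
feature vector (4 values per 1 Mb bin) feeds a PCA whose retained component
count is the smallest with cumulative explained variance >= 98%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

BIN_WIDTH = 100_000
MERGE_WIDTH = 1_000_000
SHORT_RANGE = (100, 150)
MIDDLE_RANGE = (150, 260)
LONG_RANGE = (260, 320)  # upper end closed
DROP_FRACTION = 0.10
LENGTH_CLASSES = ("short", "middle", "long")

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


@dataclass
class GenomeBins:
    """Fixed-width bin tiling with retention flags and the 1 Mb merge."""

    table: pd.DataFrame  # chrom, start, end, retained, mbin_id
    width: int = BIN_WIDTH

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    @property
    def merged_ids(self) -> list[str]:
        return sorted(self.retained["mbin_id"].unique())


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOMES


def make_bins(chrom_sizes: dict[str, int], width: int = BIN_WIDTH) -> GenomeBins:
    """Tile autosomes with adjacent non-overlapping bins.

    Sex chromosomes and unplaced contigs are excluded; a final partial bin
    is kept at reduced width.  Unrecognized autosome-like names error.
    """
    rows = []
    for chrom in sorted(chrom_sizes):
        if not _known_chrom(chrom):
            raise ValueError(f"unknown chromosome name {chrom!r}")
        if not is_autosome(chrom):
            continue
        size = int(chrom_sizes[chrom])
        for start in range(0, size, width):
            end = min(start + width, size)
            mbin = (start // MERGE_WIDTH) * MERGE_WIDTH
            rows.append((chrom, start, end, True, f"{chrom}:{mbin}"))
    if not rows:
        raise ValueError("no autosomes in chrom_sizes")
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "retained", "mbin_id"])
    return GenomeBins(table, width)


def _known_chrom(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return 1 <= int(c) <= 22
    return c in {"X", "Y", "M", "MT"} or c.startswith(("A", "B", "toy"))


def filter_bins(
    bins: GenomeBins,
    coverage: Sequence[float],
    blacklist: Sequence[tuple[str, int, int]] = (),
    drop_fraction: float = DROP_FRACTION,
) -> GenomeBins:
    """Drop blacklist-overlapping bins, then the lowest-coverage fraction.

    ``coverage`` is per-bin reference coverage aligned with ``bins.table``.
    Coverage ties break by genomic order (earlier bins dropped first).
    """
    t = bins.table.copy()
    cov = np.asarray(coverage, dtype=float)
    if len(cov) != len(t):
        raise ValueError("coverage length != bin count")
    keep = t["retained"].to_numpy().copy()
    for bl_chrom, bl_start, bl_end in blacklist:
        hit = (
            (t["chrom"] == bl_chrom)
            & (t["start"] < bl_end)
            & (t["end"] > bl_start)
        ).to_numpy()
        keep &= ~hit
    idx = np.flatnonzero(keep)
    n_drop = int(np.floor(drop_fraction * len(idx)))
    if n_drop > 0:
        # stable sort: genomic order breaks coverage ties, earliest dropped
        order = idx[np.argsort(cov[idx], kind="stable")]
        keep[order[:n_drop]] = False
    t["retained"] = keep
    return GenomeBins(t, bins.width)


def length_class(length: int) -> str | None:
    """Map fragment length to short/middle/long; None outside [100, 320]."""
    if length <= 0:
        raise ValueError(f"non-positive fragment length {length}")
    if SHORT_RANGE[0] <= length < SHORT_RANGE[1]:
        return "short"
    if MIDDLE_RANGE[0] <= length < MIDDLE_RANGE[1]:
        return "middle"
    if LONG_RANGE[0] <= length <= LONG_RANGE[1]:
        return "long"
    return None


def coverage_profile(
    fragments: pd.DataFrame,
    bins: GenomeBins,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample class coverages and nfrags per retained 1 Mb bin.

    ``fragments`` needs columns chrom, start, end, sample_id (length derived
    if absent).  Returns a wide frame indexed by sample with columns
    ``<mbin>|short``, ``<mbin>|middle``, ``<mbin>|long``, ``<mbin>|nfrags``.
    """
    df = fragments.copy()
    if "length" not in df.columns:
        df["length"] = df["end"] - df["start"]
    if (df["length"] <= 0).any():
        raise ValueError("non-positive fragment length")

    length = df["length"].to_numpy()
    klass = np.select(
        [
            (length >= SHORT_RANGE[0]) & (length < SHORT_RANGE[1]),
            (length >= MIDDLE_RANGE[0]) & (length < MIDDLE_RANGE[1]),
            (length >= LONG_RANGE[0]) & (length <= LONG_RANGE[1]),
        ],
        LENGTH_CLASSES,
        default="none",
    )
    df["klass"] = klass
    df = df[df["klass"] != "none"].copy()
    df["mid"] = (df["start"].to_numpy() + df["end"].to_numpy()) // 2

    retained = bins.retained
    n_unknown = 0
    parts = []
    for chrom, chrom_frags in df.groupby("chrom", sort=False):
        cb = retained[retained["chrom"] == chrom]
        if cb.empty:
            n_unknown += len(chrom_frags)
            continue
        starts = cb["start"].to_numpy()
        ends = cb["end"].to_numpy()
        mbins = cb["mbin_id"].to_numpy()
        pos = chrom_frags["mid"].to_numpy()
        i = np.searchsorted(starts, pos, side="right") - 1
        inside = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
        sub = chrom_frags[inside].copy()
        sub["mbin_id"] = mbins[i[inside]]
        parts.append(sub[["sample_id", "mbin_id", "klass"]])
        n_unknown += int((~inside).sum())
    if n_unknown:
        warnings.warn(f"{n_unknown} classed fragments fell outside retained bins")

    mbin_ids = bins.merged_ids
    if samples is None:
        samples = sorted(df["sample_id"].unique())
    columns = [f"{m}|{c}" for m in mbin_ids for c in (*LENGTH_CLASSES, "nfrags")]
    if not parts:
        return pd.DataFrame(0, index=list(samples), columns=columns)
    allf = pd.concat(parts, ignore_index=True)
    counts = (
        allf.groupby(["sample_id", "mbin_id", "klass"], observed=True)
        .size()
        .unstack("klass", fill_value=0)
        .reindex(columns=list(LENGTH_CLASSES), fill_value=0)
    )
    counts["nfrags"] = counts.sum(axis=1)
    wide = counts.unstack("mbin_id")
    wide.columns = [f"{m}|{c}" for c, m in wide.columns]
    wide = wide.reindex(index=list(samples), columns=columns).fillna(0).astype(int)
    wide.index.name = "sample_id"
    return wide


@dataclass
class PCFeatures:
    """Fitted PCA projection over fragmentation features."""

    scaler: StandardScaler
    pca: PCA
    n_components: int
    feature_ids: list[str]
    train_scores: pd.DataFrame = field(repr=False)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_[: self.n_components]

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        x = profiles.reindex(columns=self.feature_ids).to_numpy(dtype=float)
        z = self.pca.transform(self.scaler.transform(x))[:, : self.n_components]
        return pd.DataFrame(
            z,
            index=profiles.index,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


def pca_features(profiles: pd.DataFrame, var_frac: float = 0.98) -> PCFeatures:
    """Fit scaler+PCA on training profiles; keep the smallest PC count whose
    cumulative explained variance reaches ``var_frac``."""
    if len(profiles) < 2:
        raise ValueError("PCA needs at least 2 training samples")
    variances = profiles.var(axis=0)
    nonzero = variances[variances > 0].index
    if len(nonzero) < len(profiles.columns):
        warnings.warn(
            f"dropping {len(profiles.columns) - len(nonzero)} zero-variance features"
        )
    if len(nonzero) == 0:
        raise ValueError("all features have zero variance (identical samples)")
    x = profiles[nonzero].to_numpy(dtype=float)
    scaler = StandardScaler().fit(x)
    pca = PCA(svd_solver="full").fit(scaler.transform(x))
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    n_components = min(n_components, len(cum))
    feats = PCFeatures(
        scaler=scaler,
        pca=pca,
        n_components=n_components,
        feature_ids=list(nonzero),
        train_scores=None,  # type: ignore[arg-type]
    )
    feats.train_scores = feats.transform(profiles)
    return feats
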