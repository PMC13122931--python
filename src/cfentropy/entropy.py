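"""Fragment-level methylation entropy (BiEntropy) and region averages.

A fragment's ordered CpG calls form a binary string s (1 = methylated).
Its disorder is scored with the BiEntropy of s:

    BiEn(s) = 1/(2^(n-1) - 1) * sum_{k=0}^{n-2} H(p(k)) * 2^k

where the k-th binary derivative is the elementwise XOR of adjacent bits of
the (k-1)-th derivative (k = 0 is s itself), p(k) is the proportion of ones
in that derivative, and H is the binary Shannon entropy with 0*log0 = 0.
Weighting by 2^k emphasises the deepest derivatives, so periodic strings
(e.g. 1010) score low while irregular ones score high; constant strings
score exactly 0 and all scores lie in [0, 1].

The per-region statistic is the arithmetic mean of fragment entropies:
Entropy value = (e1 + ... + eN) / N.  Fragments qualify when they carry
3..32 CpG calls after trimming leading/trailing missing calls, with no
missing call in the interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cfentropy.io import (
    MISSING_CALL,
    ReadPattern,
    RegionFeatureMatrix,
    patterns_to_frame,
)
from cfentropy.methbin import MethBinRegion, RegionIndex

MIN_CPG_PER_FRAGMENT = 3
MAX_CPG_PER_FRAGMENT = 32


@dataclass(frozen=True)
class MethPattern:
    """A gap-free binary methylation pattern (1 = methylated)."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) < 2:
            raise ValueError("BiEn requires at least 2 CpG sites")
        if not set(self.bits) <= {0, 1}:
            raise ValueError("bits must be 0/1")

    @property
    def n(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class RegionEntropy:
    region_id: str
    sample_id: str
    fragment_entropies: tuple[float, ...]
    value: float

    @property
    def N(self) -> int:
        return len(self.fragment_entropies)


def binary_derivative(bits: Sequence[int]) -> tuple[int, ...]:
    """XOR of adjacent bits; length n-1."""
    if len(bits) < 2:
        raise ValueError("binary derivative needs at least 2 bits")
    return tuple(a ^ b for a, b in zip(bits, bits[1:]))


def _h(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p)


def bien(pattern: MethPattern | Sequence[int] | str) -> float:
    """BiEntropy of one binary methylation pattern, in [0, 1]."""
    if isinstance(pattern, str):
        pattern = MethPattern(tuple(int(c) for c in pattern))
    elif not isinstance(pattern, MethPattern):
        pattern = MethPattern(tuple(int(b) for b in pattern))
    bits = pattern.bits
    n = pattern.n
    acc = 0.0
    for k in range(n - 1):
        p = sum(bits) / len(bits)
        acc += _h(p) * (2.0**k)
        if k < n - 2:
            bits = binary_derivative(bits)
    return acc / (2.0 ** (n - 1) - 1.0)


def bien_array(bits: np.ndarray) -> np.ndarray:
    """Vectorized BiEn over a (reads x n) 0/1 matrix; one value per row."""
    b = np.asarray(bits, dtype=np.uint8)
    if b.ndim != 2 or b.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 columns")
    n = b.shape[1]
    acc = np.zeros(b.shape[0])
    for k in range(n - 1):
        p = b.mean(axis=1)
        h = np.zeros_like(p)
        inner = (p > 0) & (p < 1)
        pi = p[inner]
        h[inner] = -pi * np.log2(pi) - (1 - pi) * np.log2(1 - pi)
        acc += h * (2.0**k)
        if k < n - 2:
            b = b[:, 1:] ^ b[:, :-1]
    return acc / (2.0 ** (n - 1) - 1.0)


def fragment_filter(
    read: ReadPattern, region: MethBinRegion | None = None
) -> tuple[bool, MethPattern | None, str]:
    """Qualify one read for entropy: trim edge-missing calls, reject interior
    gaps and CpG counts outside 3..32.

    When ``region`` is given, only calls at CpGs inside the region count.
    Returns (keep, pattern-or-None, reason).
    """
    calls = read.calls
    if region is not None:
        calls = "".join(
            c
            for c, p in zip(read.calls, read.cpg_positions)
            if region.start <= p < region.end
        )
    trimmed = calls.strip(MISSING_CALL)
    if MISSING_CALL in trimmed:
        return False, None, "internal_missing"
    n = len(trimmed)
    if n < MIN_CPG_PER_FRAGMENT:
        return False, None, "too_few_cpgs"
    if n > MAX_CPG_PER_FRAGMENT:
        return False, None, "too_many_cpgs"
    return True, MethPattern(tuple(1 if c == "M" else 0 for c in trimmed)), "ok"


def region_entropy(
    fragments: Iterable[MethPattern | Sequence[int] | str],
    region_id: str = "",
    sample_id: str = "",
) -> RegionEntropy | None:
    """Mean BiEn over a region's qualified fragments; None when N == 0."""
    es = tuple(bien(f) for f in fragments)
    if not es:
        return None
    return RegionEntropy(region_id, sample_id, es, float(np.mean(es)))


# ---------------------------------------------------------------------------
# matrix construction


def _calls_to_frame(
    reads: Iterable[ReadPattern] | pd.DataFrame,
    regions: Sequence[MethBinRegion],
) -> pd.DataFrame:
    """Normalize the read stream to a DataFrame with an assigned region_id
    column and region-restricted call strings."""
    if not isinstance(reads, pd.DataFrame):
        reads = patterns_to_frame(reads)
    if reads.empty:
        return reads.assign(region_id=pd.Series(dtype=str))
    index = RegionIndex(list(regions))
    df = reads.copy()

    # assignment depends only on (chrom, cpg_positions); dedupe before voting
    keys = df[["chrom", "cpg_positions"]].drop_duplicates()
    assign_rows = []
    partial: dict[tuple[str, str], np.ndarray] = {}
    for row in keys.itertuples(index=False):
        pos = np.array(row.cpg_positions.split(","), dtype=np.int64)
        rid = _assign_positions(row.chrom, pos, index)
        assign_rows.append((row.chrom, row.cpg_positions, rid))
        if rid is not None:
            region = index.regions[rid]
            inside = (pos >= region.start) & (pos < region.end)
            if not inside.all():  # cross-region read: keep in-region calls only
                partial[(row.chrom, row.cpg_positions)] = inside
    key_df = pd.DataFrame(
        assign_rows, columns=["chrom", "cpg_positions", "region_id"]
    )
    df = df.merge(key_df, on=["chrom", "cpg_positions"], how="left")
    df = df[df["region_id"].notna()].copy()
    if df.empty or not partial:
        return df
    hit = pd.MultiIndex.from_frame(df[["chrom", "cpg_positions"]]).isin(partial)
    fixed = [
        "".join(np.array(list(calls))[partial[(c, p)]])
        for calls, c, p in zip(
            df.loc[hit, "calls"], df.loc[hit, "chrom"], df.loc[hit, "cpg_positions"]
        )
    ]
    df.loc[hit, "calls"] = fixed
    return df


def _assign_positions(chrom: str, pos: np.ndarray, index: RegionIndex) -> str | None:
    votes: dict[str, int] = {}
    order: dict[str, int] = {}
    for k, p in enumerate(pos):
        region = index.locate(chrom, int(p))
        if region is not None:
            votes[region.region_id] = votes.get(region.region_id, 0) + 1
            order.setdefault(region.region_id, k)
    if not votes:
        return None
    return max(votes.items(), key=lambda kv: (kv[1], -order[kv[0]]))[0]


def _grouped_bien(calls: pd.Series) -> np.ndarray:
    """BiEn per qualified call string; NaN marks disqualified reads.

    Expects a fresh RangeIndex on ``calls`` (positions == labels).
    """
    calls = calls.reset_index(drop=True)
    trimmed = calls.str.strip(MISSING_CALL)
    n = trimmed.str.len().to_numpy()
    clean = ~trimmed.str.contains(MISSING_CALL, regex=False)
    keep = clean & (n >= MIN_CPG_PER_FRAGMENT) & (n <= MAX_CPG_PER_FRAGMENT)
    out = np.full(len(calls), np.nan)
    kept = trimmed[keep]
    for length, group in kept.groupby(kept.str.len()):
        joined = "".join(group)
        bits = (
            np.frombuffer(joined.encode(), dtype=np.uint8).reshape(-1, length)
            == ord("M")
        ).astype(np.uint8)
        out[group.index.to_numpy()] = bien_array(bits)
    return out


def entropy_matrix(
    reads: Iterable[ReadPattern] | pd.DataFrame,
    regions: Sequence[MethBinRegion],
    samples: Sequence[str],
    known_samples: Sequence[str] | None = None,
) -> RegionFeatureMatrix:
    """Per-(sample, region) mean fragment entropy with effective depths.

    ``samples`` fixes row order; unobserved pairs are NA with depth 0.
    Samples present in reads but absent from ``samples`` are retained with a
    warning (appended after the listed rows).
    """
    df = _calls_to_frame(reads, regions)
    samples = list(samples)
    region_ids = [r.region_id for r in regions]
    if len(df):
        extra = sorted(set(df["sample_id"]) - set(samples))
        if extra:
            import warnings

            warnings.warn(f"samples not in label sheet retained: {extra}")
            samples = samples + extra
        df = df.reset_index(drop=True)
        e = _grouped_bien(df["calls"])
        ok = ~np.isnan(e)
        sub = pd.DataFrame(
            {
                "sample_id": df.loc[ok, "sample_id"].to_numpy(),
                "region_id": df.loc[ok, "region_id"].to_numpy(),
                "e": e[ok],
            }
        )
        agg = sub.groupby(["sample_id", "region_id"])["e"].agg(["mean", "size"])
        values = agg["mean"].unstack()
        depths = agg["size"].unstack()
    else:
        values = pd.DataFrame(dtype=float)
        depths = pd.DataFrame(dtype=float)
    values = values.reindex(index=samples, columns=region_ids)
    depths = depths.reindex(index=samples, columns=region_ids).fillna(0).astype(int)
    values.index.name = depths.index.name = "sample_id"
    return RegionFeatureMatrix(values, depths)
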