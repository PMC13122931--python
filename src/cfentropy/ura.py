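"""Read-level methylation fraction, U/M/X classification, U-reads abundance.

Each retained read (>= 4 observed CpG calls) gets u = C/(C+T), the fraction
of methylated calls.  Reads are U (mostly unmethylated) when u <= 1/4,
M (mostly methylated) when u >= 3/4, X (mixed) otherwise; both boundaries
are inclusive toward U/M.  Per region and sample, URA = U/(U+X+M), reported
only when the region carries at least 50 effective reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cfentropy.io import ReadPattern, RegionFeatureMatrix
from cfentropy.entropy import _calls_to_frame
from cfentropy.methbin import MethBinRegion

MIN_CPG_PER_READ = 4
MIN_EFFECTIVE_READS = 50
U_THRESHOLD = 0.25
M_THRESHOLD = 0.75


@dataclass(frozen=True)
class ReadMethylation:
    C: int
    T: int

    @property
    def u(self) -> float:
        return self.C / (self.C + self.T)

    @property
    def klass(self) -> str:
        u = self.u
        if u <= U_THRESHOLD:
            return "U"
        if u >= M_THRESHOLD:
            return "M"
        return "X"


@dataclass(frozen=True)
class RegionURA:
    region_id: str
    sample_id: str
    U: int
    X: int
    M: int

    @property
    def effective_reads(self) -> int:
        return self.U + self.X + self.M

    @property
    def ura(self) -> float | None:
        n = self.effective_reads
        if n < MIN_EFFECTIVE_READS:
            return None
        return self.U / n


def classify_read(read: ReadPattern) -> ReadMethylation | None:
    """u and U/M/X class from observed calls; None when fewer than 4 CpGs."""
    c = read.calls.count("M")
    t = read.calls.count("U")
    if c + t < MIN_CPG_PER_READ:
        return None
    return ReadMethylation(C=c, T=t)


def region_ura(
    reads: Iterable[ReadMethylation],
    region_id: str = "",
    sample_id: str = "",
) -> RegionURA:
    u = x = m = 0
    for r in reads:
        k = r.klass
        if k == "U":
            u += 1
        elif k == "M":
            m += 1
        else:
            x += 1
    return RegionURA(region_id, sample_id, U=u, X=x, M=m)


def ura_matrix(
    reads: Iterable[ReadPattern] | pd.DataFrame,
    regions: Sequence[MethBinRegion],
    samples: Sequence[str],
) -> RegionFeatureMatrix:
    """Per-(sample, region) URA with depths = U+X+M; NA below the read floor."""
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
        c = df["calls"].str.count("M").to_numpy()
        t = df["calls"].str.count("U").to_numpy()
        obs = c + t
        keep = obs >= MIN_CPG_PER_READ
        u = np.divide(c, obs, out=np.zeros_like(c, dtype=float), where=obs > 0)
        is_u = keep & (u <= U_THRESHOLD)
        sub = pd.DataFrame(
            {
                "sample_id": df.loc[keep, "sample_id"].to_numpy(),
                "region_id": df.loc[keep, "region_id"].to_numpy(),
                "is_u": is_u[keep],
            }
        )
        agg = sub.groupby(["sample_id", "region_id"])["is_u"].agg(["mean", "size"])
        values = agg["mean"].unstack()
        depths = agg["size"].unstack()
    else:
        values = pd.DataFrame(dtype=float)
        depths = pd.DataFrame(dtype=float)
    values = values.reindex(index=samples, columns=region_ids)
    depths = depths.reindex(index=samples, columns=region_ids).fillna(0).astype(int)
    values = values.mask(depths < MIN_EFFECTIVE_READS)
    values.index.name = depths.index.name = "sample_id"
    return RegionFeatureMatrix(values, depths)
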