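"""Genome partitioning into merged CpG-cluster regions and read assignment.

Regions are built by merging adjacent CpG clusters that lie less than
``merge_gap`` bp apart (strict inequality) and keeping only merged regions
with at least ``min_cpg`` CpG sites.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

from cfentropy.io import ReadPattern

DEFAULT_MERGE_GAP = 400
DEFAULT_MIN_CPG = 3

UNASSIGNED = None


@dataclass(frozen=True)
class MethBinRegion:
    """A merged CpG-cluster interval used as the feature unit."""

    region_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < 1:
            raise ValueError("region without CpG positions")
        if any(p < self.start or p >= self.end for p in self.cpg_positions):
            raise ValueError("CpG position outside [start, end)")


def build_segments(
    cpg_positions: dict[str, list[int]] | list[int],
    seed_regions: list[tuple[int, int]] | None = None,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_cpg: int = DEFAULT_MIN_CPG,
    chrom: str = "chr1",
) -> list[MethBinRegion]:
    """Partition CpG positions into disjoint merged regions.

    ``cpg_positions`` may be a per-chromosome dict or a single sorted list
    (then ``chrom`` names its chromosome).  When ``seed_regions`` is given
    (single-chromosome mode only), those intervals seed the merge; otherwise
    maximal runs of CpGs spaced < ``merge_gap`` seed it — the two routes are
    equivalent single-pass clustering under the merge rule.
    """
    if isinstance(cpg_positions, dict):
        if seed_regions is not None:
            raise ValueError("seed_regions only supported in single-chromosome mode")
        out: list[MethBinRegion] = []
        for chrom_name in sorted(cpg_positions):
            out.extend(
                build_segments(
                    cpg_positions[chrom_name],
                    merge_gap=merge_gap,
                    min_cpg=min_cpg,
                    chrom=chrom_name,
                )
            )
        return out

    pos = list(cpg_positions)
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("cpg_positions must be sorted and unique")

    if seed_regions is None:
        intervals = [(p, p + 1) for p in pos]
    else:
        intervals = sorted((int(s), int(e)) for s, e in seed_regions)
        if any(e <= s for s, e in intervals):
            raise ValueError("empty seed interval")

    # exhaustive merge: neighbors closer than merge_gap (end-to-start, strict)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    regions = []
    for s, e in merged:
        lo = bisect.bisect_left(pos, s)
        hi = bisect.bisect_left(pos, e)
        cpgs = tuple(pos[lo:hi])
        if len(cpgs) < min_cpg:
            continue
        regions.append(
            MethBinRegion(
                region_id=f"{chrom}:{s}-{e}",
                chrom=chrom,
                start=s,
                end=e,
                cpg_positions=cpgs,
            )
        )
    return regions


class RegionIndex:
    """Per-chromosome sorted interval index for read-to-region assignment."""

    def __init__(self, regions: list[MethBinRegion]):
        self.by_chrom: dict[str, tuple[list[int], list[int], list[MethBinRegion]]] = {}
        for chrom in {r.chrom for r in regions}:
            rs = sorted(
                (r for r in regions if r.chrom == chrom), key=lambda r: r.start
            )
            for a, b in zip(rs, rs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping regions on {chrom}")
            self.by_chrom[chrom] = ([r.start for r in rs], [r.end for r in rs], rs)
        self.regions = {r.region_id: r for r in regions}

    def locate(self, chrom: str, position: int) -> MethBinRegion | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, rs = entry
        i = bisect.bisect_right(starts, position) - 1
        if i >= 0 and position < ends[i]:
            return rs[i]
        return None


def assign_fragment(read: ReadPattern, index: RegionIndex) -> str | None:
    """Assign a read to the region holding the majority of its CpGs.

    Ties go to the leftmost region; a read whose CpGs overlap no region is
    unassigned (returns None).
    """
    votes: dict[str, int] = {}
    order: dict[str, int] = {}
    for k, p in enumerate(read.cpg_positions):
        region = index.locate(read.chrom, p)
        if region is not None:
            votes[region.region_id] = votes.get(region.region_id, 0) + 1
            order.setdefault(region.region_id, k)
    if not votes:
        return UNASSIGNED
    best = max(votes.items(), key=lambda kv: (kv[1], -order[kv[0]]))
    return best[0]


def regions_to_bed(regions: list[MethBinRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "region_id": [r.region_id for r in regions],
            "n_cpg": [len(r.cpg_positions) for r in regions],
        }
    )


def write_regions_bed(regions: list[MethBinRegion], path) -> None:
    regions_to_bed(regions).to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path, cpg_positions: dict[str, list[int]] | None = None):
    """Load regions from BED4(+count); CpG positions recovered from the map
    or, when absent, synthesized as region-spanning placeholders."""
    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "region_id", "n_cpg"],
        usecols=[0, 1, 2, 3],
    )
    regions = []
    for row in df.itertuples(index=False):
        if cpg_positions is not None:
            pos = [
                p
                for p in cpg_positions.get(row.chrom, [])
                if row.start <= p < row.end
            ]
        else:
            pos = [int(row.start)]
        regions.append(
            MethBinRegion(row.region_id, row.chrom, int(row.start), int(row.end),
                          tuple(pos))
        )
    return regions
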