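"""Synthetic bisulfite cohorts with planted case/control and per-type effects.

The generator emulates the data model of targeted cfDNA methylation
sequencing: per-region sets of binary CpG patterns, per-sample fragment
length distributions, and a label sheet with train/test splits.  Disorder
is induced through a two-state Markov chain over CpG sites — a read starts
methylated with probability p0 and switches state between adjacent CpGs
with probability s.  Low s yields mostly-ordered blocks (low BiEntropy);
raising s raises expected BiEntropy without changing mean methylation, so
entropy and methylation level vary independently.  Planted cancer effects
raise s by ``entropy_effect`` and shift the unmethylated-read fraction by
``ura_effect`` in informative regions, scaled per sample by a tumor-load
factor; case fragment-length mass moves into the short class by
``frag_short_shift``.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cfentropy.io import (
    CANCER_TYPES,
    LabelSheet,
    write_fragment_frame,
    write_labels,
)
from cfentropy.io import EPIREAD_COLUMNS
from cfentropy.methbin import MethBinRegion, build_segments

# toy reference: two autosomes, 5 Mb each (fragment coordinate space)
TOY_CHROM_SIZES = {"chr1": 5_000_000, "chr2": 5_000_000}

# stage proportions of the study cohort (I, II, III, IV, unknown)
STAGE_WEIGHTS = (0.21, 0.23, 0.32, 0.07, 0.17)

# per-type (train, test) counts of the 197/91 cancer split
TYPE_SPLIT = {
    "colorectal": (46, 21),
    "esophageal": (21, 9),
    "liver": (21, 10),
    "lung": (35, 16),
    "gastric": (31, 15),
    "thyroid": (18, 8),
    "ovarian": (25, 12),
}


@dataclass
class SimulationConfig:
    n_cancer_train: int = 42
    n_control_train: int = 42
    n_cancer_test: int = 18
    n_control_test: int = 18
    types: dict[str, tuple[int, int]] | None = None  # per-type (train, test)
    n_regions: int = 50
    n_informative_binary: int = 12
    n_informative_per_type: int = 3
    depth_mean: float = 80.0
    cpgs_per_fragment: tuple[int, int] = (5, 12)
    base_switch_prob: float = 0.05
    entropy_effect: float = 0.30  # switch-prob raise for disordered tumor reads
    disorder_fraction: float = 0.35  # tumor-read mass that is disordered
    ura_effect: float = 0.35  # tumor-read mass shifted to unmethylated reads
    frag_short_shift: float = 0.08  # probability mass moved into [100,150)
    n_fragments_per_sample: int = 2000
    min_tumor_load: float = 0.5
    sex_ratio: float = 0.5
    low_depth_regions: int = 2  # regions at half depth, exercising the filters
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cancer_train", "n_control_train", "n_cancer_test",
            "n_control_test", "n_regions",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.base_switch_prob + self.entropy_effect > 1.0:
            raise ValueError("switch probability exceeds 1 under entropy_effect")
        if self.ura_effect + self.disorder_fraction > 1.0:
            raise ValueError("tumor-read fractions exceed 1")
        if not 0 <= self.frag_short_shift <= 0.5:
            raise ValueError("infeasible frag_short_shift")
        needed = self.n_informative_binary
        if self.types:
            needed += self.n_informative_per_type * len(self.types)
        if needed > self.n_regions:
            raise ValueError("more informative regions requested than regions")


@dataclass
class TruthSet:
    binary_region_ids: list[str]
    per_type_region_ids: dict[str, list[str]]
    labels: pd.DataFrame


@dataclass
class Cohort:
    epireads: pd.DataFrame
    fragments: pd.DataFrame
    labels: LabelSheet
    regions: list[MethBinRegion]
    cpg_positions: dict[str, list[int]]
    truth: TruthSet
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore


def _make_regions(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay out regions as CpG runs on chr1, 2 kb apart (never merged)."""
    lo, hi = cfg.cpgs_per_fragment
    positions = []
    cursor = 1000
    n_per_region = rng.integers(lo, hi + 1, size=cfg.n_regions)
    for n in n_per_region:
        positions.extend(range(cursor, cursor + 30 * int(n), 30))
        cursor += 30 * int(n) + 2000
    cpg_map = {"chr1": positions}
    regions = build_segments(cpg_map)
    assert len(regions) == cfg.n_regions
    return regions, cpg_map


def _sample_sheet(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0

    def add(group, split, ctype, n):
        nonlocal counter
        for _ in range(n):
            counter += 1
            sid = f"S{counter:04d}"
            if ctype == "ovarian":
                sex = "female"
            else:
                sex = "female" if rng.random() < cfg.sex_ratio else "male"
            stage = (
                ("I", "II", "III", "IV", "unknown")[
                    rng.choice(5, p=STAGE_WEIGHTS)
                ]
                if group == "cancer"
                else None
            )
            load = (
                cfg.min_tumor_load
                + (1 - cfg.min_tumor_load) * rng.random()
                if group == "cancer"
                else 0.0
            )
            rows.append((sid, group, ctype, sex, stage, split, load))

    if cfg.types:
        for t, (n_tr, n_te) in cfg.types.items():
            add("cancer", "train", t, n_tr)
        for t, (n_tr, n_te) in cfg.types.items():
            add("cancer", "test", t, n_te)
    else:
        # types cycled so every cancer sample still carries a valid label
        tlist = list(CANCER_TYPES)
        for split, n in (("train", cfg.n_cancer_train), ("test", cfg.n_cancer_test)):
            for i in range(n):
                add("cancer", split, tlist[i % len(tlist)], 1)
    add("non_cancer", "train", None, cfg.n_control_train)
    add("non_cancer", "test", None, cfg.n_control_test)
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "cancer_type", "sex", "stage", "split", "load"],
    )


def simulate_cohort(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> Cohort:
    """Generate epireads, fragments and labels with planted effects.

    When ``outdir`` is given, writes ``epireads.tsv``, ``fragments.bed``,
    ``labels.tsv`` and ``regions.bed`` there; the in-memory cohort is
    returned either way and is byte-identical across runs with one seed.
    """
    rng = np.random.default_rng(cfg.seed)
    regions, cpg_map = _make_regions(cfg, rng)
    sheet = _sample_sheet(cfg, rng)
    n_samples = len(sheet)
    is_cancer = (sheet["group"] == "cancer").to_numpy()
    load = sheet["load"].to_numpy()
    types_arr = sheet["cancer_type"].to_numpy(dtype=object)

    # plant informative regions: binary first, then disjoint per-type blocks
    region_ids = [r.region_id for r in regions]
    perm = rng.permutation(cfg.n_regions)
    binary_idx = perm[: cfg.n_informative_binary]
    per_type_idx: dict[str, np.ndarray] = {}
    cursor = cfg.n_informative_binary
    type_names = sorted(cfg.types) if cfg.types else sorted(set(
        t for t in types_arr if t is not None
    ))
    for t in type_names:
        per_type_idx[t] = perm[cursor: cursor + cfg.n_informative_per_type]
        cursor += cfg.n_informative_per_type

    binary_mask = np.zeros(cfg.n_regions, dtype=bool)
    binary_mask[binary_idx] = True

    # per-region baselines: informative regions start mostly methylated so
    # the tumor hypomethylation shift is feasible and one-signed
    informative = binary_mask.copy()
    for idxs in per_type_idx.values():
        informative[idxs] = True
    p0_base = np.where(
        informative,
        rng.uniform(0.60, 0.90, size=cfg.n_regions),
        rng.uniform(0.35, 0.90, size=cfg.n_regions),
    )
    depth_scale = np.ones(cfg.n_regions)
    if cfg.low_depth_regions:
        depth_scale[perm[-cfg.low_depth_regions:]] = 0.5

    frames = []
    sample_ids = sheet["sample_id"].to_numpy()
    for ri, region in enumerate(regions):
        n_cpg = len(region.cpg_positions)
        depths = rng.poisson(cfg.depth_mean * depth_scale[ri], size=n_samples)
        total = int(depths.sum())
        if total == 0:
            continue
        # which samples carry tumor reads in this region
        active = np.zeros(n_samples)
        if binary_mask[ri]:
            active = np.where(is_cancer, load, 0.0)
        for t, idxs in per_type_idx.items():
            if ri in idxs:
                this_type = np.array([ct == t for ct in types_arr])
                active = np.where(this_type, load, active)
        # region-specific shedding heterogeneity: tumors contribute unevenly
        # across loci, so planted regions are informative yet not collinear
        active = np.clip(active * rng.uniform(0.6, 1.4, size=n_samples), 0, 1)

        # per-read component: hypomethylated / disordered tumor or background
        p_hypo = np.repeat(active * cfg.ura_effect, depths)
        p_dis = np.repeat(active * cfg.disorder_fraction, depths)
        draw = rng.random(total)
        comp = np.zeros(total, dtype=np.int8)
        comp[draw < p_hypo] = 1
        comp[(draw >= p_hypo) & (draw < p_hypo + p_dis)] = 2
        p0_r = np.select(
            [comp == 1, comp == 2], [0.03, 0.5], default=p0_base[ri]
        )
        switch_r = np.select(
            [comp == 1, comp == 2],
            [0.02, cfg.base_switch_prob + cfg.entropy_effect],
            default=cfg.base_switch_prob,
        )
        first = (rng.random(total) < p0_r).astype(np.uint8)
        flips = (
            rng.random((total, n_cpg - 1)) < switch_r[:, None]
        ).astype(np.uint8)
        bits = np.bitwise_xor.accumulate(
            np.hstack([first[:, None], flips]), axis=1
        )

        state = bits.copy()  # 0=U, 1=M, 2=missing
        # sprinkle missing calls: edge-missing (trimmed) and internal (dropped)
        n_edge = int(0.03 * total)
        n_internal = int(0.02 * total) if n_cpg >= 3 else 0
        if n_edge:
            rows = rng.choice(total, size=n_edge, replace=False)
            state[rows, 0] = 2
        if n_internal:
            rows = rng.choice(total, size=n_internal, replace=False)
            state[rows, 1 + rng.integers(0, n_cpg - 2, size=n_internal)] = 2
        chars = np.array([ord("U"), ord("M"), ord(".")], dtype=np.uint8)[state]
        calls = np.frombuffer(chars.tobytes(), dtype=f"S{n_cpg}").astype("U")

        pos_str = ",".join(map(str, region.cpg_positions))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_ids, depths),
                    "chrom": region.chrom,
                    "frag_start": region.cpg_positions[0] - 10,
                    "frag_end": region.cpg_positions[-1] + 12,
                    "cpg_positions": pos_str,
                    "calls": calls,
                }
            )
        )
    epireads = (
        pd.concat(frames, ignore_index=True)[list(EPIREAD_COLUMNS)]
        if frames
        else pd.DataFrame(columns=list(EPIREAD_COLUMNS))
    )

    fragments = _simulate_fragments(cfg, sheet, rng)

    labels = LabelSheet(
        sheet[["sample_id", "group", "cancer_type", "sex", "stage", "split"]].copy()
    )
    truth = TruthSet(
        binary_region_ids=sorted(region_ids[i] for i in binary_idx),
        per_type_region_ids={
            t: sorted(region_ids[i] for i in idxs)
            for t, idxs in per_type_idx.items()
        },
        labels=sheet.copy(),
    )
    cohort = Cohort(
        epireads=epireads,
        fragments=fragments,
        labels=labels,
        regions=regions,
        cpg_positions=cpg_map,
        truth=truth,
        config=cfg,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        epireads.to_csv(outdir / "epireads.tsv", sep="\t", index=False)
        write_fragment_frame(fragments, outdir / "fragments.bed")
        write_labels(labels, outdir / "labels.tsv")
        from cfentropy.methbin import write_regions_bed

        write_regions_bed(regions, outdir / "regions.bed")
    return cohort


def _simulate_fragments(
    cfg: SimulationConfig, sheet: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n_samples = len(sheet)
    nf = cfg.n_fragments_per_sample
    total = n_samples * nf
    is_cancer = np.repeat((sheet["group"] == "cancer").to_numpy(), nf)
    load = np.repeat(sheet["load"].to_numpy(), nf)

    # class mixture: controls (short, middle, long, none) = (.15, .70, .10, .05)
    p_short = np.where(is_cancer, 0.15 + cfg.frag_short_shift * load, 0.15)
    p_mid = np.where(is_cancer, 0.70 - cfg.frag_short_shift * load, 0.70)
    u = rng.random(total)
    short = u < p_short
    middle = ~short & (u < p_short + p_mid)
    long_ = ~short & ~middle & (u < p_short + p_mid + 0.10)
    none_ = ~(short | middle | long_)
    length = np.empty(total, dtype=np.int64)
    length[short] = rng.integers(100, 150, size=int(short.sum()))
    length[middle] = rng.integers(150, 260, size=int(middle.sum()))
    length[long_] = rng.integers(260, 321, size=int(long_.sum()))
    length[none_] = rng.integers(40, 100, size=int(none_.sum()))

    chroms = np.array(sorted(TOY_CHROM_SIZES))
    chrom_idx = rng.integers(0, len(chroms), size=total)
    sizes = np.array([TOY_CHROM_SIZES[c] for c in chroms])
    mid = rng.integers(400, sizes[chrom_idx] - 400)
    start = np.maximum(mid - length // 2, 0)
    return pd.DataFrame(
        {
            "chrom": chroms[chrom_idx],
            "start": start,
            "end": start + length,
            "sample_id": np.repeat(sheet["sample_id"].to_numpy(), nf),
            "length": length,
        }
    )


def scenario_presets() -> dict[str, SimulationConfig]:
    """Named study-shaped scenarios (cohort split of 197/157 train and
    91/76 test, mirroring the modeled study's label sheet)."""
    study = dict(
        n_cancer_train=197,
        n_control_train=157,
        n_cancer_test=91,
        n_control_test=76,
        types=dict(TYPE_SPLIT),
    )
    presets = {
        "null": SimulationConfig(
            **study,
            entropy_effect=0.0,
            disorder_fraction=0.0,
            ura_effect=0.0,
            frag_short_shift=0.0,
            seed=0,
        ),
        "strong-signal": SimulationConfig(**study, seed=0),
        "seven-type": SimulationConfig(
            **study,
            n_informative_per_type=4,
            entropy_effect=0.35,
            ura_effect=0.40,
            seed=0,
        ),
    }
    return presets


def preset(name: str, seed: int | None = None) -> SimulationConfig:
    cfg = scenario_presets()[name]
    return replace(cfg, seed=seed) if seed is not None else cfg
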