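"""Readers and writers for on-disk artifacts.

All genomic coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Epireads are 6-column TSV (sample_id, chrom, frag_start,
frag_end, comma-joined CpG positions, call string over ``M``/``U``/``.``);
fragments are BED3 plus a sample-id name column; feature matrices are TSV
with sample rows x region columns and the literal token ``NA`` for missing
cells.  Readers validate and reject malformed records rather than coercing.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

MISSING_CALL = "."
VALID_CALLS = frozenset("MU.")

CANCER_TYPES = (
    "colorectal",
    "esophageal",
    "gastric",
    "liver",
    "lung",
    "ovarian",
    "thyroid",
)

STAGES = ("I", "II", "III", "IV", "unknown")


class FormatError(ValueError):
    """A malformed on-disk record; message names the line and field."""


@dataclass(frozen=True)
class ReadPattern:
    """One sequenced bisulfite fragment: ordered CpG calls with genomic anchor.

    ``calls`` is a string over ``M`` (methylated), ``U`` (unmethylated) and
    ``.`` (missing), aligned with ``cpg_positions``.
    """

    sample_id: str
    chrom: str
    frag_start: int
    frag_end: int
    cpg_positions: tuple[int, ...]
    calls: str

    def __post_init__(self) -> None:
        if self.frag_start >= self.frag_end:
            raise FormatError(
                f"fragment start {self.frag_start} >= end {self.frag_end}"
            )
        if len(self.calls) != len(self.cpg_positions):
            raise FormatError(
                f"{len(self.cpg_positions)} CpG positions but "
                f"{len(self.calls)} calls"
            )
        pos = self.cpg_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise FormatError("cpg_positions not strictly increasing")
        if pos and (pos[0] < self.frag_start or pos[-1] >= self.frag_end):
            raise FormatError("cpg_positions outside [frag_start, frag_end)")
        if not set(self.calls) <= VALID_CALLS:
            raise FormatError(f"invalid call characters in {self.calls!r}")


@dataclass(frozen=True)
class FragmentRecord:
    """A cfDNA fragment interval (BED convention)."""

    sample_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"fragment end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabelSheet:
    """Per-sample clinical labels (group, cancer type, sex, stage, split)."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "sex", "split")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"label sheet missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        bad_group = set(t["group"]) - {"cancer", "non_cancer"}
        if bad_group:
            raise FormatError(f"unknown group token(s) {sorted(bad_group)}")
        if "cancer_type" not in t.columns:
            t["cancer_type"] = pd.NA
        ct = t["cancer_type"]
        known = ct.dropna()
        bad_ct = set(known) - set(CANCER_TYPES)
        if bad_ct:
            raise FormatError(f"unknown cancer_type token(s) {sorted(bad_ct)}")
        is_cancer = t["group"] == "cancer"
        if (is_cancer & ct.isna()).any():
            sid = t.loc[is_cancer & ct.isna(), "sample_id"].iloc[0]
            raise FormatError(f"cancer sample {sid!r} lacks cancer_type")
        if (~is_cancer & ct.notna()).any():
            sid = t.loc[~is_cancer & ct.notna(), "sample_id"].iloc[0]
            raise FormatError(f"non-cancer sample {sid!r} has cancer_type")
        bad_split = set(t["split"]) - {"train", "test"}
        if bad_split:
            raise FormatError(f"unknown split token(s) {sorted(bad_split)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, split: str) -> "LabelSheet":
        return LabelSheet(self.table[self.table["split"] == split].copy())


@dataclass
class RegionFeatureMatrix:
    """Samples x regions feature values with parallel effective-read depths.

    Missing values are NaN in ``values`` (written as ``NA``), never 0.
    """

    values: pd.DataFrame
    depths: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.depths is None:
            self.depths = pd.DataFrame(
                0, index=self.values.index, columns=self.values.columns
            )
        if not self.values.index.equals(self.depths.index) or not (
            self.values.columns.equals(self.depths.columns)
        ):
            raise ValueError("values and depths grids are not aligned")
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("negative depth")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "RegionFeatureMatrix":
        return RegionFeatureMatrix(
            self.values.loc[list(sample_ids)].copy(),
            self.depths.loc[list(sample_ids)].copy(),
        )


# ---------------------------------------------------------------------------
# epireads

EPIREAD_COLUMNS = (
    "sample_id",
    "chrom",
    "frag_start",
    "frag_end",
    "cpg_positions",
    "calls",
)


def read_epireads(path: str | Path) -> Iterator[ReadPattern]:
    """Stream validated :class:`ReadPattern` records from an epiread TSV."""
    with open(path) as fh:
        first = fh.readline()
        if not first:
            return
        lines: Iterable[tuple[int, str]]
        if first.rstrip("\n").split("\t")[0] == "sample_id":  # optional header
            lines = enumerate(fh, start=2)
        else:
            lines = enumerate([first] + list(fh), start=1)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(parts)}"
                )
            sid, chrom, s, e, pos_s, calls = parts
            try:
                start, end = int(s), int(e)
                positions = tuple(int(p) for p in pos_s.split(",")) if pos_s else ()
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                yield ReadPattern(sid, chrom, start, end, positions, calls)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_epireads(records: Iterable[ReadPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EPIREAD_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.chrom}\t{r.frag_start}\t{r.frag_end}\t"
                f"{','.join(map(str, r.cpg_positions))}\t{r.calls}\n"
            )


def read_epiread_frame(path: str | Path) -> pd.DataFrame:
    """Read an epiread TSV into a DataFrame (fast path for matrix building).

    Validation is structural (column count, coordinate order); per-read
    invariants are enforced when rows are materialized as ReadPattern.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=list(EPIREAD_COLUMNS),
        header=0 if _has_header(path) else None,
        dtype={
            "sample_id": str,
            "chrom": str,
            "frag_start": np.int64,
            "frag_end": np.int64,
            "cpg_positions": str,
            "calls": str,
        },
    )
    if (df["frag_start"] >= df["frag_end"]).any():
        bad = int((df["frag_start"] >= df["frag_end"]).idxmax())
        raise FormatError(f"{path}: row {bad}: frag_start >= frag_end")
    return df


def _has_header(path: str | Path) -> bool:
    with open(path) as fh:
        return fh.readline().split("\t")[0] == "sample_id"


def frame_to_patterns(df: pd.DataFrame) -> Iterator[ReadPattern]:
    for row in df.itertuples(index=False):
        yield ReadPattern(
            row.sample_id,
            row.chrom,
            int(row.frag_start),
            int(row.frag_end),
            tuple(int(p) for p in str(row.cpg_positions).split(",")),
            row.calls,
        )


def patterns_to_frame(records: Iterable[ReadPattern]) -> pd.DataFrame:
    rows = [
        (
            r.sample_id,
            r.chrom,
            r.frag_start,
            r.frag_end,
            ",".join(map(str, r.cpg_positions)),
            r.calls,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(EPIREAD_COLUMNS))


# ---------------------------------------------------------------------------
# fragments (BED3 + sample name)


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 BED fields, got {len(parts)}"
                )
            chrom, s, e, sid = parts[:4]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                yield FragmentRecord(sid, chrom, start, end)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample_id}\n")


def read_fragment_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "sample_id"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "sample_id": str},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: fragment with end <= start")
    df["length"] = df["end"] - df["start"]
    return df


def write_fragment_frame(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "sample_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> LabelSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cancer_type" in df.columns:
        df["cancer_type"] = df["cancer_type"].replace({"": pd.NA, "NA": pd.NA})
    return LabelSheet(df)


def write_labels(labels: LabelSheet, path: str | Path) -> None:
    out = labels.table.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# feature matrices


def write_matrix(matrix: RegionFeatureMatrix, path: str | Path) -> None:
    """Write values and depths as one TSV pair (``path`` and ``path.depths``)."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")
    matrix.depths.to_csv(
        path.with_suffix(path.suffix + ".depths"),
        sep="\t",
        index_label="sample_id",
    )


def read_matrix(path: str | Path) -> RegionFeatureMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"],
                         keep_default_na=False)
    dpath = path.with_suffix(path.suffix + ".depths")
    if dpath.exists():
        depths = pd.read_csv(dpath, sep="\t", index_col="sample_id").astype(int)
    else:
        depths = None
    return RegionFeatureMatrix(values, depths)


# ---------------------------------------------------------------------------
# model bundles


def save_bundle(bundle: object, path: str | Path) -> None:
    """Serialize a model bundle with an embedded format-version tag."""
    from cfentropy import __version__

    with open(path, "wb") as fh:
        pickle.dump({"cfentropy_version": __version__, "bundle": bundle}, fh)


def load_bundle(path: str | Path) -> object:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if "bundle" not in payload:
        raise FormatError(f"{path}: not a cfentropy model bundle")
    return payload["bundle"]
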