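"""Readers and writers for the tabular formats the pipeline touches.

All on-disk formats are plain text: the methylation matrix is a
probes-by-samples TSV of β values, probe annotation is a manifest-style CSV,
clinical follow-up is a TSV, and discovered blocks are written as BED6+.
Readers validate invariants and refuse to silently coerce bad input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing, compared case-insensitively.
MISSING_MARKERS = frozenset({"", "na", "nan"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation fractions in [0, 1).

    ``values`` is a DataFrame indexed by probe ID with sample-ID columns;
    missing entries are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate probe IDs: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = (~np.isnan(arr)) & ((arr < 0) | (arr >= 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"β value out of [0, 1) at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()


@dataclass
class SurvivalTable:
    """Per-sample right-censored follow-up: time in days, 0/1 event flag,
    plus optional clinical covariates (one column each)."""

    data: pd.DataFrame
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for col in ("time_days", "event"):
            if col not in self.data.columns:
                raise FormatError(f"survival table missing column {col!r}")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample IDs in survival table")
        if (self.data["time_days"] < 0).any():
            raise FormatError("negative follow-up time")
        bad = ~self.data["event"].isin([0, 1])
        if bad.any():
            raise FormatError(
                f"event indicator outside {{0,1}} for samples "
                f"{self.data.index[bad].tolist()[:5]}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time_days"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time_days", "event"])

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class MCB:
    """A maximal run of co-methylated CpGs on one chromosome.

    Coordinates are 1-based inclusive positions of the first and last member
    CpG; ``probes`` are the member probe IDs in genomic order.
    """

    mcb_id: int
    chrom: str
    start: int
    end: int
    probes: list[str] = field(default_factory=list)
    gene: str | None = None
    gene_r: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"MCB {self.mcb_id}: start > end")
        if len(self.probes) < 2:
            raise ValueError(f"MCB {self.mcb_id}: needs at least 2 member CpGs")

    @property
    def n_cpgs(self) -> int:
        return len(self.probes)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _read_table(path, sep: str, **kw) -> pd.DataFrame:
    markers = ["NA", "Na", "na", "nA", "NaN", "nan", "NAN", ""]
    return pd.read_csv(path, sep=sep, na_values=markers, keep_default_na=False, **kw)


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes-by-samples TSV of β values.

    First column is the probe ID, header row holds sample IDs; empty cells
    and "NA"/"NaN" (any case) denote missing.  Values outside [0, 1) are
    rejected with the offending probe and sample named.
    """
    df = _read_table(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric β value in sample {col!r}: "
                f"{bad.iloc[0]!r} at probe {bad.index[0]!r}"
            )
    return BetaMatrix(df.astype(float))


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id", lineterminator="\n")


def read_manifest(path) -> pd.DataFrame:
    """Read a 450K-style manifest CSV into a per-probe annotation frame.

    Expected columns: probe_id, chrom, pos (1-based), genes (semicolon
    separated, possibly empty), snp_flag (0/1 or true/false).  Gene lists are
    deduplicated preserving first occurrence; probes with a missing position
    are dropped with a logged warning; two probes sharing (chrom, pos) is a
    validation error.
    """
    df = _read_table(path, sep=",", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos", "genes", "snp_flag"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise FormatError("duplicate probe IDs in manifest")

    no_pos = df["pos"].isna() | df["chrom"].isna()
    if no_pos.any():
        logger.warning("manifest: dropped %d probes with missing position", int(no_pos.sum()))
        df = df[~no_pos]
    df = df.copy()
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise FormatError("manifest positions must be ≥ 1 (1-based)")

    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["chrom", "pos"]].iloc[0]
        raise FormatError(
            f"two probes share position {pair['chrom']}:{pair['pos']}"
        )

    def _genes(cell) -> tuple[str, ...]:
        if pd.isna(cell) or str(cell).strip() == "":
            return ()
        seen: list[str] = []
        for g in str(cell).split(";"):
            g = g.strip()
            if g and g not in seen:
                seen.append(g)
        return tuple(seen)

    df["genes"] = df["genes"] if "genes" in df else ""
    ann = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "genes": [_genes(c) for c in df["genes"]],
            "snp_flag": df["snp_flag"].map(_parse_flag).to_numpy(),
        },
        index=pd.Index(df["probe_id"], name="probe_id"),
    )
    return ann


def _parse_flag(v) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in {"1", "true", "t", "yes"}:
            return True
        if s in {"0", "false", "f", "no", ""}:
            return False
        raise FormatError(f"unparseable SNP flag: {v!r}")
    if pd.isna(v):
        return False
    return bool(int(v))


def write_manifest(ann: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "probe_id": ann.index,
            "chrom": ann["chrom"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "genes": [";".join(g) for g in ann["genes"]],
            "snp_flag": ann["snp_flag"].astype(int).to_numpy(),
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_clinical(path) -> SurvivalTable:
    """Read a clinical TSV with columns sample, time_days, event.

    Samples whose time or event is missing are excluded and counted in
    ``SurvivalTable.n_excluded``; any extra columns ride along as covariates.
    """
    df = _read_table(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    n0 = len(df)
    keep = df["time_days"].notna() & df["event"].notna()
    excluded = n0 - int(keep.sum())
    if excluded:
        logger.info("clinical: excluded %d samples with missing time/event", excluded)
    df = df[keep].copy()
    bad = ~df["event"].isin([0, 1])
    if bad.any():
        raise FormatError(
            f"event must be 0 or 1; offending sample(s): {df.loc[bad, 'sample'].tolist()[:5]}"
        )
    df["event"] = df["event"].astype(int)
    df["time_days"] = df["time_days"].astype(float)
    df = df.set_index("sample")
    df.index.name = "sample"
    return SurvivalTable(df, n_excluded=excluded)


def write_clinical(surv: SurvivalTable, path) -> None:
    surv.data.to_csv(path, sep="\t", na_rep="NA", index_label="sample", lineterminator="\n")


_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tprobes"


def write_mcb_bed(mcbs: Sequence[MCB], path) -> None:
    """Write blocks as BED6+1: 0-based half-open interval, block ID as name,
    CpG count in the score field, comma-joined member probes in column 7.

    Input must already be sorted by (chrom, start); manifest coordinates are
    1-based so the BED start is ``start - 1``.
    """
    keys = [(m.chrom, m.start) for m in mcbs]
    if keys != sorted(keys):
        raise ValueError("MCBs must be sorted by (chrom, start) before writing")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_BED_HEADER + "\n")
        for m in mcbs:
            fh.write(
                f"{m.chrom}\t{m.start - 1}\t{m.end}\tMCB_{m.mcb_id}\t{m.n_cpgs}\t.\t"
                + ",".join(m.probes)
                + "\n"
            )


def read_mcb_bed(path) -> list[MCB]:
    """Read back a BED6+1 block file written by :func:`write_mcb_bed`."""
    mcbs: list[MCB] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise FormatError(f"expected 7 BED columns, got {len(fields)}")
            chrom, start, end, name, score, _strand, probes = fields[:7]
            mcbs.append(
                MCB(
                    mcb_id=int(name.removeprefix("MCB_")),
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    probes=probes.split(","),
                )
            )
    return mcbs


def match_probes(beta: BetaMatrix, ann: pd.DataFrame) -> tuple[BetaMatrix, pd.DataFrame]:
    """Strict-match the probe sets of a β matrix and an annotation frame.

    Probes present in only one source are dropped with a logged count; the
    returned pair covers exactly the intersection, in the β matrix's order.
    """
    shared = beta.probe_ids.intersection(ann.index)
    dropped = (beta.n_probes - len(shared)) + (len(ann) - len(shared))
    if dropped:
        logger.info("probe match: dropped %d probes present in only one source", dropped)
    if len(shared) == 0:
        raise FormatError("β matrix and manifest share no probes")
    order = [p for p in beta.probe_ids if p in set(shared)]
    return BetaMatrix(beta.values.loc[order]), ann.loc[order]
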