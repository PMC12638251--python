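"""Containers and readers/writers for every external table the pipeline touches.

Table kinds
-----------
* guide library (TSV: guide_id, gene, is_control) -> :class:`GuideLibrary`
* sgRNA count matrix (TSV, first column guide ids) + sample sheet (TSV:
  sample_id, condition, replicate, day) -> :class:`CountMatrix`
* gene expression (TSV: gene, tpm) -> :class:`ExpressionTable`
* gene/metabolite set databases (standard GMT) -> :class:`AnnotationSetDB`
* feature x sample abundance matrices (CSV, empty/"NA"/"NaN" cells are
  missing) + group sheet -> :class:`AbundanceMatrix`

No numerics live here beyond validation; round-tripping (write then read) is
the identity for every kind.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ScreenDeltaWarning

#: condition label reserved for the pre-switch (day-7) reference samples
BASELINE = "baseline"

_INT_RE = re.compile(r"^\d+$")
_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideLibrary:
    """sgRNA -> gene map. ``frame`` is indexed by guide_id with columns
    ``gene`` (str) and ``is_control`` (bool)."""

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate guide ids in library: {dups[:5]}")
        if "gene" not in f.columns:
            raise FormatError("guide library needs a 'gene' column")
        if "is_control" not in f.columns:
            object.__setattr__(
                self, "frame", f.assign(is_control=False)
            )
        f = self.frame
        if not (~f["is_control"]).any():
            raise FormatError("library contains no non-control guides")

    @property
    def guides(self) -> pd.Index:
        return self.frame.index

    @property
    def targeting(self) -> pd.DataFrame:
        """Non-control guides only."""
        return self.frame[~self.frame["is_control"]]

    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.targeting["gene"].unique()))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CountMatrix:
    """Integer sgRNA read counts (guides x samples) plus per-sample metadata.

    ``samples`` is indexed by sample_id with columns ``condition`` (str),
    ``replicate`` (int) and ``day`` (int). At least one sample must carry the
    :data:`BASELINE` condition.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate guide ids in counts: {dups[:5]}")
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            raise FormatError("counts must be integer-typed")
        if (c.to_numpy() < 0).any():
            g, s = np.argwhere(c.to_numpy() < 0)[0]
            raise FormatError(
                f"negative count at guide {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = [s for s in c.columns if s not in self.samples.index]
        if missing:
            raise ConfigurationError(
                f"samples absent from sample sheet: {missing}"
            )
        if not (self.samples.loc[list(c.columns), "condition"] == BASELINE).any():
            raise ConfigurationError(
                f"no sample with condition {BASELINE!r}; the screen needs a pre-switch reference"
            )

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    def condition_of(self, sample: str) -> str:
        return str(self.samples.loc[sample, "condition"])


@dataclass(frozen=True)
class ExpressionTable:
    """gene -> TPM (transcripts per million), used to nominate the empirical
    null (non-expressed) genes."""

    tpm: pd.Series

    def __post_init__(self):
        if self.tpm.index.has_duplicates:
            dups = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate genes in expression table: {dups[:5]}")
        if (self.tpm < 0).any():
            bad = self.tpm.index[self.tpm < 0][0]
            raise FormatError(f"negative TPM for gene {bad!r}")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Feature x sample intensities with per-sample group labels.

    Missing measurements are NaN, never zero. On the raw (linear) scale all
    present intensities must be > 0; after a log transform set
    ``log_scale=True`` and the positivity invariant no longer applies.
    ``isotopologue`` optionally maps feature_id -> (metabolite, k) for
    m+k-indexed tracer tables.
    """

    values: pd.DataFrame
    groups: pd.Series
    log_scale: bool = False
    isotopologue: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups[:5]}")
        missing = [s for s in v.columns if s not in self.groups.index]
        if missing:
            raise ConfigurationError(
                f"samples absent from group sheet: {missing}"
            )
        if self.groups.astype(str).str.len().eq(0).any():
            raise FormatError("empty group label")
        if not self.log_scale:
            arr = v.to_numpy(dtype=float)
            bad = (arr <= 0) & ~np.isnan(arr)
            if bad.any():
                g, s = np.argwhere(bad)[0]
                raise FormatError(
                    f"non-positive intensity at feature {v.index[g]!r}, "
                    f"sample {v.columns[s]!r} (missing values must be blank, not zero)"
                )
        if self.isotopologue is not None:
            k = self.isotopologue["k"]
            if (k < 0).any() or not np.issubdtype(k.dtype, np.integer):
                raise FormatError("isotopologue index m+k must be a non-negative integer")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


class AnnotationSetDB:
    """Named gene or metabolite sets (GMT carrier), insertion-ordered."""

    def __init__(self, sets: dict[str, list[str]] | None = None,
                 descriptions: dict[str, str] | None = None):
        self.sets: dict[str, list[str]] = {}
        self.descriptions: dict[str, str] = {}
        for name, items in (sets or {}).items():
            self.add(name, items, (descriptions or {}).get(name, ""))

    def add(self, name: str, items, description: str = "",
            override: bool = False) -> None:
        if name in self.sets and not override:
            raise FormatError(f"duplicate set name {name!r}")
        deduped = list(dict.fromkeys(str(i) for i in items))
        if len(deduped) < len(list(items)):
            warnings.warn(
                f"set {name!r}: duplicate items collapsed", ScreenDeltaWarning,
                stacklevel=2,
            )
        if not deduped:
            raise FormatError(f"set {name!r} is empty")
        self.sets[name] = deduped
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name) -> bool:
        return name in self.sets

    def __getitem__(self, name) -> list[str]:
        return self.sets[name]

    def universe(self) -> set[str]:
        out: set[str] = set()
        for items in self.sets.values():
            out.update(items)
        return out


# ---------------------------------------------------------------------------
# TSV readers (screen side)
# ---------------------------------------------------------------------------

def _parse_bool(token: str, *, context: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise FormatError(f"{context}: cannot parse boolean {token!r}")


def read_library(path) -> GuideLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"guide_id", "gene"}
    if not need.issubset(df.columns):
        raise FormatError(
            f"library must have columns {sorted(need)}, got {list(df.columns)}"
        )
    if "is_control" in df.columns:
        ctrl = [
            _parse_bool(v, context=f"library row {i + 2}")
            for i, v in enumerate(df["is_control"])
        ]
    else:
        ctrl = [False] * len(df)
    frame = pd.DataFrame(
        {"gene": df["gene"].astype(str).to_numpy(), "is_control": ctrl},
        index=pd.Index(df["guide_id"].astype(str), name="guide_id"),
    )
    return GuideLibrary(frame)


def write_library(library: GuideLibrary, path) -> None:
    out = library.frame.reset_index()
    out["is_control"] = out["is_control"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "condition", "replicate", "day"}
    if not need.issubset(df.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(need)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in sample sheet")
    out = pd.DataFrame(
        {
            "condition": df["condition"].astype(str).to_numpy(),
            "replicate": df["replicate"].astype(int).to_numpy(),
            "day": df["day"].astype(int).to_numpy(),
        },
        index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
    )
    return out


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


def read_counts(path, library: GuideLibrary, sample_sheet: pd.DataFrame) -> CountMatrix:
    """Read an sgRNA count TSV (first column guide ids) against a library.

    Guides in the file but absent from the library are rejected; guides in
    the library but absent from the file are reported with a warning. Cells
    must be non-negative integers — decimals and negatives are format errors
    naming the offending cell, never rounded.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("count table needs a guide-id column plus at least one sample")
    guide_col = df.columns[0]
    guides = df[guide_col].astype(str)
    if guides.duplicated().any():
        dup = guides[guides.duplicated()].iloc[0]
        raise FormatError(f"duplicate guide id {dup!r} in count table")
    sample_cols = list(df.columns[1:])
    data = np.empty((len(df), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            token = str(raw).strip()
            if not _INT_RE.match(token):
                raise FormatError(
                    f"count {raw!r} at guide {guides.iloc[i]!r}, sample {col!r} "
                    "is not a non-negative integer"
                )
            data[i, j] = int(token)
    counts = pd.DataFrame(
        data, index=pd.Index(guides, name="guide_id"),
        columns=pd.Index(sample_cols, name="sample_id"),
    )
    unknown = counts.index.difference(library.guides)
    if len(unknown):
        raise FormatError(
            f"guides in count table but absent from library: {list(unknown[:5])}"
        )
    absent = library.guides.difference(counts.index)
    if len(absent):
        warnings.warn(
            f"{len(absent)} library guides have no counts and are dropped "
            f"(e.g. {list(absent[:3])})",
            ScreenDeltaWarning,
            stacklevel=2,
        )
    return CountMatrix(counts=counts, samples=sample_sheet)


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.counts.reset_index().to_csv(path, sep="\t", index=False)


def read_expression(path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    need = {"gene", "tpm"}
    if not need.issubset(df.columns):
        raise FormatError(
            f"expression table must have columns {sorted(need)}, got {list(df.columns)}"
        )
    tpm = pd.to_numeric(df["tpm"], errors="coerce")
    if tpm.isna().any():
        bad = df.loc[tpm.isna(), "gene"].iloc[0]
        raise FormatError(f"non-numeric TPM for gene {bad!r}")
    return ExpressionTable(pd.Series(tpm.to_numpy(), index=pd.Index(df["gene"], name="gene"), name="tpm"))


def write_expression(expr: ExpressionTable, path) -> None:
    expr.tpm.rename("tpm").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> AnnotationSetDB:
    """Parse a standard GMT file (set_name TAB description TAB item1 ...).

    Sets are kept in file order; duplicate items within one set collapse with
    a warning; duplicate set names and short lines are format errors with
    their line number. An empty file is a valid empty database.
    """
    db = AnnotationSetDB()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc, items = fields[0], fields[1], fields[2:]
            if name in db:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            db.add(name, [i for i in items if i != ""], desc)
    return db


def write_gmt(db: AnnotationSetDB, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, items in db.sets.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *items]) + "\n")


# ---------------------------------------------------------------------------
# abundance CSV
# ---------------------------------------------------------------------------

def read_group_sheet(path) -> pd.Series:
    df = pd.read_csv(path, dtype=str)
    need = {"sample_id", "group"}
    if not need.issubset(df.columns):
        raise FormatError(
            f"group sheet must have columns {sorted(need)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in group sheet")
    return pd.Series(
        df["group"].astype(str).to_numpy(),
        index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
        name="group",
    )


def write_group_sheet(groups: pd.Series, path) -> None:
    groups.rename("group").rename_axis("sample_id").reset_index().to_csv(path, index=False)


def read_abundance(path, group_sheet: pd.Series, *, log_scale: bool = False,
                   isotopologue: bool = False) -> AbundanceMatrix:
    """Read a feature x sample abundance CSV.

    Missing cells (empty, "NA", "NaN") become NaN, never zero. A measured
    intensity of zero or below is a format error on the raw scale. When
    ``isotopologue`` is true the file must carry ``metabolite`` and ``k``
    columns right after the feature id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("abundance table needs a feature-id column plus samples")
    feat_col = df.columns[0]
    features = pd.Index(df[feat_col].astype(str), name="feature_id")
    iso = None
    meta_cols: list[str] = []
    if isotopologue:
        if not {"metabolite", "k"}.issubset(df.columns):
            raise FormatError("isotopologue table needs 'metabolite' and 'k' columns")
        iso = pd.DataFrame(
            {"metabolite": df["metabolite"].astype(str).to_numpy(),
             "k": df["k"].astype(int).to_numpy()},
            index=features,
        )
        meta_cols = ["metabolite", "k"]
    sample_cols = [c for c in df.columns[1:] if c not in meta_cols]
    data = np.full((len(df), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        for i, raw in enumerate(df[col]):
            token = str(raw).strip()
            if token in _MISSING_TOKENS:
                continue
            try:
                x = float(token)
            except ValueError:
                raise FormatError(
                    f"unparseable intensity {raw!r} at feature "
                    f"{features[i]!r}, sample {col!r}"
                ) from None
            if not log_scale and x <= 0:
                raise FormatError(
                    f"non-positive intensity {raw!r} at feature {features[i]!r}, "
                    f"sample {col!r} (missing values must be blank)"
                )
            data[i, j] = x
    values = pd.DataFrame(data, index=features, columns=sample_cols)
    return AbundanceMatrix(values=values, groups=group_sheet,
                           log_scale=log_scale, isotopologue=iso)


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    out = matrix.values.copy()
    if matrix.isotopologue is not None:
        out = pd.concat([matrix.isotopologue, out], axis=1)
    out.reset_index().to_csv(path, index=False, na_rep="")
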