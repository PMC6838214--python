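"""Reading, validating and writing AIRR Rearrangement tables and clone trees.

The unit of analysis throughout the package is the :class:`RepertoireTable`:
one annotated rearrangement record per row, with field names following the
AIRR Community Rearrangement schema (``sequence_alignment``, ``junction``,
``v_call`` and friends).  Tables carry different degrees of upstream
post-processing — alignment only, full V(D)J annotation, clonal clustering,
per-clone phylogenies — and each summary statistic requires a minimum
:class:`CapabilityLevel`.  This module never performs annotation, clustering
or tree inference itself; it assumes such metadata are present.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "RepertoireTable",
    "CapabilityLevel",
    "CloneTreeSet",
    "read_airr",
    "write_airr",
    "read_clone_trees",
    "capability",
    "normalize_gene_call",
    "degap",
    "degap_pair",
]

#: AIRR Rearrangement core fields recognized by this package.
STRING_FIELDS = (
    "sequence_alignment",
    "germline_alignment",
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "np1",
    "np2",
    "clone_id",
    "locus",
)
INT_FIELDS = (
    "v_3p_deletion",
    "v_5p_deletion",
    "d_3p_deletion",
    "d_5p_deletion",
    "j_3p_deletion",
    "j_5p_deletion",
)
BOOL_FIELDS = ("productive",)
RECOGNIZED_FIELDS = STRING_FIELDS + INT_FIELDS + BOOL_FIELDS

LOCI = frozenset({"IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG"})

_GAP_CHARS = frozenset(".-")
_ALLELE_RE = re.compile(r"\*[0-9]+$")


class AirrIOError(ValueError):
    """Malformed or unusable AIRR input."""


class CapabilityLevel(enum.IntEnum):
    """Ordered degrees of assumed post-processing.

    Each level implies all lower levels: an ``annotated`` table supports
    every alignment-only summary, a ``clustered`` table every annotated
    summary, and so on.
    """

    alignment_only = 1
    annotated = 2
    clustered = 3
    phylogenetic = 4


@dataclass
class CloneTreeSet:
    """Rooted per-clonal-family trees keyed by ``clone_id``."""

    trees: dict[str, dendropy.Tree] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, tree in self.trees.items():
            if len(tree.leaf_nodes()) < 1:
                raise AirrIOError(f"tree for clone {cid!r} has no leaves")

    def __len__(self) -> int:
        return len(self.trees)


class RepertoireTable:
    """An AIRR-schema rearrangement table plus optional clone trees.

    Wraps a :class:`pandas.DataFrame` whose recognized columns follow the
    AIRR Rearrangement schema.  Missing values are pandas NA; sequences are
    uppercased on construction.  Unrecognized columns are preserved but
    ignored by all summaries.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trees: CloneTreeSet | None = None,
        validate: bool = True,
    ) -> None:
        self.df = _coerce_schema(df)
        self.trees = trees
        if validate:
            self.validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[Mapping], **kwargs) -> "RepertoireTable":
        return cls(pd.DataFrame(list(records)), **kwargs)

    # -- basic protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"RepertoireTable({len(self)} records, "
            f"capability={self.capability().name})"
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise AirrIOError("repertoire table has zero records")
        for col in INT_FIELDS:
            if col in df.columns:
                vals = df[col].dropna()
                if (vals < 0).any():
                    raise AirrIOError(f"negative values in {col}")
        if "sequence_alignment" in df.columns and "germline_alignment" in df.columns:
            both = df[["sequence_alignment", "germline_alignment"]].dropna()
            bad = both["sequence_alignment"].str.len() != both[
                "germline_alignment"
            ].str.len()
            if bad.any():
                raise AirrIOError(
                    "sequence_alignment and germline_alignment lengths differ "
                    f"in {int(bad.sum())} record(s)"
                )
        if "locus" in df.columns:
            loci = set(df["locus"].dropna().unique())
            if len(loci) > 1:
                raise AirrIOError(f"locus not uniform within table: {sorted(loci)}")
            unknown = loci - LOCI
            if unknown:
                raise AirrIOError(f"unknown locus value(s): {sorted(unknown)}")

    # -- column access ---------------------------------------------------
    def has(self, column: str) -> bool:
        """True if ``column`` exists and is non-missing for >= 1 record."""
        return column in self.df.columns and self.df[column].notna().any()

    def column(self, name: str, dropna: bool = True) -> pd.Series:
        if name not in self.df.columns:
            raise AirrIOError(f"column {name!r} absent from table")
        s = self.df[name]
        return s.dropna() if dropna else s

    def capability(self) -> CapabilityLevel:
        return capability(self)

    def subset(self, index) -> "RepertoireTable":
        """Row subset (positional) preserving trees; no re-validation."""
        sub = RepertoireTable.__new__(RepertoireTable)
        sub.df = self.df.iloc[index].reset_index(drop=True)
        sub.trees = self.trees
        return sub


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in STRING_FIELDS:
        if col in df.columns:
            s = df[col].astype("string")
            s = s.replace("", pd.NA)
            if col not in ("clone_id",):
                s = s.str.upper()
            df[col] = s
    for col in INT_FIELDS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="raise").astype(
                "Int64"
            )
    for col in BOOL_FIELDS:
        if col in df.columns:
            df[col] = (
                df[col]
                .replace("", pd.NA)
                .map(
                    lambda v: v
                    if v is pd.NA or isinstance(v, bool)
                    else str(v).strip().upper() in ("T", "TRUE", "1"),
                    na_action="ignore",
                )
                .astype("boolean")
            )
    return df


# -- capability ----------------------------------------------------------

def capability(table: RepertoireTable) -> CapabilityLevel:
    """Highest post-processing level supported by the table's columns.

    Adding columns (or trees) never lowers the level.
    """
    level = CapabilityLevel.alignment_only
    if table.has("v_call") and table.has("j_call"):
        level = CapabilityLevel.annotated
    if table.has("clone_id"):
        level = CapabilityLevel.clustered
    if table.trees is not None and len(table.trees) > 0:
        level = CapabilityLevel.phylogenetic
    return level


# -- gene-call and gap normalization --------------------------------------

def normalize_gene_call(call: str, collapse_allele: bool = True) -> str:
    """Normalize an AIRR gene call to a single gene name.

    Comma-separated ambiguous calls keep only the first entry; the ``*NN``
    allele suffix is stripped (disable with ``collapse_allele=False``) so
    usage distributions are comparable across annotation tools.
    """
    first = call.split(",")[0].strip()
    if collapse_allele:
        first = _ALLELE_RE.sub("", first)
    return first


def degap(seq: str) -> str:
    """Strip IMGT gap characters ('.' and '-') from a sequence."""
    return "".join(c for c in seq if c not in _GAP_CHARS)


def degap_pair(a: str, b: str) -> tuple[str, str]:
    """Drop positions gapped in *either* aligned sequence, from both.

    Paired dropping preserves positional correspondence, so downstream
    mutation calls and distances are over nucleotides only.
    """
    if len(a) != len(b):
        raise AirrIOError("aligned sequences have unequal lengths")
    kept = [(x, y) for x, y in zip(a, b) if x not in _GAP_CHARS and y not in _GAP_CHARS]
    if not kept:
        return "", ""
    xs, ys = zip(*kept)
    return "".join(xs), "".join(ys)


# -- file I/O -------------------------------------------------------------

def read_airr(path: str | Path, locus: str = "auto") -> RepertoireTable:
    """Read an AIRR Rearrangement TSV into a :class:`RepertoireTable`.

    Recognized AIRR columns are mapped by exact name; unrecognized columns
    are preserved but ignored.  Empty strings become missing values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such AIRR file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise AirrIOError(f"{path}: no header row") from None
    if df.shape[1] == 0:
        raise AirrIOError(f"{path}: no header row")
    if len(df) == 0:
        raise AirrIOError(f"{path}: header but zero data rows")
    if locus != "auto":
        if locus not in LOCI:
            raise AirrIOError(f"unknown locus {locus!r}")
        df["locus"] = locus
    return RepertoireTable(df)


def write_airr(table: RepertoireTable, path: str | Path) -> None:
    """Write a table as AIRR Rearrangement TSV (round-trips recognized fields)."""
    df = table.df.copy()
    for col in BOOL_FIELDS:
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: "T" if v else "F", na_action="ignore"
            )
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_clone_trees(path: str | Path) -> CloneTreeSet:
    """Read a two-column ``clone_id<TAB>newick`` TSV into a CloneTreeSet."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such tree file: {path}")
    trees: dict[str, dendropy.Tree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            clone_id, newick = line.split("\t", 1)
            trees[clone_id] = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
    return CloneTreeSet(trees)
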