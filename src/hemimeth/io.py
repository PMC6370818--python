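"""Readers, writers and dyad assembly for strand-resolved methylation calls.

The pipeline's primary input dialect is the Bismark genome-wide cytosine
report: a headerless 7-column TSV with chromosome, 1-based position, strand,
methylated read count, unmethylated read count, cytosine context and
trinucleotide context.  A CpG dyad is the palindromic pair of cytosines at
positions ``p`` (plus strand) and ``p+1`` (minus strand); each strand is
measured independently by bisulfite reads, and their comparison is the basis
of the absolute methylation difference (AMD) statistic in :mod:`hemimeth.amd`.

Coordinate conventions: all file positions are 1-based (Bismark convention);
gene windows are stored as 1-based inclusive ``[window_start, window_end]``
intervals.  A dyad is addressed by its plus-strand cytosine position and
belongs to a gene window iff that position lies inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PLUS = "+"
MINUS = "-"

#: Columns of the in-memory per-strand call table.
CALL_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "depth", "level"]

#: Columns of the dyad table (written to / read from TSV).
DYAD_COLUMNS = [
    "chrom",
    "plus_pos",
    "plus_level",
    "minus_level",
    "plus_depth",
    "minus_depth",
    "amd",
    "plus_meth",
    "minus_meth",
]

#: Columns of the per-gene methylation profile table.
PROFILE_COLUMNS = [
    "gene_id",
    "n_cpg",
    "plus_mean",
    "minus_mean",
    "gene_level",
    "gene_amd",
    "total_depth",
]

#: Half-widths of the TSS window, in bases along the gene's orientation.
TSS_UPSTREAM = 1500
TSS_DOWNSTREAM = 2000


class CytosineReportError(ValueError):
    """Malformed cytosine report (wrong column count, bad values)."""


class ValidationError(ValueError):
    """Input rows violate a documented invariant (negative counts, bad strand)."""


@dataclass(frozen=True)
class CpGSiteCall:
    """One strand's measurement of a single cytosine."""

    chrom: str
    pos: int  # 1-based position of the C on its own strand
    strand: str  # "+" or "-"
    meth_count: int
    unmeth_count: int

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float | None:
        """Percent methylation; undefined (None) at zero depth."""
        d = self.depth
        if d == 0:
            return None
        return 100.0 * self.meth_count / d


@dataclass(frozen=True)
class CpGDyad:
    """Paired plus/minus measurements of one CpG."""

    chrom: str
    plus_pos: int
    plus_level: float
    minus_level: float
    plus_depth: int
    minus_depth: int

    @property
    def minus_pos(self) -> int:
        return self.plus_pos + 1

    @property
    def amd(self) -> float:
        return abs(self.plus_level - self.minus_level)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS and its strand-aware promoter window (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    @property
    def window(self) -> tuple[int, int]:
        if self.strand == PLUS:
            return self.tss - TSS_UPSTREAM, self.tss + TSS_DOWNSTREAM
        return self.tss - TSS_DOWNSTREAM, self.tss + TSS_UPSTREAM


@dataclass
class PairingStats:
    """Bookkeeping from :func:`pair_dyads`."""

    n_calls: int = 0
    n_zero_depth: int = 0
    n_under_covered: int = 0
    n_unpaired: int = 0
    n_dyads: int = 0


def _finalize_calls(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["depth"] = df["meth_count"] + df["unmeth_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["level"] = np.where(
            df["depth"] > 0, 100.0 * df["meth_count"] / df["depth"], np.nan
        )
    return df[CALL_COLUMNS]


def read_cytosine_report(path: str | Path, context_filter: str | None = "CpG") -> pd.DataFrame:
    """Read a Bismark cytosine report into a per-strand call table.

    Parameters
    ----------
    path:
        Tab-separated file with columns chrom, pos (1-based), strand,
        meth_count, unmeth_count, context, trinucleotide.
    context_filter:
        Keep only rows whose context matches.  ``"CpG"`` (default) accepts both
        the ``CpG`` and ``CG`` spellings Bismark variants emit; ``None`` keeps
        every row.

    Returns
    -------
    DataFrame with :data:`CALL_COLUMNS`, in input order.
    """
    path = Path(path)
    rows: list[tuple] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 6:
                raise CytosineReportError(
                    f"{path}: line {lineno}: expected >= 6 tab-separated columns, got {len(parts)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context = parts[:6]
            if strand not in (PLUS, MINUS):
                raise ValidationError(f"{path}: line {lineno}: unknown strand {strand!r}")
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise CytosineReportError(f"{path}: line {lineno}: non-integer field ({exc})")
            if meth < 0 or unmeth < 0:
                raise ValidationError(f"{path}: line {lineno}: negative read count")
            if context_filter is not None:
                ok = context == context_filter or (
                    context_filter == "CpG" and context in ("CG", "CpG")
                )
                if not ok:
                    continue
            rows.append((chrom, pos, strand, meth, unmeth))
    if n_lines == 0:
        logger.warning("cytosine report %s is empty", path)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth_count", "unmeth_count"])
    if df.empty:
        df = df.astype({"pos": np.int64, "meth_count": np.int64, "unmeth_count": np.int64})
    return _finalize_calls(df)


def calls_from_records(records: Iterable[CpGSiteCall]) -> pd.DataFrame:
    """Build a call table from :class:`CpGSiteCall` records."""
    df = pd.DataFrame(
        [(c.chrom, c.pos, c.strand, c.meth_count, c.unmeth_count) for c in records],
        columns=["chrom", "pos", "strand", "meth_count", "unmeth_count"],
    )
    return _finalize_calls(df)


def pair_dyads(
    calls: pd.DataFrame, min_depth: int = 5, stats: PairingStats | None = None
) -> pd.DataFrame:
    """Assemble CpG dyads from one sample's strand-resolved calls.

    A dyad is emitted iff a plus-strand call at position ``p`` and a
    minus-strand call at ``p+1`` both exist and both have depth >= min_depth
    (the depth filter is per strand: the AMD compares two independent
    measurements, each of which must be adequately sampled).  Zero-depth calls
    carry an undefined level and are dropped before pairing; unpaired and
    under-covered calls are tallied in *stats*.

    Raises
    ------
    ValidationError
        If two calls share the same (chrom, pos, strand).
    """
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    st = stats if stats is not None else PairingStats()
    st.n_calls = len(calls)
    dup = calls.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        first = calls.loc[dup, ["chrom", "pos", "strand"]].iloc[0]
        raise ValidationError(
            f"duplicate call at {first['chrom']}:{first['pos']} strand {first['strand']}"
        )
    live = calls[calls["depth"] > 0]
    st.n_zero_depth = len(calls) - len(live)
    covered = live[live["depth"] >= min_depth]
    st.n_under_covered = len(live) - len(covered)

    plus = covered[covered["strand"] == PLUS]
    minus = covered[covered["strand"] == MINUS].copy()
    minus["plus_pos"] = minus["pos"] - 1
    merged = plus.merge(
        minus,
        left_on=["chrom", "pos"],
        right_on=["chrom", "plus_pos"],
        suffixes=("_p", "_m"),
    )
    dyads = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "plus_pos": merged["pos_p"].astype(np.int64),
            "plus_level": merged["level_p"],
            "minus_level": merged["level_m"],
            "plus_depth": merged["depth_p"].astype(np.int64),
            "minus_depth": merged["depth_m"].astype(np.int64),
            "plus_meth": merged["meth_count_p"].astype(np.int64),
            "minus_meth": merged["meth_count_m"].astype(np.int64),
        }
    )
    dyads["amd"] = (dyads["plus_level"] - dyads["minus_level"]).abs()
    dyads = dyads[DYAD_COLUMNS].sort_values(["chrom", "plus_pos"], kind="stable")
    dyads = dyads.reset_index(drop=True)
    st.n_dyads = len(dyads)
    st.n_unpaired = len(covered) - 2 * len(dyads)
    return dyads


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene TSS table (TSV with header) or a BED6 file.

    The TSV dialect has columns ``gene_id, chrom, strand, tss`` with tss
    1-based.  In BED6 (chrom, start, end, name, score, strand; 0-based
    half-open) the TSS is the start for plus-strand genes and the end for
    minus-strand genes, converted to 1-based.

    Returns a DataFrame with gene_id, chrom, strand, tss, window_start,
    window_end (1-based inclusive, strand-aware: 1500 bases upstream through
    2000 downstream of the TSS along the gene's orientation).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "gene_id" in first:
        df = pd.read_csv(path, sep="\t")
        missing = {"gene_id", "chrom", "strand", "tss"} - set(df.columns)
        if missing:
            raise CytosineReportError(f"{path}: missing columns {sorted(missing)}")
        genes = df[["gene_id", "chrom", "strand", "tss"]].copy()
    else:
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        tss = np.where(bed["strand"] == PLUS, bed["start"] + 1, bed["end"])
        genes = pd.DataFrame(
            {
                "gene_id": bed["name"],
                "chrom": bed["chrom"],
                "strand": bed["strand"],
                "tss": tss.astype(np.int64),
            }
        )
    bad = ~genes["strand"].isin([PLUS, MINUS])
    if bad.any():
        sym = genes.loc[bad, "strand"].iloc[0]
        raise ValidationError(f"{path}: unknown strand symbol {sym!r}")
    genes["tss"] = genes["tss"].astype(np.int64)
    return add_windows(genes)


def add_windows(genes: pd.DataFrame) -> pd.DataFrame:
    """Attach strand-aware TSS windows (1-based inclusive) to a gene table."""
    genes = genes.copy()
    plus = genes["strand"] == PLUS
    genes["window_start"] = np.where(
        plus, genes["tss"] - TSS_UPSTREAM, genes["tss"] - TSS_DOWNSTREAM
    ).astype(np.int64)
    genes["window_end"] = np.where(
        plus, genes["tss"] + TSS_DOWNSTREAM, genes["tss"] + TSS_UPSTREAM
    ).astype(np.int64)
    return genes


def assign_dyads_to_genes(dyads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map dyads into gene TSS windows.

    Returns a long table with one row per (dyad, gene) membership: all dyad
    columns plus ``gene_id``.  A dyad belongs to a window iff its plus-strand
    position lies inside the 1-based inclusive window; overlapping windows
    each receive the dyad.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # half-open interval end: +1 to make the inclusive end queryable
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.window_start, row.window_end + 1, row.gene_id
        )
    out_idx: list[int] = []
    out_gene: list[str] = []
    for chrom, sub in dyads.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for idx, pos in zip(sub.index, sub["plus_pos"].to_numpy()):
            for iv in tree.at(int(pos)):
                out_idx.append(idx)
                out_gene.append(iv.data)
    assigned = dyads.loc[out_idx].copy()
    assigned["gene_id"] = out_gene
    return assigned.reset_index(drop=True)


def write_dyad_table(dyads: pd.DataFrame, path: str | Path) -> None:
    dyads.to_csv(path, sep="\t", index=False)


def read_dyad_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DYAD_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise CytosineReportError(f"{path}: dyad table missing columns {sorted(missing)}")
    return df


def write_profile_table(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_value_table(path: str | Path, value_col: str) -> pd.Series:
    """Read a two-column (gene_id, value) TSV into a Series keyed by gene."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or value_col not in df.columns:
        raise CytosineReportError(f"{path}: expected columns gene_id, {value_col}")
    return df.set_index("gene_id")[value_col]
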