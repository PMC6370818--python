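"""The absolute methylation difference (AMD) statistic and its sampling null.

A CpG dyad measured on both strands yields two methylation levels; their
absolute difference (the AMD, in percentage points) is sensitive to
hemi-methylation: a site methylated on exactly one strand in part of the cell
population pushes the two strand levels apart.  Finite sequencing depth also
pushes them apart, so the observed AMD is only meaningful against the AMD
expected from binomial read sampling alone.

The null model: if a site has true methylation ``p`` on both strands (no
hemi-methylation), the two strand measurements are independent
``X ~ Binomial(n1, p)`` and ``Y ~ Binomial(n2, p)`` read draws, and the
expected AMD is ``100 * E|X/n1 - Y/n2|``, computed here by exact enumeration
over the (n1+1)(n2+1) outcome grid — never by normal approximation, since
approximation error is precisely the kind of bias the statistic measures.

For a whole sample the null is aggregated over a 102-bin methylation scheme
({0}, (0,1], ..., (99,100), {100}): every dyad contributes its pooled level
(mean of the two strand levels) to the bin weights and its per-strand depth
pair to the expectation, and the aggregate null is the weight-summed
expectation.  Observed mean AMD minus this aggregate is the *AMD excess*; its
significance is assessed by a within-dyad read-reshuffling test (see
:func:`amd_excess`).

Gene-level AMDs average each strand over all dyads in the TSS window first and
difference the two strand means; the gene-level null treats the whole window
as one site whose depth is the summed depth, split evenly between two virtual
strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special

from .io import PROFILE_COLUMNS, assign_dyads_to_genes

N_BINS = 102  # {0}, (0,1], ..., (99,100), {100}


class NullModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binning


def meth_bin_index(levels: np.ndarray | float) -> np.ndarray:
    """Map methylation percentages to the 102-bin scheme.

    Bin 0 is exactly 0%, bin 101 exactly 100%, and bin k (1..100) is the
    open-closed interval (k-1, k].
    """
    lv = np.asarray(levels, dtype=float)
    if np.any((lv < 0) | (lv > 100)):
        raise ValueError("methylation levels must lie in [0, 100]")
    idx = np.ceil(lv).astype(np.int64)
    idx = np.where(lv == 0.0, 0, idx)
    idx = np.where(lv == 100.0, 101, idx)
    return idx


def meth_bin_representative(idx: np.ndarray | int) -> np.ndarray:
    """Representative methylation (percent) of each bin: 0, 0.5, ..., 99.5, 100."""
    ix = np.asarray(idx, dtype=float)
    rep = ix - 0.5
    rep = np.where(ix == 0, 0.0, rep)
    rep = np.where(ix == N_BINS - 1, 100.0, rep)
    return rep


# ---------------------------------------------------------------------------
# exact expectation


def _validate_depths(n1: int, n2: int) -> tuple[int, int]:
    for n in (n1, n2):
        if not float(n).is_integer() or n < 1:
            raise ValueError(f"depth must be a positive integer, got {n!r}")
    return int(n1), int(n2)


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial pmf over 0..n via log-gamma (stable for p arbitrarily near 0/1)."""
    k = np.arange(n + 1)
    if p == 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p == 1.0:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    logs = (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )
    return np.exp(logs)


@lru_cache(maxsize=200_000)
def _expectation_cached(n1: int, n2: int, p: float) -> float:
    x = np.arange(n1 + 1)
    y = np.arange(n2 + 1)
    px = _binom_pmf(n1, p)
    py = _binom_pmf(n2, p)
    diff = np.abs(x[:, None] / n1 - y[None, :] / n2)
    return float(100.0 * px @ diff @ py)


def exact_abs_mean_diff_expectation(n1: int, n2: int, p: float) -> float:
    """``100 * E|X/n1 - Y/n2|`` for independent X~Bin(n1,p), Y~Bin(n2,p).

    Exact enumeration over all (n1+1)(n2+1) outcome pairs weighted by the
    product of binomial pmfs.  Symmetric under (n1, n2) swap and p <-> 1-p;
    0 at p in {0, 1}; equals 200*p*(1-p) at n1 = n2 = 1.
    """
    n1, n2 = _validate_depths(n1, n2)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n2 < n1:  # canonical order for the cache
        n1, n2 = n2, n1
    return _expectation_cached(n1, n2, float(p))


# ---------------------------------------------------------------------------
# site-level statistics


def site_amd(plus_level, minus_level):
    """Per-site AMD: |plus level - minus level| in percentage points."""
    return np.abs(np.asarray(plus_level, dtype=float) - np.asarray(minus_level, dtype=float))


def pooled_level(dyads: pd.DataFrame) -> np.ndarray:
    """A dyad's single-site methylation estimate: mean of the strand levels."""
    return 0.5 * (dyads["plus_level"].to_numpy() + dyads["minus_level"].to_numpy())


@dataclass
class TheoreticalAMDNull:
    """Binomial-sampling expectation of the AMD, binned by methylation.

    ``table`` has one row per (bin, plus depth, minus depth) cell with the
    fraction of dyads in the cell and the exact expectation at the bin's
    representative methylation; ``aggregate`` is the weight-summed expectation
    over the whole sample.
    """

    table: pd.DataFrame  # bin, rep_level, plus_depth, minus_depth, weight, expectation
    aggregate: float

    def per_bin(self) -> pd.DataFrame:
        """Depth-weighted expectation per methylation bin."""
        t = self.table
        w = t.groupby("bin").apply(
            lambda g: np.average(g["expectation"], weights=g["weight"]),
            include_groups=False,
        )
        out = pd.DataFrame({"bin": w.index, "expectation": w.to_numpy()})
        out["rep_level"] = meth_bin_representative(out["bin"].to_numpy())
        out["weight"] = t.groupby("bin")["weight"].sum().to_numpy()
        return out.reset_index(drop=True)


def theoretical_site_null(dyads: pd.DataFrame) -> TheoreticalAMDNull:
    """Aggregate sampling-only AMD expectation for one sample's dyads.

    Each dyad is binned by its pooled level; within each (bin, depth pair)
    cell the expectation is computed once by exact enumeration at the bin's
    representative methylation (exactly 0 and 1 in the two point bins, where
    the expectation vanishes).
    """
    if len(dyads) == 0:
        raise NullModelError("cannot build a null from zero dyads")
    bins = meth_bin_index(pooled_level(dyads))
    cells = (
        pd.DataFrame(
            {
                "bin": bins,
                "plus_depth": dyads["plus_depth"].to_numpy(),
                "minus_depth": dyads["minus_depth"].to_numpy(),
            }
        )
        .groupby(["bin", "plus_depth", "minus_depth"])
        .size()
        .rename("count")
        .reset_index()
    )
    reps = meth_bin_representative(cells["bin"].to_numpy())
    exp = np.array(
        [
            exact_abs_mean_diff_expectation(int(n1), int(n2), rep / 100.0)
            for n1, n2, rep in zip(cells["plus_depth"], cells["minus_depth"], reps)
        ]
    )
    cells["rep_level"] = reps
    cells["weight"] = cells["count"] / cells["count"].sum()
    cells["expectation"] = exp
    aggregate = float(np.sum(cells["weight"] * cells["expectation"]))
    table = cells[["bin", "rep_level", "plus_depth", "minus_depth", "weight", "expectation"]]
    return TheoreticalAMDNull(table=table, aggregate=aggregate)


def expected_site_amd(dyads: pd.DataFrame) -> np.ndarray:
    """Per-dyad sampling-null AMD expectation (same convention as the table)."""
    bins = meth_bin_index(pooled_level(dyads))
    reps = meth_bin_representative(bins)
    return np.array(
        [
            exact_abs_mean_diff_expectation(int(n1), int(n2), rep / 100.0)
            for n1, n2, rep in zip(
                dyads["plus_depth"].to_numpy(), dyads["minus_depth"].to_numpy(), reps
            )
        ]
    )


@dataclass
class AMDExcessResult:
    observed_mean: float
    null_aggregate: float
    excess: float
    p_value: float
    n_dyads: int
    n_permutations: int
    per_bin: pd.DataFrame  # bin, rep_level, n, observed_mean, expectation, excess

    def to_dict(self) -> dict:
        return {
            "observed_mean_amd": self.observed_mean,
            "null_aggregate_amd": self.null_aggregate,
            "excess": self.excess,
            "p_value": self.p_value,
            "n_dyads": self.n_dyads,
            "n_permutations": self.n_permutations,
        }


def amd_excess(
    dyads: pd.DataFrame,
    null: TheoreticalAMDNull | None = None,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> AMDExcessResult:
    """Observed mean AMD minus the sampling-null aggregate, with a test.

    The one-sided test uses the exact conditional null of "two interchangeable
    measurements of one site": within each dyad the pooled reads are re-split
    between the strands by hypergeometric resampling conditional on the total
    methylated count (naive strand-label swapping leaves |plus - minus|
    unchanged, so re-splitting the reads is the exchangeable-null device).
    The empirical p-value is (1 + #{permuted mean >= observed mean}) /
    (n_permutations + 1).
    """
    if null is None:
        null = theoretical_site_null(dyads)
    obs = dyads["amd"].to_numpy(dtype=float)
    obs_mean = float(obs.mean())

    n1 = dyads["plus_depth"].to_numpy(dtype=np.int64)
    n2 = dyads["minus_depth"].to_numpy(dtype=np.int64)
    m = (dyads["plus_meth"] + dyads["minus_meth"]).to_numpy(dtype=np.int64)
    total = n1 + n2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.hypergeometric(m, total - m, n1, size=(n_permutations, len(dyads)))
    perm_amd = np.abs(draws / n1 - (m - draws) / n2) * 100.0
    perm_means = perm_amd.mean(axis=1)
    p = float((1 + np.sum(perm_means >= obs_mean)) / (n_permutations + 1))

    bins = meth_bin_index(pooled_level(dyads))
    obs_bin = (
        pd.DataFrame({"bin": bins, "amd": obs}).groupby("bin")["amd"].agg(["mean", "size"])
    )
    per_bin = null.per_bin().merge(
        obs_bin.rename(columns={"mean": "observed_mean", "size": "n"}), on="bin", how="left"
    )
    per_bin["excess"] = per_bin["observed_mean"] - per_bin["expectation"]

    return AMDExcessResult(
        observed_mean=obs_mean,
        null_aggregate=null.aggregate,
        excess=obs_mean - null.aggregate,
        p_value=p,
        n_dyads=len(dyads),
        n_permutations=n_permutations,
        per_bin=per_bin[["bin", "rep_level", "n", "observed_mean", "expectation", "excess"]],
    )


# ---------------------------------------------------------------------------
# gene-level statistics


def gene_profile(dyads_in_window: pd.DataFrame, gene_id: str) -> dict:
    """Profile one gene from the dyads inside its TSS window.

    Each strand's levels are averaged (unweighted) over the window's dyads
    first; the gene AMD is the absolute difference of the two strand means.
    An empty window yields an unmeasured profile (NaN means, n_cpg 0), never a
    zero.
    """
    n = len(dyads_in_window)
    if n == 0:
        return {
            "gene_id": gene_id,
            "n_cpg": 0,
            "plus_mean": np.nan,
            "minus_mean": np.nan,
            "gene_level": np.nan,
            "gene_amd": np.nan,
            "total_depth": 0,
        }
    d = dyads_in_window.drop_duplicates(subset=["chrom", "plus_pos"])
    pm = float(d["plus_level"].mean())
    mm = float(d["minus_level"].mean())
    return {
        "gene_id": gene_id,
        "n_cpg": len(d),
        "plus_mean": pm,
        "minus_mean": mm,
        "gene_level": 0.5 * (pm + mm),
        "gene_amd": abs(pm - mm),
        "total_depth": int((d["plus_depth"] + d["minus_depth"]).sum()),
    }


def gene_profiles(dyads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene methylation profiles over TSS windows (vectorised).

    Returns one row per gene in *genes*; genes with no measured dyad in their
    window appear with n_cpg 0 and NaN levels so downstream stages can exclude
    them explicitly.
    """
    assigned = assign_dyads_to_genes(dyads, genes)
    if len(assigned):
        assigned = assigned.drop_duplicates(subset=["gene_id", "chrom", "plus_pos"])
        grp = assigned.groupby("gene_id")
        agg = pd.DataFrame(
            {
                "n_cpg": grp.size(),
                "plus_mean": grp["plus_level"].mean(),
                "minus_mean": grp["minus_level"].mean(),
                "total_depth": (grp["plus_depth"].sum() + grp["minus_depth"].sum()),
            }
        )
    else:
        agg = pd.DataFrame(columns=["n_cpg", "plus_mean", "minus_mean", "total_depth"])
    out = genes[["gene_id"]].merge(agg, left_on="gene_id", right_index=True, how="left")
    out["n_cpg"] = out["n_cpg"].fillna(0).astype(np.int64)
    out["total_depth"] = out["total_depth"].fillna(0).astype(np.int64)
    out["gene_level"] = 0.5 * (out["plus_mean"] + out["minus_mean"])
    out["gene_amd"] = (out["plus_mean"] - out["minus_mean"]).abs()
    return out[PROFILE_COLUMNS]


def measured(profiles: pd.DataFrame, min_cpg: int = 1) -> pd.DataFrame:
    """Genes with at least *min_cpg* measured dyads in the window."""
    return profiles[profiles["n_cpg"] >= min_cpg].reset_index(drop=True)


def theoretical_gene_null(gene_level: float, total_depth: int) -> float:
    """Sampling-null AMD for a gene treated as one pooled CpG site.

    The window's summed depth is split evenly between two virtual strands
    (rounded to the nearest integer, at least 1 per strand) and the exact
    expectation is evaluated at the gene's mean methylation.
    """
    if total_depth < 2:
        raise NullModelError("gene null requires total_depth >= 2")
    n = max(1, int(round(total_depth / 2)))
    return exact_abs_mean_diff_expectation(n, n, gene_level / 100.0)


def combine_sample_amds(tables: dict[str, pd.Series]) -> pd.Series:
    """Average per-entity AMDs across samples (e.g. cell-cycle fractions).

    Entities missing from any sample are dropped (inner join); averaging is
    the plain arithmetic mean.
    """
    if not tables:
        raise ValueError("no AMD tables given")
    df = pd.DataFrame(tables).dropna()
    if len(df) == 0:
        raise ValueError("no entities shared by all samples")
    return df.mean(axis=1)


def hplc_methylation_fraction(dc_amount: float, mdc_amount: float) -> float:
    """Global 5mdC fraction from HPLC peak quantities: 100*5mdC/(dC + 5mdC)."""
    if dc_amount < 0 or mdc_amount < 0:
        raise ValueError("amounts must be non-negative")
    total = dc_amount + mdc_amount
    if total == 0:
        raise ValueError("dC and 5mdC amounts are both zero")
    return 100.0 * mdc_amount / total
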