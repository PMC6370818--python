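"""Condition comparisons: demethylation targets, overlap, AMD-response curves.

The experimental design behind these operations contrasts passive
demethylation (Dnmt1 knockdown: maintenance methylation fails at replication,
leaving hemi-methylated dyads) with active demethylation (Tet1: enzymatic
conversion of methylated cytosines, preferentially clearing hemi-methylated
dyads) across three systems (MEF, and reprogramming with or without vitamin
C).  All operations work on per-entity methylation levels (CpG dyads or
genes, in percent), drop missing entities pairwise, and are deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"


class ConditionError(KeyError):
    pass


class ConditionMatrix:
    """Per-entity methylation levels across (system, perturbation) conditions.

    Thin wrapper over a wide DataFrame whose index is the entity id and whose
    columns are (system, perturbation) pairs; NaN marks an unmeasured entity.
    """

    def __init__(self, wide: pd.DataFrame):
        if not isinstance(wide.columns, pd.MultiIndex):
            wide = wide.copy()
            wide.columns = pd.MultiIndex.from_tuples(wide.columns)
        self.wide = wide

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ConditionMatrix":
        """Build from a long table with entity, system, perturbation, level."""
        wide = long.pivot_table(
            index="entity", columns=["system", "perturbation"], values="level"
        )
        return cls(wide)

    def conditions(self) -> list[tuple[str, str]]:
        return list(self.wide.columns)

    def level(self, system: str, perturbation: str) -> pd.Series:
        key = (system, perturbation)
        if key not in self.wide.columns:
            raise ConditionError(f"condition {key!r} not present in matrix")
        return self.wide[key]


@dataclass
class OverlapStats:
    frac_a_in_b: float
    frac_b_in_a: float
    jaccard: float
    p_enrichment: float
    n_a: int
    n_b: int
    n_both: int
    n_universe: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def demethylation_delta(
    matrix: ConditionMatrix,
    system: str,
    perturbation: str,
    control: str = CONTROL,
) -> pd.Series:
    """Per-entity demethylation: control level minus perturbed level.

    Positive values mean demethylation.  Only entities measured in both
    conditions are returned.
    """
    ctrl = matrix.level(system, control)
    pert = matrix.level(system, perturbation)
    delta = (ctrl - pert).dropna()
    delta.name = "delta"
    return delta


def select_above_average(deltas: pd.Series) -> pd.Index:
    """Entities demethylated more than the table average (strict)."""
    if len(deltas) == 0:
        return pd.Index([])
    return deltas.index[deltas > deltas.mean()]


def overlap_stats(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    universe: Iterable[Hashable],
) -> OverlapStats:
    """Directional overlap fractions, Jaccard, and hypergeometric enrichment.

    The enrichment p-value is one-sided (over-representation of the overlap
    given set sizes within the universe).  The overlap fractions depend only
    on the two sets; the p-value also depends on the universe.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    both = a & b
    n_a, n_b, n_u, k = len(a), len(b), len(u), len(both)
    frac_a = k / n_a if n_a else float("nan")
    frac_b = k / n_b if n_b else float("nan")
    union = len(a | b)
    jacc = k / union if union else float("nan")
    p = float(stats.hypergeom.sf(k - 1, n_u, n_a, n_b)) if n_a and n_b else float("nan")
    return OverlapStats(frac_a, frac_b, jacc, p, n_a, n_b, k, n_u)


def consistent_targets(sets: Sequence[Iterable[Hashable]]) -> set:
    """Strict intersection of per-system target sets."""
    if len(sets) < 2:
        raise ValueError("need at least two sets to intersect")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


def delta_correlation(
    deltas_a: pd.Series, deltas_b: pd.Series, method: str = "pearson"
) -> CorrelationResult:
    """Correlation of two per-entity tables over their shared entities."""
    df = pd.concat({"a": deltas_a, "b": deltas_b}, axis=1).dropna()
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 shared entities")
    a, b = df["a"].to_numpy(), df["b"].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, method)
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), n, method)


def amd_response_curve(
    amds: pd.Series, deltas: pd.Series, n_groups: int = 14
) -> pd.DataFrame:
    """Demethylation as a function of AMD rank, in equal-count groups.

    Entities shared by both tables are sorted by (AMD, entity id) — the id
    tie-break keeps runs reproducible — and split into *n_groups* groups of
    near-equal size (any remainder spread over the first groups).  Returns
    per-group counts and means in ascending AMD order.
    """
    df = pd.concat({"amd": amds, "delta": deltas}, axis=1).dropna()
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > len(df):
        raise ValueError(f"n_groups={n_groups} exceeds {len(df)} shared entities")
    df = df.sort_index(kind="stable").sort_values("amd", kind="stable")
    parts = np.array_split(np.arange(len(df)), n_groups)
    rows = []
    for g, idx in enumerate(parts):
        sub = df.iloc[idx]
        rows.append(
            {
                "group": g + 1,
                "n": len(sub),
                "mean_amd": float(sub["amd"].mean()),
                "mean_delta": float(sub["delta"].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QuantileComparison:
    top_mean: float
    rest_mean: float
    difference: float
    p_value: float
    n_top: int
    n_rest: int


def top_quantile_comparison(
    amds: pd.Series, deltas: pd.Series, q: float = 0.2
) -> QuantileComparison:
    """Mean demethylation in the top-q AMD entities versus the rest.

    Two-sided Wilcoxon rank-sum p-value; ties in AMD broken by entity id so
    the split is deterministic.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    df = pd.concat({"amd": amds, "delta": deltas}, axis=1).dropna()
    df = df.sort_index(kind="stable").sort_values("amd", kind="stable", ascending=False)
    k = max(1, int(round(q * len(df))))
    top, rest = df.iloc[:k], df.iloc[k:]
    if len(rest) == 0:
        raise ValueError("q too large: no entities left in the comparison group")
    stat_p = stats.mannwhitneyu(top["delta"], rest["delta"], alternative="two-sided")
    return QuantileComparison(
        top_mean=float(top["delta"].mean()),
        rest_mean=float(rest["delta"].mean()),
        difference=float(top["delta"].mean() - rest["delta"].mean()),
        p_value=float(stat_p.pvalue),
        n_top=len(top),
        n_rest=len(rest),
    )


def hemi_abundance_change(
    amd_tables: Mapping[str, pd.Series],
    control: str = CONTROL,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Mean AMD per condition over shared entities, with paired tests.

    For each non-control condition the difference of means versus control is
    assessed by a paired sign-flip permutation test (two-sided) over the
    shared entities.
    """
    if control not in amd_tables:
        raise ConditionError(f"control condition {control!r} missing")
    df = pd.DataFrame(amd_tables).dropna()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    ctrl = df[control].to_numpy()
    for cond in df.columns:
        mean_amd = float(df[cond].mean())
        if cond == control:
            rows.append({"condition": cond, "mean_amd": mean_amd, "diff_vs_control": 0.0, "p_value": float("nan")})
            continue
        d = df[cond].to_numpy() - ctrl
        obs = abs(d.mean())
        flips = rng.choice([-1.0, 1.0], size=(n_permutations, len(d)))
        perm = np.abs((flips * d).mean(axis=1))
        p = float((1 + np.sum(perm >= obs)) / (n_permutations + 1))
        rows.append(
            {
                "condition": cond,
                "mean_amd": mean_amd,
                "diff_vs_control": float(d.mean()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def select_expression_responsive(log2fc: pd.Series) -> pd.Index:
    """Genes whose |log2 fold change| strictly exceeds the table mean."""
    fc = log2fc.dropna().abs()
    if len(fc) == 0:
        return pd.Index([])
    return fc.index[fc > fc.mean()]


@dataclass
class ExpressionCoupling:
    selected: pd.Index
    correlation: CorrelationResult


def expression_selection_and_correlation(
    deltas: pd.Series, log2fc: pd.Series, method: str = "pearson"
) -> ExpressionCoupling:
    """Select expression-responsive genes and correlate demethylation with
    expression change over the shared genes."""
    return ExpressionCoupling(
        selected=select_expression_responsive(log2fc),
        correlation=delta_correlation(deltas, log2fc, method=method),
    )
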