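"""Synthetic strand-resolved bisulfite data with known hemi-methylation truth.

Each CpG dyad is described by a population state vector over the four
strand-state combinations (``uu``, ``mu``, ``um``, ``mm``; first letter plus
strand, second minus strand, ``m`` methylated).  The plus-strand methylation
is ``f_mm + f_mu``, the minus-strand ``f_mm + f_um``, and the true AMD is
``100 * |f_mu - f_um|`` — the AMD sees hemi-methylation only through an
orientation imbalance, so the generator gives each dyad a coherent preferred
orientation (drawn with equal probability per dyad, hence balanced across the
genome) and places its hemi mass on that strand with concordance
``orientation_skew`` (default 1: fully coherent within a dyad).

Perturbation model (one round each):

* **Tet1** (active): each hemi dyad loses its methylated strand with
  probability ``r_hemi``; each fully methylated dyad loses each strand
  independently with probability ``r_full``.  Vitamin C multiplies ``r_full``
  by ``vc_full_multiplier`` and ``r_hemi`` by ``vc_hemi_multiplier`` (both
  clipped at 1).  Defaults r_hemi=0.40 and r_full=0.16 reproduce the observed
  preferential demethylation of hemi-methylated substrate (a ~40% drop of a
  pure-hemi pool versus ~16% of a fully methylated pool), and the vitamin-C
  multipliers (2.0 / 1.3) its stronger boost on fully methylated substrate.
* **sh-Dnmt1** (passive): one replication generation in which a fraction
  ``maintenance_failure`` of fully methylated dyads fail maintenance on the
  daughter strand and become hemi-methylated (oriented by the dyad's
  preferred orientation); hemi dyads are left intact.
* **control**: identity.

Read sampling is per strand: depth ~ Poisson(mean) (or fixed) and methylated
count ~ Binomial(depth, strand level), emitted in the Bismark cytosine-report
dialect.  Expression changes are coupled to true demethylation with a larger
gain for the active arm (``kappa_active`` > ``kappa_passive``), and
accessibility decreases with methylation and with hemi content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import DYAD_COLUMNS, add_windows

SYSTEMS = ("MEF", "OKMS-Vc-", "OKMS-Vc+")
PERTURBATIONS = ("control", "sh-Dnmt1", "Tet1")
GENE_CLASSES = ("background", "pluripotency_like", "emt_like")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class DyadStateVector:
    """Population fractions of the four strand states at one dyad."""

    f_uu: float
    f_mu: float
    f_um: float
    f_mm: float

    def __post_init__(self):
        vals = (self.f_uu, self.f_mu, self.f_um, self.f_mm)
        if any(v < -1e-12 for v in vals):
            raise SimulationError("state fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise SimulationError("state fractions must sum to 1")

    @property
    def plus_level(self) -> float:
        return 100.0 * (self.f_mm + self.f_mu)

    @property
    def minus_level(self) -> float:
        return 100.0 * (self.f_mm + self.f_um)

    @property
    def pooled_level(self) -> float:
        return 0.5 * (self.plus_level + self.minus_level)

    @property
    def true_amd(self) -> float:
        return 100.0 * abs(self.f_mu - self.f_um)

    @property
    def hemi_fraction(self) -> float:
        return self.f_mu + self.f_um

    def as_array(self) -> np.ndarray:
        return np.array([self.f_uu, self.f_mu, self.f_um, self.f_mm])


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    Rates are population fractions per perturbation round; levels are percent.
    The seed fully determines every output.
    """

    # genome layout
    n_genes: int = 1000
    class_mix: dict = field(
        default_factory=lambda: {
            "background": 0.85,
            "pluripotency_like": 0.10,
            "emt_like": 0.05,
        }
    )
    gene_spacing: int = 10_000  # bp between successive TSSs; windows never overlap

    # dyad-only simulations
    n_dyads: int = 10_000

    # read sampling
    depth_mean: float = 30.0
    depth_model: str = "poisson"  # or "fixed"

    # baseline biology
    background_hemi: float = 0.03  # replication-transient, orientation-incoherent
    background_hemi_rich_fraction: float = 0.15  # hemi-rich non-pluripotency promoters
    background_hemi_rich: float = 0.15
    background_uniform_fraction: float = 0.3  # rest of background is CpG-island-like low
    pluripotency_hemi: float = 0.30
    emt_hemi: float = 0.01
    orientation_skew: float = 1.0  # within-dyad hemi orientation coherence
    level_jitter_sd: float = 5.0  # per-dyad spread around the gene's level, percent

    # perturbation rates
    r_hemi: float = 0.40
    r_full: float = 0.16
    vc_full_multiplier: float = 2.0
    vc_hemi_multiplier: float = 1.3
    maintenance_failure: float = 0.30  # lambda: mm -> hemi per generation under sh-Dnmt1
    generations: int = 1  # perturbation rounds applied before measurement

    # expression / accessibility coupling
    kappa_active: float = 2.0
    kappa_passive: float = 0.5
    expression_noise_sd: float = 0.3
    acc_meth_weight: float = 1.0
    acc_hemi_weight: float = 1.0
    acc_noise_sd: float = 0.1

    seed: int = 0

    def validate(self) -> None:
        rates = {
            "r_hemi": self.r_hemi,
            "r_full": self.r_full,
            "maintenance_failure": self.maintenance_failure,
            "background_hemi": self.background_hemi,
            "pluripotency_hemi": self.pluripotency_hemi,
            "emt_hemi": self.emt_hemi,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.orientation_skew <= 1.0:
            raise SimulationError("orientation_skew must lie in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SimulationError("class_mix must sum to 1")
        if self.kappa_active < self.kappa_passive or self.kappa_passive < 0:
            raise SimulationError("require kappa_active >= kappa_passive >= 0")
        if self.depth_model not in ("poisson", "fixed"):
            raise SimulationError(f"unknown depth model {self.depth_model!r}")
        if self.generations < 1:
            raise SimulationError("generations must be >= 1")

    def effective_rates(self, vc: bool) -> tuple[float, float]:
        """(r_hemi, r_full) after the vitamin-C multipliers, clipped at 1."""
        if not vc:
            return self.r_hemi, self.r_full
        return (
            min(1.0, self.r_hemi * self.vc_hemi_multiplier),
            min(1.0, self.r_full * self.vc_full_multiplier),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# state construction and perturbation


def make_states(
    levels: np.ndarray,
    hemi: np.ndarray,
    orientation: np.ndarray,
    skew: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Build state vectors (n, 4: uu, mu, um, mm) from pooled levels (%),
    hemi fractions and per-dyad orientations (+1 favours mu, -1 favours um).

    The fully methylated fraction is ``level/100 - hemi/2`` (clipped at 0, so
    very low levels with large hemi raise the realised level to hemi/2).
    """
    levels = np.asarray(levels, dtype=float)
    hemi = np.asarray(hemi, dtype=float)
    orientation = np.asarray(orientation)
    major = hemi * (1.0 + skew) / 2.0
    minor = hemi - major
    f_mu = np.where(orientation > 0, major, minor)
    f_um = hemi - f_mu
    f_mm = np.clip(levels / 100.0 - hemi / 2.0, 0.0, 1.0 - hemi)
    f_uu = 1.0 - hemi - f_mm
    return np.column_stack([f_uu, f_mu, f_um, f_mm])


def _perturb_states(
    states: np.ndarray,
    perturbation: str,
    config: SimulationConfig,
    vc: bool = False,
    orientation: np.ndarray | None = None,
    generations: int = 1,
) -> np.ndarray:
    """Vectorised perturbation of (n, 4) state arrays over one or more rounds."""
    for _ in range(generations - 1):
        states = _perturb_states(states, perturbation, config, vc=vc, orientation=orientation)
    uu, mu, um, mm = states.T
    if perturbation == "control":
        return states.copy()
    if perturbation == "Tet1":
        r_h, r_f = config.effective_rates(vc)
        new_uu = uu + (mu + um) * r_h + mm * r_f**2
        new_mu = mu * (1 - r_h) + mm * r_f * (1 - r_f)
        new_um = um * (1 - r_h) + mm * (1 - r_f) * r_f
        new_mm = mm * (1 - r_f) ** 2
        return np.column_stack([new_uu, new_mu, new_um, new_mm])
    if perturbation == "sh-Dnmt1":
        lam = config.maintenance_failure
        fail = mm * lam
        if orientation is None:
            orientation = np.ones(len(states))
        major = fail * (1.0 + config.orientation_skew) / 2.0
        minor = fail - major
        to_mu = np.where(np.asarray(orientation) > 0, major, minor)
        to_um = fail - to_mu
        return np.column_stack([uu, mu + to_mu, um + to_um, mm - fail])
    raise SimulationError(f"unknown perturbation {perturbation!r}")


def apply_perturbation(
    state: DyadStateVector,
    perturbation: str,
    vc: bool = False,
    config: SimulationConfig | None = None,
    orientation: int = 1,
) -> DyadStateVector:
    """Single-dyad perturbation (see module docstring for the model)."""
    config = config or SimulationConfig()
    config.validate()
    out = _perturb_states(
        state.as_array()[None, :], perturbation, config, vc=vc,
        orientation=np.array([orientation]), generations=config.generations,
    )[0]
    return DyadStateVector(*out)


# ---------------------------------------------------------------------------
# read sampling


def simulate_reads(
    states: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample strand-resolved calls for (n, 4) states at dyad positions.

    Returns a call table in the :mod:`hemimeth.io` layout: one plus-strand
    row at the dyad position and one minus-strand row at position + 1 per
    dyad, with binomial methylated counts at the strand's true level and
    Poisson (or fixed) per-strand depth.
    """
    n = len(states)
    p_plus = states[:, 3] + states[:, 1]
    p_minus = states[:, 3] + states[:, 2]
    if config.depth_model == "poisson":
        d_plus = rng.poisson(config.depth_mean, size=n)
        d_minus = rng.poisson(config.depth_mean, size=n)
    else:
        d_plus = np.full(n, int(round(config.depth_mean)), dtype=np.int64)
        d_minus = d_plus.copy()
    m_plus = rng.binomial(d_plus, np.clip(p_plus, 0, 1))
    m_minus = rng.binomial(d_minus, np.clip(p_minus, 0, 1))
    calls = pd.DataFrame(
        {
            "chrom": np.concatenate([chroms, chroms]),
            "pos": np.concatenate([positions, positions + 1]).astype(np.int64),
            "strand": np.repeat(["+", "-"], n),
            "meth_count": np.concatenate([m_plus, m_minus]).astype(np.int64),
            "unmeth_count": np.concatenate(
                [d_plus - m_plus, d_minus - m_minus]
            ).astype(np.int64),
        }
    )
    calls["depth"] = calls["meth_count"] + calls["unmeth_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        calls["level"] = np.where(
            calls["depth"] > 0, 100.0 * calls["meth_count"] / calls["depth"], np.nan
        )
    return calls.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_cytosine_report(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls in the Bismark cytosine-report dialect (7 columns)."""
    out = calls[["chrom", "pos", "strand", "meth_count", "unmeth_count"]].copy()
    out["context"] = "CG"
    out["trinucleotide"] = "CGG"
    out.to_csv(path, sep="\t", index=False, header=False)


def dyads_from_states(
    states: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample reads and return the paired dyad table directly (no file I/O).

    Dyads whose sampled depth falls below 1 on either strand are dropped (no
    defined level); no further depth filter is applied here.
    """
    n = len(states)
    p_plus = states[:, 3] + states[:, 1]
    p_minus = states[:, 3] + states[:, 2]
    if config.depth_model == "poisson":
        d_plus = rng.poisson(config.depth_mean, size=n)
        d_minus = rng.poisson(config.depth_mean, size=n)
    else:
        d_plus = np.full(n, int(round(config.depth_mean)), dtype=np.int64)
        d_minus = d_plus.copy()
    m_plus = rng.binomial(np.maximum(d_plus, 0), np.clip(p_plus, 0, 1))
    m_minus = rng.binomial(np.maximum(d_minus, 0), np.clip(p_minus, 0, 1))
    keep = (d_plus > 0) & (d_minus > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        plus_level = 100.0 * m_plus / d_plus
        minus_level = 100.0 * m_minus / d_minus
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chroms)[keep],
            "plus_pos": np.asarray(positions)[keep].astype(np.int64),
            "plus_level": plus_level[keep],
            "minus_level": minus_level[keep],
            "plus_depth": d_plus[keep].astype(np.int64),
            "minus_depth": d_minus[keep].astype(np.int64),
            "plus_meth": m_plus[keep].astype(np.int64),
            "minus_meth": m_minus[keep].astype(np.int64),
        }
    )
    df["amd"] = (df["plus_level"] - df["minus_level"]).abs()
    df["dyad_index"] = np.flatnonzero(keep)
    return df[DYAD_COLUMNS + ["dyad_index"]]


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class StudyBundle:
    """In-memory result of :func:`simulate_study`.

    ``calls`` maps (system, perturbation) to a strand-resolved call table;
    ``truth`` carries the baseline per-dyad ground truth (states, hemi
    fraction, orientation, gene assignment); ``gene_truth`` the per-condition
    true gene levels; ``expression`` per-arm log2 fold changes;
    ``accessibility`` a per-gene openness score in the unperturbed state.
    """

    config: SimulationConfig
    genes: pd.DataFrame
    truth: pd.DataFrame
    gene_truth: pd.DataFrame
    calls: dict[tuple[str, str], pd.DataFrame]
    expression: pd.DataFrame
    accessibility: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as plain-text files plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth_dyads.tsv", sep="\t", index=False)
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        self.accessibility.to_csv(out / "accessibility.tsv", sep="\t", index=False)
        for (system, pert), calls in self.calls.items():
            name = f"calls_{system}_{pert}.CpG_report.txt".replace("/", "-")
            write_cytosine_report(calls, out / name)
        manifest = {"config": self.config.to_dict(), "seed": self.config.seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Draw gene classes, TSSs, and per-gene CpG dyad positions."""
    classes = rng.choice(
        list(config.class_mix), size=config.n_genes, p=list(config.class_mix.values())
    )
    strands = np.where(np.arange(config.n_genes) % 2 == 0, "+", "-")
    tss = 20_000 + np.arange(config.n_genes) * config.gene_spacing
    genes = add_windows(
        pd.DataFrame(
            {
                "gene_id": [f"g{i:05d}" for i in range(config.n_genes)],
                "chrom": "chrS",
                "strand": strands,
                "tss": tss.astype(np.int64),
                "gene_class": classes,
            }
        )
    )
    pos_list, gene_idx = [], []
    for i, row in enumerate(genes.itertuples(index=False)):
        lo, hi = row.window_start, row.window_end
        cls = row.gene_class
        if cls == "pluripotency_like":
            # spacings inside the 45-90 bp band; 3500/83..3500/45 keeps the
            # CpG count inside the 42-83 window band
            gaps = rng.uniform(45, 83, size=100)
        elif cls == "emt_like":
            gaps = rng.uniform(100, 250, size=60)
        else:
            gaps = rng.uniform(20, 300, size=200)
        pos = lo + 2 + np.cumsum(gaps).astype(np.int64)
        pos = pos[pos <= hi - 1]
        pos_list.append(pos)
        gene_idx.append(np.full(len(pos), i))
    if pos_list:
        positions = np.concatenate(pos_list)
        gene_idx = np.concatenate(gene_idx)
    else:
        positions = np.empty(0, dtype=np.int64)
        gene_idx = np.empty(0, dtype=np.int64)
    return genes, positions, gene_idx


def _baseline_truth(config, genes, positions, gene_idx, rng) -> pd.DataFrame:
    """Draw per-gene biology and expand it to per-dyad ground-truth states.

    Gene-level draws: pluripotency-like promoters sit at 40-60% methylation
    with a large, clonally coherent hemi fraction; EMT-like promoters are
    nearly fully methylated with almost no hemi; background promoters are
    mostly CpG-island-like (low methylation, Beta-shaped) with a uniform
    minority spanning the full range, and a small subset is hemi-rich.
    The hemi orientation is drawn once per gene (replication is locally
    coherent) and shared by its dyads; the background's replication-transient
    hemi is incoherent across cells and therefore carries no orientation
    skew, contributing depth noise but no true AMD.
    """
    n = len(positions)
    cls = genes["gene_class"].to_numpy()[gene_idx]
    gene_level = np.empty(config.n_genes)
    gene_hemi = np.empty(config.n_genes)
    gene_skew = np.empty(config.n_genes)
    gene_orient = rng.choice([-1, 1], size=config.n_genes)
    for i, c in enumerate(genes["gene_class"]):
        if c == "pluripotency_like":
            gene_level[i] = rng.uniform(40, 60)
            gene_hemi[i] = config.pluripotency_hemi
            gene_skew[i] = config.orientation_skew
        elif c == "emt_like":
            gene_level[i] = rng.uniform(88, 98)
            gene_hemi[i] = config.emt_hemi
            gene_skew[i] = config.orientation_skew
        else:
            if rng.random() < config.background_uniform_fraction:
                gene_level[i] = rng.uniform(2, 98)
            else:
                gene_level[i] = 100.0 * rng.beta(1.2, 6.0)
            if rng.random() < config.background_hemi_rich_fraction:
                gene_hemi[i] = config.background_hemi_rich
                gene_skew[i] = config.orientation_skew
            else:
                gene_hemi[i] = config.background_hemi
                gene_skew[i] = 0.0  # transient hemi: incoherent, no AMD
    level = np.clip(gene_level[gene_idx] + rng.normal(0, config.level_jitter_sd, n), 0.0, 100.0)
    hemi = gene_hemi[gene_idx]
    orientation = gene_orient[gene_idx]
    states = make_states(level, hemi, orientation, gene_skew[gene_idx])
    truth = pd.DataFrame(
        {
            "chrom": "chrS",
            "plus_pos": positions,
            "gene_id": genes["gene_id"].to_numpy()[gene_idx],
            "gene_class": cls,
            "f_uu": states[:, 0],
            "f_mu": states[:, 1],
            "f_um": states[:, 2],
            "f_mm": states[:, 3],
            "hemi_fraction": hemi,
            "orientation": orientation,
            "true_amd": 100.0 * np.abs(states[:, 1] - states[:, 2]),
        }
    )
    return truth


def simulate_study(
    config: SimulationConfig | None = None, write_dir: str | Path | None = None
) -> StudyBundle:
    """Generate the full three-system study with ground truth.

    Systems: MEF, OKMS-Vc-, OKMS-Vc+ (vitamin C active only in the last);
    perturbations: control, sh-Dnmt1, Tet1.  All systems share the same gene
    set and baseline truth; read sampling is independent per condition.
    """
    config = config or SimulationConfig()
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    layout_rng = np.random.default_rng(root_ss.spawn(1)[0])
    genes, positions, gene_idx = _gene_layout(config, layout_rng)
    truth = _baseline_truth(config, genes, positions, gene_idx, layout_rng)
    base_states = truth[["f_uu", "f_mu", "f_um", "f_mm"]].to_numpy()
    orientation = truth["orientation"].to_numpy()

    calls: dict[tuple[str, str], pd.DataFrame] = {}
    gene_truth_rows = []
    cond_seeds = root_ss.spawn(len(SYSTEMS) * len(PERTURBATIONS))
    k = 0
    for system in SYSTEMS:
        vc = system == "OKMS-Vc+"
        for pert in PERTURBATIONS:
            st = _perturb_states(
                base_states, pert, config, vc=vc, orientation=orientation,
                generations=config.generations,
            )
            rng = np.random.default_rng(cond_seeds[k]); k += 1
            calls[(system, pert)] = simulate_reads(st, positions, truth["chrom"].to_numpy(), config, rng)
            lv = pd.DataFrame(
                {
                    "gene_id": truth["gene_id"],
                    "level": 100.0 * (st[:, 3] + 0.5 * (st[:, 1] + st[:, 2])),
                    "hemi": st[:, 1] + st[:, 2],
                }
            ).groupby("gene_id", sort=False).mean()
            gene_truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": lv.index,
                        "system": system,
                        "perturbation": pert,
                        "true_level": lv["level"].to_numpy(),
                        "true_hemi": lv["hemi"].to_numpy(),
                    }
                )
            )
    gene_truth = pd.concat(gene_truth_rows, ignore_index=True)

    expr_rng = np.random.default_rng(root_ss.spawn(1)[0])
    expr_rows = []
    if len(gene_truth):
        wide = gene_truth.pivot_table(
            index="gene_id", columns=["system", "perturbation"], values="true_level"
        )
        for system in SYSTEMS:
            for pert in ("Tet1", "sh-Dnmt1"):
                delta = wide[(system, "control")] - wide[(system, pert)]
                kappa = config.kappa_active if pert == "Tet1" else config.kappa_passive
                fc = kappa * delta / 100.0 + expr_rng.normal(
                    0, config.expression_noise_sd, len(delta)
                )
                expr_rows.append(
                    pd.DataFrame(
                        {"gene_id": delta.index, "system": system, "perturbation": pert, "log2fc": fc}
                    )
                )
    expression = (
        pd.concat(expr_rows, ignore_index=True)
        if expr_rows
        else pd.DataFrame(columns=["gene_id", "system", "perturbation", "log2fc"])
    )

    acc_rng = np.random.default_rng(root_ss.spawn(1)[0])
    mef = gene_truth[(gene_truth["system"] == "MEF") & (gene_truth["perturbation"] == "control")]
    accessibility = pd.DataFrame(
        {
            "gene_id": mef["gene_id"].to_numpy(),
            "accessibility": (
                config.acc_meth_weight * (100.0 - mef["true_level"].to_numpy()) / 100.0
                - config.acc_hemi_weight * mef["true_hemi"].to_numpy()
                + acc_rng.normal(0, config.acc_noise_sd, len(mef))
            ),
        }
    )

    bundle = StudyBundle(
        config=config,
        genes=genes,
        truth=truth,
        gene_truth=gene_truth,
        calls=calls,
        expression=expression,
        accessibility=accessibility,
    )
    if write_dir is not None:
        bundle.write(write_dir)
    return bundle


def simulate_null_dyads(
    n_dyads: int,
    depth: float,
    seed: int | np.random.SeedSequence,
    levels: np.ndarray | None = None,
    hemi: float | np.ndarray = 0.0,
    skew: float = 1.0,
    depth_model: str = "fixed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience generator for dyad-level calibration experiments.

    Draws pooled levels (uniform on [0, 100] unless given), builds states at
    the requested hemi fraction and orientation skew, samples reads, and
    returns (dyads, truth).  With ``hemi=0`` this is an exact no-hemi null.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    if levels is None:
        levels = rng.uniform(0.0, 100.0, n_dyads)
    hemi_arr = np.broadcast_to(np.asarray(hemi, dtype=float), (n_dyads,))
    orientation = rng.choice([-1, 1], size=n_dyads)
    states = make_states(levels, hemi_arr, orientation, skew)
    cfg = SimulationConfig(depth_mean=depth, depth_model=depth_model)
    positions = 100 + 100 * np.arange(n_dyads)
    chroms = np.full(n_dyads, "chrS")
    dyads = dyads_from_states(states, positions, chroms, cfg, rng)
    truth = pd.DataFrame(
        {
            "plus_pos": positions,
            "true_level": np.asarray(levels, dtype=float),
            "hemi_fraction": hemi_arr,
            "orientation": orientation,
            "true_amd": 100.0 * np.abs(states[:, 1] - states[:, 2]),
        }
    )
    return dyads, truth
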