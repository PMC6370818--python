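"""Aggregate stage outputs from a run directory into one summary report."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _section_condition_means(run_dir: Path) -> dict | None:
    rows = {}
    for path in sorted(run_dir.glob("dyads_*.tsv")):
        name = path.stem[len("dyads_") :]
        df = pd.read_csv(path, sep="\t")
        if {"plus_level", "minus_level", "amd"} <= set(df.columns):
            rows[name] = {
                "mean_methylation": float(
                    (0.5 * (df["plus_level"] + df["minus_level"])).mean()
                ),
                "mean_amd": float(df["amd"].mean()),
                "n_dyads": int(len(df)),
            }
    return rows or None


def _section_json(run_dir: Path, pattern: str) -> dict | None:
    out = {}
    for path in sorted(run_dir.glob(pattern)):
        out[path.stem] = json.loads(path.read_text())
    return out or None


def _section_zones(run_dir: Path) -> dict | None:
    path = run_dir / "zones.tsv"
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    if "zone" not in df.columns:
        return None
    counts = df["zone"].value_counts().to_dict()
    return {str(k): int(v) for k, v in counts.items()}


def _section_selections(run_dir: Path) -> dict | None:
    out = {}
    for path in sorted(run_dir.glob("*.selection.txt")):
        with open(path) as fh:
            n = sum(1 for line in fh if line.strip())
        out[path.name[: -len(".selection.txt")]] = n
    return out or None


def build_report(run_dir: str | Path) -> dict:
    """Collect whatever stage outputs exist under *run_dir* into one dict."""
    run_dir = Path(run_dir)
    report: dict = {}
    sections = {
        "condition_means": _section_condition_means(run_dir),
        "amd_excess": _section_json(run_dir, "*.excess.json"),
        "overlap": _section_json(run_dir, "*.overlap.json"),
        "zone_counts": _section_zones(run_dir),
        "selection_sizes": _section_selections(run_dir),
    }
    for key, val in sections.items():
        if val is not None:
            report[key] = val
    return report


def render_markdown(report: dict) -> str:
    lines = ["# hemimeth run summary", ""]
    if "condition_means" in report:
        lines += ["## Mean methylation and AMD per condition", ""]
        lines += ["| condition | mean methylation (%) | mean AMD (pts) | dyads |", "|---|---|---|---|"]
        for cond, row in report["condition_means"].items():
            lines.append(
                f"| {cond} | {row['mean_methylation']:.2f} | {row['mean_amd']:.2f} | {row['n_dyads']} |"
            )
        lines.append("")
    if "amd_excess" in report:
        lines += ["## AMD excess over the sampling null", ""]
        for name, d in report["amd_excess"].items():
            lines.append(
                f"- {name}: observed {d.get('observed_mean_amd', float('nan')):.3f}, "
                f"null {d.get('null_aggregate_amd', float('nan')):.3f}, "
                f"excess {d.get('excess', float('nan')):.3f} (p = {d.get('p_value')})"
            )
        lines.append("")
    if "overlap" in report:
        lines += ["## Target-set overlap", ""]
        for name, d in report["overlap"].items():
            lines.append(
                f"- {name}: A-in-B {d.get('frac_a_in_b')}, B-in-A {d.get('frac_b_in_a')}, "
                f"Jaccard {d.get('jaccard')}, enrichment p {d.get('p_enrichment')}"
            )
        lines.append("")
    if "zone_counts" in report:
        lines += ["## Zone membership", ""]
        for zone, n in sorted(report["zone_counts"].items()):
            lines.append(f"- zone {zone}: {n} genes")
        lines.append("")
    if "selection_sizes" in report:
        lines += ["## Selection sizes", ""]
        for name, n in report["selection_sizes"].items():
            lines.append(f"- {name}: {n} genes")
        lines.append("")
    return "\n".join(lines) + "\n"
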