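"""Cohort report: summary tables and the assay's statistical tests.

Emits a human-readable ``report.md`` and a machine-readable
``stats.yaml`` from an analysis result: per-phase occupancy, viability
and secretion summaries (mean/SD and box-plot quartiles), the paired
Wilcoxon signed-rank comparisons between phases, and the drug-response
phenotype mix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .dynamics import RESPONSE_LABELS
from .stats import (DegenerateDataError, summary_stats, wilcoxon_signed_rank)

__all__ = ["build_report", "write_report"]


def build_report(result) -> dict:
    """Assemble the report payload from an AnalysisResult."""
    phases = list(result.secretion)
    out: dict = {"phases": {}, "tests": {}, "cohort": result.cohort,
                 "cohort_single_cell": result.cohort_single_cell}

    t0_obs = result.observations[phases[0]]
    counts = t0_obs["n_cells_detected"].to_numpy()
    out["occupancy_percent"] = {
        int(k): round(100.0 * (counts == k).mean(), 3) for k in range(4)}
    out["occupancy_percent"]["4_plus"] = round(
        100.0 * (counts >= 4).mean(), 3)

    for phase in phases:
        obs = result.observations[phase]
        live = int(obs["n_live"].sum())
        dead = int(obs["n_dead"].sum())
        sec = result.secretion[phase]
        secretors = sec.loc[sec["above_background"] & (sec["n_live"] >= 1),
                            "rate_pg_per_cell_day"].dropna()
        out["phases"][phase] = {
            "viability_percent": (100.0 * live / (live + dead)
                                  if live + dead else float("nan")),
            "n_live_cells": live,
            "n_dead_cells": dead,
            "background_mean": result.backgrounds[phase].mean_intensity,
            "background_sd": result.backgrounds[phase].sd_intensity,
            "registration": {
                "dx_um": result.transforms[phase].dx_um,
                "dy_um": result.transforms[phase].dy_um,
                "theta_deg": result.transforms[phase].theta_deg,
                "residual_um": result.transforms[phase].residual_um,
            },
            "secretion_pg_cell_day": (summary_stats(secretors)
                                      if len(secretors) else None),
        }

    # Paired secretion comparisons between consecutive phases, over wells
    # quantified and alive in both.
    for pa, pb in zip(phases, phases[1:]):
        a = result.secretion[pa].set_index("well_id")
        b = result.secretion[pb].set_index("well_id")
        common = a.index[(a["n_live"] >= 1) & (b["n_live"] >= 1)
                         & a["above_background"]]
        try:
            t = wilcoxon_signed_rank(
                a.loc[common, "rate_pg_per_cell_day"].to_numpy(),
                b.loc[common, "rate_pg_per_cell_day"].to_numpy())
            out["tests"][f"wilcoxon_{pa}_vs_{pb}"] = {
                "statistic": t.statistic, "p_value": t.p_value, "n": t.n,
                "method": t.method, "stars": t.stars}
        except (DegenerateDataError, ValueError) as exc:
            out["tests"][f"wilcoxon_{pa}_vs_{pb}"] = {"error": str(exc)}
    return out


def _fmt(v, nd=3):
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "--"
    return f"{v:.{nd}f}" if isinstance(v, float) else str(v)


def write_report(result, out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = build_report(result)

    lines = ["# Fluorospot cohort report", ""]
    lines += ["## Well occupancy (detected, t0)", "",
              "| cells/well | % of wells |", "|---|---|"]
    for k, v in payload["occupancy_percent"].items():
        lines.append(f"| {k} | {_fmt(float(v), 2)} |")
    lines += ["", "## Per-phase summary", "",
              "| phase | viability % | secretors mean (pg/cell/day) | SD |"
              " median | Q1 | Q3 |", "|---|---|---|---|---|---|---|"]
    for phase, ph in payload["phases"].items():
        s = ph["secretion_pg_cell_day"] or {}
        lines.append(
            f"| {phase} | {_fmt(ph['viability_percent'], 1)} | "
            f"{_fmt(s.get('mean'))} | {_fmt(s.get('sd'))} | "
            f"{_fmt(s.get('median'))} | {_fmt(s.get('q1'))} | "
            f"{_fmt(s.get('q3'))} |")
    lines += ["", "## Paired comparisons (Wilcoxon signed-rank)", ""]
    for name, t in payload["tests"].items():
        if "error" in t:
            lines.append(f"- {name}: not testable ({t['error']})")
        else:
            lines.append(f"- {name}: W = {_fmt(t['statistic'], 1)}, "
                         f"p = {t['p_value']:.3g} {t['stars']} (n = {t['n']})")
    if payload["cohort"]:
        lines += ["", "## Response phenotypes", ""]
        for lab in RESPONSE_LABELS:
            frac = payload["cohort"].get("response_fractions", {}).get(lab)
            if frac is not None:
                lines.append(f"- {lab}: {100 * frac:.2f}%")
        pc = payload["cohort"].get("mean_percent_change_t0_t1")
        if pc is not None and np.isfinite(pc):
            lines.append(f"- mean per-well percent change t0 -> t1: {pc:+.1f}%")
    md_path = out_dir / "report.md"
    md_path.write_text("\n".join(lines) + "\n")

    yaml_path = out_dir / "stats.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)
    return md_path, yaml_path


def _plain(obj):
    """YAML-safe copy (numpy scalars -> python, tuples -> lists)."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
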