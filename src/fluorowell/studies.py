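"""Round-trip cohort recovery studies.

The published cohort numbers are measurements of the authors' own cells,
so they cannot be recomputed from unreleased images; what can be checked
is parameter recovery: simulate a chip whose population preset is pinned
to the printed numbers, run the analysis pipeline on the rendered images
alone (no ground-truth access), and measure how well the cohort
statistics come back.  Each function here performs one such study at
full chip scale and returns the recovered quantities.
"""

from __future__ import annotations

import numpy as np

from .detection import cohort_viability, viability_per_well
from .geometry import ChipGeometry
from .pipeline import analyze_experiment
from .stats import wilcoxon_signed_rank
from .synthetic import SimulationConfig, simulate_experiment

__all__ = ["basal_rate_study", "occupancy_study", "paired_occupancy_study",
           "viability_study", "timecourse_study"]


def basal_rate_study(preset: str, seed: int,
                     geometry: ChipGeometry | None = None) -> dict:
    """Recover the basal per-cell secretion rate of a basal preset.

    Simulates t0, runs detection, registration, calibration fitting and
    quantification, and reports the mean rate over viable above-background
    single-cell wells plus the fraction of detected single cells called
    above background.
    """
    cfg = SimulationConfig(preset=preset, seed=seed,
                           geometry=geometry or ChipGeometry(),
                           phases=("t0",))
    exp = simulate_experiment(cfg)
    res = analyze_experiment(exp)
    sec = res.secretion["t0"]
    singles = sec[sec.n_live == 1]
    above = singles[singles.above_background]
    return {
        "mean_rate_pg_cell_day": float(above.rate_pg_per_cell_day.mean()),
        "above_background_pct": 100.0 * len(above) / len(singles),
        "n_single_cell_wells": int(len(singles)),
    }


def occupancy_study(seed: int, geometry: ChipGeometry | None = None) -> dict:
    """Recover the well-occupancy distribution from the t0 images.

    Counts live plus dead cells per well (the seeding image is taken
    before any treatment, and dead cells remain visible in the
    ethidium channel), and reports the percentage of wells at each count.
    """
    cfg = SimulationConfig(preset="lncap-basal", seed=seed,
                           geometry=geometry or ChipGeometry(),
                           phases=("t0",))
    exp = simulate_experiment(cfg)
    obs = viability_per_well(exp.images["t0"]["cell"],
                             exp.images["t0"]["dead"], exp.geometry)
    counts = np.array([o.n_cells_detected for o in obs])
    return {
        "pct_by_count": {k: 100.0 * float((counts == k).mean())
                         for k in range(4)},
        "n_wells": int(len(counts)),
    }


def paired_occupancy_study(seed: int,
                           geometry: ChipGeometry | None = None) -> dict:
    """One- vs two-cell wells: per-cell rates by detected occupancy.

    Runs the paired preset, groups wells by the detected live-cell
    count, and compares the two groups' per-cell rates with a Wilcoxon
    signed-rank test on randomly matched subsamples.
    """
    cfg = SimulationConfig(preset="lncap-paired", seed=seed,
                           geometry=geometry or ChipGeometry(),
                           phases=("t0",))
    exp = simulate_experiment(cfg)
    res = analyze_experiment(exp)
    sec = res.secretion["t0"]
    above = sec[sec.above_background]
    one = above.loc[above.n_live == 1, "rate_pg_per_cell_day"].to_numpy()
    two = above.loc[above.n_live == 2, "rate_pg_per_cell_day"].to_numpy()
    rng = np.random.default_rng(seed + 104729)
    n = min(len(one), len(two))
    pairs_a = rng.choice(one, size=n, replace=False)
    pairs_b = rng.choice(two, size=n, replace=False)
    test = wilcoxon_signed_rank(pairs_a, pairs_b)
    return {
        "mean_rate_single": float(one.mean()),
        "mean_rate_double": float(two.mean()),
        "n_single": int(len(one)),
        "n_double": int(len(two)),
        "wilcoxon_p": test.p_value,
    }


def viability_study(preset: str, seed: int,
                    geometry: ChipGeometry | None = None) -> dict:
    """Cohort viability at t2 from the rendered live/dead channels."""
    cfg = SimulationConfig(preset=preset, seed=seed,
                           geometry=geometry or ChipGeometry(),
                           phases=("t2",))
    exp = simulate_experiment(cfg)
    obs = viability_per_well(exp.images["t2"]["cell"],
                             exp.images["t2"]["dead"], exp.geometry,
                             phase="t2")
    n_cells = sum(o.n_cells_detected for o in obs)
    return {
        "viability_pct": cohort_viability(obs),
        "n_cells": int(n_cells),
    }


def timecourse_study(seed: int, geometry: ChipGeometry | None = None) -> dict:
    """Stimulation response on the time-course preset.

    Quantifies t0 and t1 against their registered membranes and reports
    the mean per-cell percent change among single-cell wells viable at
    both phases and above background at t0, plus the t0 secreting
    fraction among viable single cells.
    """
    cfg = SimulationConfig(preset="lncap-timecourse-enza", seed=seed,
                           geometry=geometry or ChipGeometry(),
                           phases=("t0", "t1"))
    exp = simulate_experiment(cfg)
    res = analyze_experiment(exp)
    cohort = res.cohort_single_cell
    return {
        "mean_percent_change_t0_t1": cohort["mean_percent_change_t0_t1"],
        "secreting_fraction_t0_pct":
            100.0 * cohort["phases"]["t0"]["secreting_fraction"],
        "n_wells": cohort["n_wells"],
    }
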