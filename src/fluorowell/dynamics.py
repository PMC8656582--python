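"""Per-well secretion time series across the three membranes, and
drug-response phenotyping.

Each well followed through the three 24 h phases yields a trajectory
(rate at t0, after androgen stimulation at t1, after anti-androgen
treatment at t2).  Trajectories are classified by two config-exposed
thresholds: a cell counts as stimulated when its t0 -> t1 fold change
reaches ``stim_fold_min`` (default 1.5x), and as inhibited when its
t1 -> t2 relative drop reaches ``drop_min`` (default 30%).  Stimulated
and inhibited = androgen-sensitive; stimulated but not inhibited =
resistant; never above background or unstimulated = insensitive/low
producer; dead by t2 = nonviable.  The thresholds sit between the
simulated effect sizes (2x stimulation, 85% inhibition) and the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PHASES

__all__ = ["SecretionTimeSeries", "ResponseClass", "ClassificationThresholds",
           "build_timeseries", "classify_response", "cohort_metrics"]

RESPONSE_LABELS = ("sensitive", "insensitive_low", "resistant",
                   "nonviable", "unclassified")


@dataclass(frozen=True)
class SecretionTimeSeries:
    """One well's three-phase record (rates in pg/cell/day)."""

    well_id: int
    n_cells: int
    rates: tuple[float, float, float]
    above_background: tuple[bool, bool, bool]
    alive: tuple[bool, bool, bool]
    drug_arm: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClassificationThresholds:
    stim_fold_min: float = 1.5
    drop_min: float = 0.30


@dataclass(frozen=True)
class ResponseClass:
    label: str
    fold_stim: float
    drop_inhib: float


def build_timeseries(secretion_tables: dict[str, pd.DataFrame],
                     observations: dict[str, pd.DataFrame],
                     duration_h: float = 24.0,
                     drug_arm: str = "") -> list[SecretionTimeSeries]:
    """Join per-phase quantification and detection into per-well series.

    ``secretion_tables[phase]`` needs columns well_id, mass_pg,
    above_background; ``observations[phase]`` needs well_id and n_live.
    One series is built per well with at least one live cell at t0.  The
    well universes of the three phases must agree (the membranes index
    the same physical chip); a missing phase is flagged on the series
    rather than imputed.
    """
    present = [p for p in PHASES if p in secretion_tables]
    if not present:
        raise ValueError("no quantified phases supplied")
    universe = None
    for p in present:
        wells = set(secretion_tables[p]["well_id"])
        if universe is None:
            universe = wells
        elif wells != universe:
            raise ValueError(
                f"phase {p!r} quantifies a different well universe "
                f"({len(wells)} vs {len(universe)} wells)")

    sec = {p: secretion_tables[p].set_index("well_id") for p in present}
    obs = {p: observations[p].set_index("well_id") for p in observations}
    t0_obs = obs["t0"]
    day = duration_h / 24.0

    series: list[SecretionTimeSeries] = []
    for well_id in sorted(universe):
        n0 = int(t0_obs.loc[well_id, "n_live"]) if well_id in t0_obs.index else 0
        if n0 < 1:
            continue
        rates, above, alive, flags = [], [], [], []
        for p in PHASES:
            if p not in sec:
                rates.append(float("nan"))
                above.append(False)
                alive.append(False)
                flags.append(f"missing_{p}")
                continue
            row = sec[p].loc[well_id]
            n_live = int(obs[p].loc[well_id, "n_live"]) if p in obs else n0
            alive.append(n_live >= 1)
            divisor = n_live if n_live >= 1 else n0
            rates.append(float(row["mass_pg"]) / divisor / day)
            above.append(bool(row["above_background"]))
        # death is permanent: once a phase reads no live cell, later
        # phases cannot count as alive
        alive = list(np.logical_and.accumulate(alive)) if "missing_t0" not in flags \
            else alive
        series.append(SecretionTimeSeries(
            well_id=int(well_id), n_cells=n0, rates=tuple(rates),
            above_background=tuple(above), alive=tuple(alive),
            drug_arm=drug_arm, flags=tuple(flags)))
    return series


def classify_response(series: SecretionTimeSeries,
                      thresholds: ClassificationThresholds | None = None
                      ) -> ResponseClass:
    """Label one trajectory; ``unclassified`` is the safety valve for
    trajectories the rule cannot place (e.g. undefined folds)."""
    th = thresholds or ClassificationThresholds()
    r0, r1, r2 = series.rates
    if r0 > 0:
        fold = r1 / r0
    else:
        fold = float("inf") if r1 > 0 else float("nan")
    drop = 1.0 - r2 / r1 if r1 > 0 else float("nan")

    if not series.alive[2]:
        label = "nonviable"
    elif (not series.above_background[0] and not series.above_background[1]) \
            or (np.isfinite(fold) and fold < th.stim_fold_min):
        label = "insensitive_low"
    elif fold >= th.stim_fold_min and np.isfinite(drop) and drop >= th.drop_min:
        label = "sensitive"
    elif fold >= th.stim_fold_min and np.isfinite(drop) and drop < th.drop_min:
        label = "resistant"
    else:
        label = "unclassified"
    return ResponseClass(label=label, fold_stim=float(fold), drop_inhib=float(drop))


def cohort_metrics(series_list: list[SecretionTimeSeries],
                   thresholds: ClassificationThresholds | None = None) -> dict:
    """Cohort summary across a list of well trajectories.

    Per phase: viable fraction, secreting fraction (above background
    among viable), and mean/SD rate among those secretors.  Across
    phases: the mean per-cell percent change t0 -> t1 over wells viable
    at both phases and above background at t0, and the response-label
    mix from :func:`classify_response`.
    """
    if not series_list:
        raise ValueError("cohort_metrics requires a non-empty cohort")
    n = len(series_list)
    out: dict = {"n_wells": n, "phases": {}}
    for k, phase in enumerate(PHASES):
        alive = np.array([s.alive[k] for s in series_list])
        above = np.array([s.above_background[k] for s in series_list])
        rates = np.array([s.rates[k] for s in series_list])
        secreting = alive & above
        sec_rates = rates[secreting]
        out["phases"][phase] = {
            "viable_fraction": float(alive.mean()),
            "secreting_fraction": float(secreting.sum() / alive.sum())
            if alive.any() else float("nan"),
            "mean_rate_secretors": float(sec_rates.mean()) if sec_rates.size else float("nan"),
            "sd_rate_secretors": float(sec_rates.std(ddof=1)) if sec_rates.size > 1 else 0.0,
        }

    sel = [s for s in series_list
           if s.alive[0] and s.alive[1] and s.above_background[0]
           and s.rates[0] > 0]
    if sel:
        changes = np.array([(s.rates[1] - s.rates[0]) / s.rates[0] * 100.0
                            for s in sel])
        out["mean_percent_change_t0_t1"] = float(changes.mean())
        out["n_percent_change"] = len(sel)
    else:
        out["mean_percent_change_t0_t1"] = float("nan")
        out["n_percent_change"] = 0

    labels = [classify_response(s, thresholds).label for s in series_list]
    out["response_fractions"] = {
        lab: labels.count(lab) / n for lab in RESPONSE_LABELS}
    return out
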