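"""Three-phase drug-response study: stimulation, inhibition, phenotypes.

Runs the full analysis on a time-course experiment (baseline, androgen
stimulation with R1881, anti-androgen treatment with enzalutamide),
builds per-well secretion trajectories, classifies each into
sensitive / insensitive-low / resistant / nonviable, and applies the
paired Wilcoxon signed-rank test between phases.
"""

from fluorowell import ChipGeometry, SimulationConfig, simulate_experiment
from fluorowell import wilcoxon_signed_rank
from fluorowell.pipeline import AnalysisParams, analyze_experiment

geometry = ChipGeometry(n_rows=20, n_cols=20, active_area_mm=(2.0, 2.0),
                        tile_grid=(2, 2))
config = SimulationConfig(preset="lncap-timecourse-enza", geometry=geometry,
                          seed=23)
experiment = simulate_experiment(config)
result = analyze_experiment(
    experiment, AnalysisParams(allow_fewer_empty=True,
                               min_registration_spots=20))

cohort = result.cohort_single_cell
t0 = cohort["phases"]["t0"]
print(f"secreting fraction at t0: {100 * t0['secreting_fraction']:.1f}% "
      "of viable single cells (preset: 53%)")
print(f"mean per-cell change t0 -> t1: "
      f"{cohort['mean_percent_change_t0_t1']:+.1f}% "
      "(androgen stimulation doubles ~91.5% of secretors)")
print("response phenotypes among single-cell wells:")
for label, frac in cohort["response_fractions"].items():
    print(f"  {label:16s} {100 * frac:5.1f}%")

a = result.secretion["t0"].set_index("well_id")
b = result.secretion["t1"].set_index("well_id")
wells = a.index[(a.n_live == 1) & (b.n_live >= 1) & a.above_background]
test = wilcoxon_signed_rank(a.loc[wells, "rate_pg_per_cell_day"],
                            b.loc[wells, "rate_pg_per_cell_day"])
print(f"Wilcoxon t0 vs t1: W={test.statistic:.0f}, p={test.p_value:.2e} "
      f"{test.stars} over {test.n} paired wells")
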