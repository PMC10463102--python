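"""End-to-end run: simulate a cohort, fit trajectory curves, project outcomes.

Runs the full pipeline on a 4000-patient synthetic cohort with 100 cluster
bootstraps and prints the cohort-level LDL-C reductions, the projected
absolute reduction in 4-year death incidence, and the NNT table.  Figures
(mean LDL-C curves and projected risk reductions) are written next to the
script output directory.
"""

from pathlib import Path

from lltproject import PipelineConfig, SimConfig, run_pipeline, simulate_cohort
from lltproject.plots import plot_risk_reduction, plot_trajectories

out_dir = Path("scratch/example_run")
cohort = simulate_cohort(SimConfig(n_patients=4000, seed=17))
config = PipelineConfig(seed=17, n_bootstrap=100)
result = run_pipeline(
    config, cohort.patients, cohort.labs, cohort.fills, cohort.events, out_dir=out_dir
)

print("exclusion flow:")
print(result.exclusion_report.to_string(index=False))

rs = result.reduction_summary.set_index(["timepoint", "quantity"])["est"]
print("\nprojected mean LDL-C reductions vs observed therapy (mg/dL):")
for tp in ("1y", "3y"):
    statin = rs.loc[(tp, "statin")]
    inc = rs.loc[(tp, "incremental_ez")]
    print(
        f"  {tp}: optimized statin {statin:5.1f};  + ezetimibe adds {inc:4.1f}"
        f"  (total {rs.loc[(tp, 'total')]:5.1f}, ratio {100 * rs.loc[(tp, 'ez_ratio')]:.1f}%)"
    )

p = result.projection
death = p[(p.outcome == "death") & (p.months.round() == 48)].set_index("scenario")
print("\n4-year death incidence:")
print(f"  observed: {100 * death.loc['opt_statin', 'observed_inc']:.2f}%")
for sc, label in (("opt_statin", "optimized statin"), ("opt_statin_ez", "+ ezetimibe")):
    r = death.loc[sc]
    print(
        f"  {label:<17}: projected {100 * r.projected_inc:.2f}%,"
        f" ARR {100 * r.arr:.2f}% (95% CI {100 * r.arr_lo:.2f}-{100 * r.arr_hi:.2f})"
    )

print("\nNNT to prevent one event (95% CI):")
print(result.nnt_table.to_string(index=False))

plot_trajectories(result.curves, out_dir / "ldl_curves.png")
plot_risk_reduction(result.projection, out_dir / "risk_reduction.png")
print(f"\nfigures and tables written to {out_dir}/")
print()
print("Reading the numbers: the ARR is the share of patients whose death")
print("within 4 years would be averted under the optimized regimen per the")
print("rate-ratio extrapolation; its reciprocal (rounded up) is the NNT.")
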