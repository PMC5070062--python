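"""A full simulated group study: 17 ASD vs 15 TD participants.

Simulates every session from the packaged calibrated presets, runs the event
and measure layers, gates each variable on Shapiro-Wilk normality, fits the
(rank) ANCOVA with the nonverbal developmental score as covariate and applies
Benjamini-Hochberg FDR within each task.  Writes the report bundle to
scratch/study/ and prints the transition rows of the group table.
"""

from pathlib import Path

from jagaze import StudyConfig, run_study

out = Path("scratch/study")
result = run_study(StudyConfig(out_dir=out, seed=42, n_asd=17, n_td=15))

print(f"usable trials: "
      + ", ".join(f"{r['group']} {r['mean']:.1f}±{r['std']:.1f}"
                  for _, r in result.usable_stats.iterrows()))

cols = ["task", "variable", "mean_ASD", "mean_TD", "F", "p", "eta2_partial",
        "ranked", "fdr_significant"]
rows = result.comparisons
rows = rows[rows["variable"].str.startswith(("trans_", "between", "norm_trans"))]
with __import__("pandas").option_context("display.width", 120):
    print(rows[cols].round(3).to_string(index=False))

print(f"\nreport bundle written to {out}/")
# Large-effect rows (eta2 > 0.14) that survive FDR mirror the initiating-JA
# group differences the generator was calibrated to produce; the RJA rows
# should stay non-significant.
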