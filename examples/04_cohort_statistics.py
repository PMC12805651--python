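"""Run a full synthetic study and summarize the cohort statistics.

Simulates the default cohort (2 control, 3 two-week, 3 three-week animals),
computes every animal's ventilation panel and mechanics battery, then fits
the one-way group model for respiratory-system compliance and correlates
each parameter with log10 tumor count.
"""

from xvlung.pipeline import RunConfig, build_study_table
from xvlung.stats import correlate_with_tumor_count, fit_group_model

config = RunConfig()
table = build_study_table(config, seed=1)

cols = ["animal_id", "group", "tumor_count", "msv", "nvdp_pct", "crs", "h"]
print(table[cols].round(4).to_string(index=False))

comp = fit_group_model(table, "crs")
print("\ncompliance (crs) marginal means with 95% CI:")
for g in comp.groups:
    lo, hi = comp.emmean_ci[g]
    print(f"  {g:>8s}: {comp.emmeans[g]:.4f}  [{lo:.4f}, {hi:.4f}]")
print("pairwise contrasts (Tukey-adjusted):")
for c in comp.contrasts:
    print(f"  {c['contrast']:>18s}: {c['estimate']:+.4f}  p_adj={c['p_adj']:.4f}")

for param in ("crs", "msv", "mean_ct_gray"):
    r = correlate_with_tumor_count(table, param)
    print(f"Pearson r({param} vs log10 tumor count) = {r.pearson_r:+.3f} "
          f"(p={r.p_value:.4f}, n={r.n_pairs})")
print(
    "\nThe 3-week group loses compliance and ventilation while gaining CT\n"
    "density; compliance correlates negatively and CT gray positively with\n"
    "tumor count, mirroring how increasing burden stiffens the lung."
)
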