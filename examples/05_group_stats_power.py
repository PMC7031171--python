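"""Age/sex mixed-model comparison and the Monte-Carlo sample-size estimate.

Simulates a cohort in which older subjects fatigue less (normalised
slopes -0.12 vs -0.21 %/s), fits the mixed model with age, sex and
test-day fixed effects and a subject random intercept, and prints the
Type-III F table, EMM contrasts and Cohen's d.  Then runs the power
simulation for five comparisons to reproduce a study-size calculation.
"""

from semgfatigue import CohortSpec, generate_cohort
from semgfatigue.group_stats import fit_group_model, power_simulation

spec = CohortSpec(n_per_group=50, seed=21)  # defaults: -0.21 young, -0.12 old
res = fit_group_model(generate_cohort(spec), "slope_norm")

print(res.anova.to_string(index=False))
print()
print(res.contrasts[["contrast", "estimate", "se", "p", "p_holm", "cohens_d"]]
      .to_string(index=False))

power = power_simulation(
    {"age": 0.5, "sex": 0.35, "age_x_sex": 0.4, "onset_age": 0.5, "onset_sex": 0.6},
    alpha=0.01,
    target_power=0.9,
    attrition_fraction=0.10,
    n_grid=list(range(100, 401, 20)),
    n_sims=400,
    seed=5,
)
print(f"\nrequired n/group for 90% power on all five comparisons at alpha 0.01: "
      f"{power.required_n}")
print(f"after 10% attrition inflation: {power.required_n_inflated}")
print("\nBonferroni-adjusted p values (family of 5) gate the main effects at")
print("p <= 0.01; Holm-adjusted subgroup contrasts localise any effect; d is")
print("the EMM difference over the model-implied between-subject SD.")
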