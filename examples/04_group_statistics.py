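"""Reproduce the reference cohort's summary statistics and run a rank-MANOVA.

First recomputes the published Welch t and rank-ANOVA F values from the
embedded summary tables, then runs the full rank-transform -> MANOVA path on
a freshly simulated cohort panel.
"""

import warnings

from tastepe import (CohortSpec, manova, rank_transform_panel,
                     simulate_cohort)
from tastepe.benchmarks import table1_reproduction, table2_reproduction
from tastepe.pipeline import fit_cohort_panel

t1 = table1_reproduction()
print("Welch t from printed summaries (control - AN):")
for scale in ("age", "harm_avoidance", "reward_dependence"):
    row = t1.loc[scale]
    print(f"  {scale:18s} t={row['t']:+.3f}  published {row['t_published']:+.3f}")

t2 = table2_reproduction()
row = t2.loc["caudate_head_R"]
print(f"right caudate rank-ANOVA: F={row['F']:.3f} (published {row['F_published']}),"
      f" eta_p^2={row['partial_eta2']:.3f}")

spec = CohortSpec(seed=42)
records = simulate_cohort(spec)
panel = fit_cohort_panel(records, spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ranked = rank_transform_panel(panel, columns=list(spec.roi_names))
res = manova(ranked, ranked["group"], roi_columns=list(spec.roi_names))
print(f"simulated cohort (n=108): Wilks lambda={res.wilks_lambda:.3f}, "
      f"partial eta^2={res.partial_eta2:.3f}, p={res.p_value:.2g}")
print(f"caudate_head_R follow-up: F={res.univariate.loc['caudate_head_R', 'F']:.1f},"
      f" Bonferroni p={res.univariate.loc['caudate_head_R', 'p_bonferroni']:.2g}")

# For two groups partial eta^2 equals 1 - lambda; the simulated AN-elevated
# caudate amplitude surfaces as a large Bonferroni-significant follow-up F.
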