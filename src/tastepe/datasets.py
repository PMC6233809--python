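"""Reference summary statistics for the adolescent anorexia-nervosa cohort.

Published group-level summaries for a cross-sectional taste-conditioning
study of 56 female adolescents/young adults with anorexia nervosa (AN) and 52
matched healthy controls: demographic and behavioral scale means (SD), and
rank-transformed prediction-error parameter-estimate means (SD) for the 18
reward-circuit regions of interest. These tables serve two purposes: they are
the calibration targets for the synthetic cohort generator, and they are the
inputs to the summary-statistic reproductions (Welch t, pooled rank-ANOVA F,
partial eta-squared).
"""

from __future__ import annotations

from tastepe.stats import SummaryStat

N_AN = 56
N_CONTROL = 52

#: Demographic/behavioral scales: name -> (AN SummaryStat, control SummaryStat,
#: published Welch t with the control-minus-AN contrast).
TABLE1: dict[str, tuple[SummaryStat, SummaryStat, float]] = {
    "age": (SummaryStat(56, 16.56, 2.47), SummaryStat(52, 16.01, 2.80), -1.078),
    "bmi": (SummaryStat(56, 15.88, 0.86), SummaryStat(52, 20.86, 2.07), 16.125),
    "bmi_percentile": (SummaryStat(56, 2.36, 2.63), SummaryStat(52, 58.57, 21.94), 17.081),
    "drive_for_thinness": (SummaryStat(56, 19.38, 7.13), SummaryStat(52, 2.13, 3.05), -16.422),
    "body_dissatisfaction": (SummaryStat(56, 24.76, 10.20), SummaryStat(52, 3.62, 4.32), -14.103),
    "punishment_sensitivity": (SummaryStat(56, 12.57, 4.02), SummaryStat(52, 5.54, 3.66), -9.481),
    "reward_sensitivity": (SummaryStat(56, 7.25, 3.83), SummaryStat(52, 6.65, 3.76), -0.815),
    "harm_avoidance": (SummaryStat(56, 21.98, 7.43), SummaryStat(52, 10.79, 4.80), -9.362),
    "reward_dependence": (SummaryStat(56, 14.64, 3.58), SummaryStat(52, 15.77, 3.67), 1.616),
    "breakfast_calories": (SummaryStat(56, 602.857, 145.42), SummaryStat(52, 568.75, 151.12), -1.195),
    "sucrose_sweetness": (SummaryStat(56, 8.00, 1.24), SummaryStat(52, 8.06, 1.07), 0.258),
}

#: Rank-transformed PE parameter estimates per ROI: name ->
#: (AN SummaryStat, control SummaryStat, published one-way F, published
#: partial eta-squared). The right-ventral-striatum row of the published
#: table duplicates another row's summaries and is internally inconsistent;
#: it is retained here but flagged.
TABLE2: dict[str, tuple[SummaryStat, SummaryStat, float, float]] = {
    "caudate_head_R": (SummaryStat(56, 67.179, 30.158), SummaryStat(52, 40.846, 26.660), 22.972, 0.178),
    "caudate_head_L": (SummaryStat(56, 67.786, 30.206), SummaryStat(52, 40.192, 25.917), 25.772, 0.196),
    "ventral_striatum_R": (SummaryStat(56, 57.232, 33.889), SummaryStat(52, 45.134, 27.793), 8.646, 0.075),
    "ventral_striatum_L": (SummaryStat(56, 62.750, 32.410), SummaryStat(52, 45.615, 27.752), 9.695, 0.084),
    "nucleus_accumbens_R": (SummaryStat(56, 66.196, 30.972), SummaryStat(52, 41.904, 26.678), 18.939, 0.152),
    "nucleus_accumbens_L": (SummaryStat(56, 65.857, 30.064), SummaryStat(52, 42.269, 28.094), 17.676, 0.143),
    "inferior_ofc_R": (SummaryStat(56, 61.804, 32.709), SummaryStat(52, 46.635, 27.977), 6.659, 0.059),
    "inferior_ofc_L": (SummaryStat(56, 59.161, 32.977), SummaryStat(52, 49.481, 28.911), 2.614, 0.024),
    "medial_ofc_R": (SummaryStat(56, 60.411, 33.670), SummaryStat(52, 48.135, 27.494), 4.269, 0.039),
    "medial_ofc_L": (SummaryStat(56, 59.804, 32.777), SummaryStat(52, 48.788, 28.904), 3.410, 0.031),
    "middle_ofc_R": (SummaryStat(56, 58.268, 32.302), SummaryStat(52, 50.442, 30.009), 1.694, 0.016),
    "middle_ofc_L": (SummaryStat(56, 57.661, 32.559), SummaryStat(52, 51.096, 29.869), 1.186, 0.011),
    "gyrus_rectus_R": (SummaryStat(56, 59.393, 32.503), SummaryStat(52, 49.231, 29.399), 5.953, 0.053),
    "gyrus_rectus_L": (SummaryStat(56, 57.607, 32.217), SummaryStat(52, 51.154, 30.279), 1.152, 0.011),
    "dorsal_anterior_insula_R": (SummaryStat(56, 60.339, 31.840), SummaryStat(52, 48.212, 29.784), 4.162, 0.038),
    "dorsal_anterior_insula_L": (SummaryStat(56, 58.732, 32.410), SummaryStat(52, 49.942, 29.742), 2.146, 0.020),
    "ventral_anterior_insula_R": (SummaryStat(56, 62.607, 32.984), SummaryStat(52, 45.769, 27.112), 8.326, 0.073),
    "ventral_anterior_insula_L": (SummaryStat(56, 57.232, 33.889), SummaryStat(52, 51.558, 28.331), 0.884, 0.008),
}

#: ROI rows whose published summaries are internally inconsistent (the right
#: ventral striatum duplicates the left ventral anterior insula summaries and
#: its F does not recompute from them); excluded from reproduction checks.
TABLE2_INCONSISTENT = ("ventral_striatum_R",)

#: Published multivariate group test (no covariates): Wilks lambda and
#: partial eta-squared over the 18-ROI panel.
MANOVA_WILKS_LAMBDA = 0.642
MANOVA_PARTIAL_ETA2 = 0.358

#: Weight-restoration summary for the AN group: age-adjusted BMI percentile
#: change mean (SD) over treatment days mean (SD), i.e. 0.51 percentile/day.
BMI_PERCENTILE_CHANGE = SummaryStat(56, 20.37, 15.12)
TREATMENT_DAYS = SummaryStat(56, 40.01, 10.94)

#: Salivary cortisol subset sizes (scan-day saliva sampling).
N_CORTISOL_AN = 20
N_CORTISOL_CONTROL = 25
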