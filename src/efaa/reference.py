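"""Published group-level summary values for the mild-TBI FAA study design
that this package models.

These constants serve two roles: they are the default effect sizes of the
synthetic cohort generator, and they are the inputs to the arithmetic
self-checks (``efaa reproduce-table1``) that verify the internal identities
of the asymmetry indices — mean FAA = mean ln(F4) − mean ln(F3), and
mean eFAA = mean FAA(threat) − mean FAA(neutral).

Groups: healthy controls, mild-TBI without current post-concussion symptoms
(NonSymp) and mild-TBI with symptoms (Symp).
"""

GROUP_SIZES = {"Control": 17, "NonSymp": 12, "Symp": 15}

#: group-mean FAA (ln-ratio) per emotion condition
GROUP_FAA = {
    "Control": {"neutral": 0.057, "threat": 0.060},
    "NonSymp": {"neutral": -0.215, "threat": -0.194},
    "Symp": {"neutral": -0.135, "threat": -0.154},
}

#: group-mean eFAA = FAA(threat) − FAA(neutral)
GROUP_EFAA = {"Control": 0.003, "NonSymp": 0.021, "Symp": -0.019}

#: group-mean log alpha power (ln µV²-scale) at (F4, F3) per emotion
GROUP_LN_POWER = {
    ("Control", "neutral"): (0.788, 0.732),
    ("Control", "threat"): (0.798, 0.738),
    ("NonSymp", "neutral"): (1.180, 1.395),
    ("NonSymp", "threat"): (1.189, 1.383),
    ("Symp", "neutral"): (0.549, 0.684),
    ("Symp", "threat"): (0.545, 0.699),
}

#: rows of GROUP_LN_POWER whose printed FAA column is exact at 3 decimals
LN_EXACT_ROWS = (
    ("NonSymp", "neutral"),
    ("NonSymp", "threat"),
    ("Symp", "neutral"),
    ("Symp", "threat"),
    ("Control", "threat"),
)

#: pooled overall-FAA moments used by the reported mean ± 2.5·SD outlier rule
POOLED_FAA_MEAN = -0.14
POOLED_FAA_SD = 0.41
OUTLIER_K = 2.5
OUTLIER_BOUNDS = (-1.165, 0.885)

#: reported Spearman couplings of eFAA with questionnaire/clinical scores
COUPLING = {"bdi": -0.52, "rpq": -0.34, "pta_hours": 0.41}

#: between-subject spread (SD of overall FAA / of eFAA), group-typical
FAA_SUBJECT_SD = 0.30
EFAA_SUBJECT_SD = 0.03

#: group age distributions (mean, SD) in years
AGE = {"Control": (40.7, 12.1), "NonSymp": (41.1, 11.1), "Symp": (41.1, 11.1)}

#: months from injury to recording (mean, SD, min, max), mild-TBI groups
MONTHS_POST_INJURY = (20.4, 6.9, 9.0, 37.0)
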