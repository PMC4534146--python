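"""Published summary counts from a cross-sectional DCIS case-control study.

These constants transcribe the printed summary tables of a 280-sample
tissue-microarray study of ductal carcinoma in situ (122 samples of DCIS
with no invasive component over long follow-up, 158 samples of DCIS with
concurrent invasive breast carcinoma; 271 unique patients).  They serve two
purposes: default parameters for the synthetic cohort generator, and frozen
inputs/expected values for the diagnostic and association stages, whose
printed statistics are reproduced exactly from these counts.

Counts are stored as ``(all, dcis_only, dcis_ibc)`` triples unless noted.
"""

from __future__ import annotations

import pandas as pd

from .calling import LOCI

N_SAMPLES = 280
N_DCIS_ONLY = 122
N_DCIS_IBC = 158

# ---------------------------------------------------------------------------
# Per-locus and combination gain prevalence (counts of samples)
# status -> (all, dcis_only, dcis_ibc)

LOCUS_GAIN_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "1q": {"no_signal": (80, 35, 45), "no": (96, 49, 47), "yes": (104, 38, 66)},
    "8q24": {"no_signal": (63, 27, 36), "no": (121, 63, 58), "yes": (96, 32, 64)},
    "11q13": {"no_signal": (74, 32, 42), "no": (143, 71, 72), "yes": (63, 19, 44)},
    "HER2": {"no_signal": (0, 0, 0), "no": (188, 84, 104), "yes": (92, 38, 54)},
}

COMBO_GAIN_COUNTS: dict[tuple[str, ...], dict[str, tuple[int, int, int]]] = {
    ("1q", "8q24"): {"no_signal": (94, 43, 51), "no": (133, 63, 70), "yes": (53, 16, 37)},
    ("1q", "11q13"): {"no_signal": (108, 46, 62), "no": (138, 67, 71), "yes": (34, 9, 25)},
    ("1q", "HER2"): {"no_signal": (80, 35, 45), "no": (145, 66, 79), "yes": (55, 21, 34)},
    ("8q24", "11q13"): {"no_signal": (87, 37, 50), "no": (159, 78, 81), "yes": (34, 7, 27)},
    ("8q24", "HER2"): {"no_signal": (63, 27, 36), "no": (163, 74, 89), "yes": (54, 21, 33)},
    ("11q13", "HER2"): {"no_signal": (74, 32, 42), "no": (165, 78, 87), "yes": (41, 12, 29)},
    ("1q", "8q24", "11q13"): {"no_signal": (112, 49, 63), "no": (146, 68, 78), "yes": (22, 5, 17)},
    ("1q", "8q24", "HER2"): {"no_signal": (94, 43, 51), "no": (150, 66, 84), "yes": (36, 13, 23)},
    ("1q", "11q13", "HER2"): {"no_signal": (105, 44, 61), "no": (140, 68, 72), "yes": (35, 10, 25)},
    ("1q", "8q24", "11q13", "HER2"): {"no_signal": (112, 49, 63), "no": (148, 68, 80), "yes": (20, 5, 15)},
}

#: Mutually exclusive six-level category (plus unable-to-determine):
#: category -> (all, dcis_only, dcis_ibc)
CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "unable_to_determine": (112, 49, 63),
    "no_gains": (43, 29, 14),
    "only_1q": (31, 15, 16),
    "only_8q24": (19, 8, 11),
    "only_11q13": (8, 4, 4),
    "two_of_three": (45, 12, 33),
    "all_three": (22, 5, 17),
}

#: Share of gained samples with low-level gain (1–2 extra copies) per locus,
#: from the study's descriptive results; HER2 not reported, taken as 1q-like.
LOW_GAIN_SHARE: dict[str, float] = {"1q": 0.80, "8q24": 0.78, "11q13": 0.53, "HER2": 0.80}

# ---------------------------------------------------------------------------
# Diagnostic-performance fixtures: per-marker 2x2 counts against the
# invasive label, marker-positive = all member loci gained, no_signal
# samples excluded.  Column order follows the printed layout.

DIAGNOSTIC_MARKERS: tuple[tuple[str, ...], ...] = (
    ("1q",),
    ("8q24",),
    ("11q13",),
    ("HER2",),
    ("1q", "8q24"),
    ("1q", "11q13"),
    ("1q", "HER2"),
    ("8q24", "11q13"),
    ("8q24", "HER2"),
    ("11q13", "HER2"),
    ("1q", "8q24", "11q13"),
    ("1q", "8q24", "11q13", "HER2"),
)

#: marker -> (tp, fp, fn, tn); tp = gained with IBC, fp = gained DCIS-only.
DIAGNOSTIC_COUNTS: dict[tuple[str, ...], tuple[int, int, int, int]] = {
    ("1q",): (66, 38, 47, 49),
    ("8q24",): (64, 32, 58, 63),
    ("11q13",): (44, 19, 72, 71),
    ("HER2",): (54, 38, 104, 84),
    ("1q", "8q24"): (37, 16, 70, 63),
    ("1q", "11q13"): (25, 9, 71, 67),
    ("1q", "HER2"): (34, 21, 79, 66),
    ("8q24", "11q13"): (27, 7, 81, 78),
    ("8q24", "HER2"): (33, 21, 89, 74),
    ("11q13", "HER2"): (29, 12, 87, 78),
    ("1q", "8q24", "11q13"): (17, 5, 78, 68),
    ("1q", "8q24", "11q13", "HER2"): (15, 5, 80, 68),
}

#: Printed performance statistics per marker:
#: (sensitivity, specificity, ppv, npv, fisher_p) — percentages to 3 dp.
DIAGNOSTIC_PRINTED: dict[tuple[str, ...], tuple[float, float, float, float, float]] = {
    ("1q",): (58.407, 56.322, 63.462, 51.042, 0.046),
    ("8q24",): (52.459, 66.316, 66.667, 52.066, 0.006),
    ("11q13",): (37.931, 78.889, 69.841, 49.650, 0.010),
    ("HER2",): (34.177, 68.852, 58.696, 44.681, 0.610),
    ("1q", "8q24"): (34.579, 79.747, 69.811, 47.368, 0.034),
    ("1q", "11q13"): (26.042, 88.158, 73.529, 48.551, 0.022),
    ("1q", "HER2"): (30.088, 75.862, 61.818, 45.517, 0.425),
    ("8q24", "11q13"): (25.0, 91.765, 79.412, 49.057, 0.002),
    ("8q24", "HER2"): (27.049, 77.895, 61.111, 45.399, 0.432),
    ("11q13", "HER2"): (25.0, 86.667, 70.732, 47.273, 0.052),
    ("1q", "8q24", "11q13"): (17.895, 93.151, 77.273, 46.575, 0.040),
    ("1q", "8q24", "11q13", "HER2"): (15.789, 93.151, 75.000, 45.946, 0.094),
}

#: Printed univariate odds ratios (OR, ci_low, ci_high) by gain category,
#: reference = no_gains.
UNIVARIATE_OR_PRINTED: dict[str, tuple[float, float, float]] = {
    "only_1q": (2.21, 0.85, 5.71),
    "only_8q24": (2.85, 0.94, 8.66),
    "only_11q13": (2.07, 0.45, 9.52),
    "two_of_three": (5.70, 2.27, 14.27),
    "all_three": (7.04, 2.16, 23.00),
}

#: Printed multivariable (complete-case, n=158) odds ratios for the gain
#: category.  NOT reproducible from summary counts (requires the raw
#: patient-level covariates); kept for reference only and exercised solely
#: through synthetic parameter-recovery simulations.
MULTIVARIABLE_OR_PRINTED: dict[str, tuple[float, float, float]] = {
    "only_1q": (1.96, 0.68, 5.67),
    "only_8q24": (4.23, 1.15, 15.50),
    "only_11q13": (2.51, 0.42, 15.00),
    "two_of_three": (9.07, 2.93, 28.11),
    "all_three": (17.96, 3.92, 82.24),
}

# ---------------------------------------------------------------------------
# Patient characteristics (271 patients) — covariate marginals used as
# synthetic-generator defaults.  category -> count (missing listed where
# reported).

COVARIATE_MARGINALS: dict[str, dict[str, int]] = {
    "age_group": {"<40": 24, "40-49": 90, "50-64": 90, ">=65": 67},
    "race": {
        "nh_white": 199,
        "nh_api": 53,
        "hispanic": 10,
        "nh_black": 4,
        "missing": 5,
    },
    "hr_status": {"positive": 137, "negative": 122, "missing": 12},
    "grade": {"1": 56, "2": 130, "3": 83, "missing": 2},
}


def default_state_probs() -> dict[str, dict[str, dict[str, float]]]:
    """Per-group, per-locus true-state probabilities from the prevalence counts.

    Gained samples are split between low and high gain states using the
    study's reported low-gain shares; ``no`` samples are disomic and
    ``no_signal`` samples are assay failures.
    """
    totals = {"dcis_only": N_DCIS_ONLY, "dcis_ibc": N_DCIS_IBC}
    out: dict[str, dict[str, dict[str, float]]] = {}
    for gi, group in enumerate(("dcis_only", "dcis_ibc"), start=1):
        out[group] = {}
        for locus in LOCI:
            c = LOCUS_GAIN_COUNTS[locus]
            n = totals[group]
            p_fail = c["no_signal"][gi] / n
            p_gain = c["yes"][gi] / n
            low = LOW_GAIN_SHARE[locus]
            out[group][locus] = {
                "assay_failure": p_fail,
                "disomy": 1.0 - p_fail - p_gain,
                "low_gain": p_gain * low,
                "high_gain": p_gain * (1.0 - low),
            }
    return out


def locus_status_profiles() -> pd.DataFrame:
    """Per-sample locus statuses realizing the published per-locus margins.

    Loci are assigned independently (the published joint distribution is not
    recoverable from margins), so single-locus tabulations match the printed
    counts exactly while combination rows need not.  Group sizes are exact.
    """
    rows = []
    for gi, (group, n) in enumerate(
        (("dcis_only", N_DCIS_ONLY), ("dcis_ibc", N_DCIS_IBC)), start=1
    ):
        statuses = {}
        for locus in LOCI:
            c = LOCUS_GAIN_COUNTS[locus]
            col = (
                ["no_signal"] * c["no_signal"][gi]
                + ["no_gain"] * c["no"][gi]
                + ["gain"] * c["yes"][gi]
            )
            assert len(col) == n, (locus, group)
            statuses[locus] = col
        for i in range(n):
            rows.append(
                {"sample_id": f"{group}_{i:03d}", "group": group}
                | {locus: statuses[locus][i] for locus in LOCI}
            )
    return pd.DataFrame(rows)


def category_profiles() -> pd.DataFrame:
    """Per-sample locus statuses realizing the published mutually exclusive
    category counts (one canonical status vector per category)."""
    realization = {
        "unable_to_determine": {"1q": "no_signal", "8q24": "no_signal", "11q13": "no_signal"},
        "no_gains": {"1q": "no_gain", "8q24": "no_gain", "11q13": "no_gain"},
        "only_1q": {"1q": "gain", "8q24": "no_gain", "11q13": "no_gain"},
        "only_8q24": {"1q": "no_gain", "8q24": "gain", "11q13": "no_gain"},
        "only_11q13": {"1q": "no_gain", "8q24": "no_gain", "11q13": "gain"},
        "two_of_three": {"1q": "gain", "8q24": "gain", "11q13": "no_gain"},
        "all_three": {"1q": "gain", "8q24": "gain", "11q13": "gain"},
    }
    rows = []
    k = 0
    for gi, group in enumerate(("dcis_only", "dcis_ibc"), start=1):
        for category, counts in CATEGORY_COUNTS.items():
            for _ in range(counts[gi]):
                rows.append(
                    {"sample_id": f"s{k:03d}", "group": group, "HER2": "no_gain"}
                    | realization[category]
                )
                k += 1
    return pd.DataFrame(rows)
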