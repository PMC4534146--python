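"""2x2 diagnostic performance of gain markers against the invasive label.

For each marker (a locus combination whose positivity means "all member
loci gained"), samples with a determinable combination status are
cross-tabulated against the DCIS-only / DCIS-with-IBC label, yielding
sensitivity, specificity, predictive values and a two-tailed Fisher exact
test.  Percentages follow the usual conventions (e.g. sensitivity =
100·TP/(TP+FN)); degenerate denominators yield missing values, not zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import LOCI
from .profiles import combo_status

__all__ = [
    "TwoByTwo",
    "DiagnosticPerformance",
    "build_two_by_two",
    "performance",
    "fisher_exact_two_tailed",
    "diagnostics_table",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Marker-by-outcome contingency counts.

    tp: marker-positive with invasive cancer; fp: marker-positive DCIS-only;
    fn: marker-negative with invasive cancer; tn: marker-negative DCIS-only.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Percentages in [0, 100] (NaN where the denominator is empty)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    fisher_p: float


def build_two_by_two(
    profiles: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    marker: Sequence[str],
    case_label: str = "dcis_ibc",
) -> TwoByTwo:
    """Cross-tabulate a marker against the invasive label.

    Samples whose combination status is ``no_signal`` are excluded, so the
    evaluable total varies per marker.
    """
    lab = pd.Series(labels)
    tp = fp = fn = tn = 0
    for _, row in profiles.iterrows():
        group = lab.get(row["sample_id"], None)
        if group is None:
            raise KeyError(f"no label for sample {row['sample_id']!r}")
        status = combo_status({l: row[l] for l in LOCI}, marker)
        if status == "no_signal":
            continue
        case = group == case_label
        if status == "yes":
            tp, fp = tp + case, fp + (not case)
        else:
            fn, tn = fn + case, tn + (not case)
    return TwoByTwo(tp, fp, fn, tn)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def performance(t: TwoByTwo) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and Fisher p for one 2x2 table."""
    return DiagnosticPerformance(
        sensitivity=_pct(t.tp, t.tp + t.fn),
        specificity=_pct(t.tn, t.tn + t.fp),
        ppv=_pct(t.tp, t.tp + t.fp),
        npv=_pct(t.tn, t.tn + t.fn),
        fisher_p=fisher_exact_two_tailed(t),
    )


def fisher_exact_two_tailed(t: TwoByTwo) -> float:
    """Two-tailed Fisher exact p under the conditional hypergeometric null.

    Probability-mass rule: the sum over all tables with the observed margins
    whose probability does not exceed the observed table's.  Exact
    enumeration (no asymptotics); any zero margin gives p = 1 by convention.
    """
    if t.total == 0:
        raise ValueError("empty table")
    if (
        t.tp + t.fp == 0
        or t.fn + t.tn == 0
        or t.tp + t.fn == 0
        or t.fp + t.tn == 0
    ):
        return 1.0
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def diagnostics_table(
    profiles: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    markers: Iterable[Sequence[str]],
    case_label: str = "dcis_ibc",
) -> pd.DataFrame:
    """Assemble the per-marker performance table (one column per marker)."""
    cols = {}
    for marker in markers:
        t = build_two_by_two(profiles, labels, marker, case_label=case_label)
        perf = performance(t)
        cols["+".join(marker)] = {
            "all_cases": t.total,
            "ibc": t.tp + t.fn,
            "dcis_only": t.fp + t.tn,
            "true_positive": t.tp,
            "false_negative": t.fn,
            "false_positive": t.fp,
            "true_negative": t.tn,
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
            "ppv": perf.ppv,
            "npv": perf.npv,
            "fisher_p": perf.fisher_p,
        }
    return pd.DataFrame(cols)
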