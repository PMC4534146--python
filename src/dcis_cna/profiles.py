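"""Per-sample multi-locus gain profiles and the mutually exclusive category.

Combines the per-locus copy-number calls of the 1q / 8q24 / 11q13 / HER2
panel into combination statuses ("are all member loci gained?") and the
six-level mutually exclusive gain category that drives the association
analyses: unable-to-determine, no gains, a single gained locus (three
variants), two of three, or all three risk loci gained.  HER2 is scored and
can join combinations, but never enters the mutually exclusive category.
Deleted calls count as not-gained throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import LOCI, LocusCall

__all__ = [
    "TRIPLE_LOCI",
    "GAIN_CATEGORIES",
    "GainProfile",
    "combo_status",
    "gain_category",
    "assemble_profiles",
    "tabulate_prevalence",
    "category_counts",
]

#: The three risk loci entering the mutually exclusive category.
TRIPLE_LOCI = ("1q", "8q24", "11q13")

GAIN_CATEGORIES = (
    "unable_to_determine",
    "no_gains",
    "only_1q",
    "only_8q24",
    "only_11q13",
    "two_of_three",
    "all_three",
)


@dataclass(frozen=True)
class GainProfile:
    """Per-locus calls for one sample across the full panel."""

    sample_id: str
    calls: Mapping[str, LocusCall]

    def __post_init__(self) -> None:
        missing = [l for l in LOCI if l not in self.calls]
        if missing:
            raise ValueError(f"profile {self.sample_id!r} missing loci {missing}")

    def statuses(self) -> dict[str, str]:
        return {l: self.calls[l].status for l in LOCI}


def _statuses(profile) -> Mapping[str, str]:
    if isinstance(profile, GainProfile):
        return profile.statuses()
    return profile


def combo_status(profile, loci: Sequence[str]) -> str:
    """Status of a locus combination: yes / no / no_signal.

    ``no_signal`` if any member locus is unevaluable; ``yes`` only if every
    member locus is gained.
    """
    loci = tuple(loci)
    if not loci or any(l not in LOCI for l in loci):
        raise ValueError(f"loci must be a nonempty subset of {LOCI}, got {loci}")
    st = _statuses(profile)
    member = [st[l] for l in loci]
    if any(s == "no_signal" for s in member):
        return "no_signal"
    if all(s == "gain" for s in member):
        return "yes"
    return "no"


def gain_category(profile) -> str:
    """Mutually exclusive gain category over the three risk loci.

    HER2 is ignored; a sample is ``unable_to_determine`` if any risk locus
    is unevaluable, otherwise categorized by its set of gained risk loci
    (deleted and no-gain calls both count as not gained).
    """
    st = _statuses(profile)
    missing = [l for l in TRIPLE_LOCI if l not in st]
    if missing:
        raise ValueError(f"missing locus call(s): {missing}")
    triple = [st[l] for l in TRIPLE_LOCI]
    if any(s == "no_signal" for s in triple):
        return "unable_to_determine"
    gained = [l for l, s in zip(TRIPLE_LOCI, triple) if s == "gain"]
    if not gained:
        return "no_gains"
    if len(gained) == 1:
        return f"only_{gained[0]}"
    if len(gained) == 2:
        return "two_of_three"
    return "all_three"


def assemble_profiles(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy calls table into one row per sample with the category.

    ``calls`` needs columns sample_id, locus, status covering all four loci
    for every sample.  Returns columns sample_id, one status column per
    locus, and gain_category.
    """
    wide = calls.pivot(index="sample_id", columns="locus", values="status")
    missing = [l for l in LOCI if l not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing or list(wide.index[wide.isna().any(axis=1)])
        raise ValueError(f"incomplete panel for: {bad}")
    wide = wide[list(LOCI)].reset_index()
    wide.columns.name = None
    # vectorized equivalent of gain_category() per row
    triple = wide[list(TRIPLE_LOCI)]
    utd = (triple == "no_signal").any(axis=1)
    gained = triple == "gain"
    n_gained = gained.sum(axis=1)
    cat = pd.Series("no_gains", index=wide.index, dtype=object)
    for locus in TRIPLE_LOCI:
        only = gained[locus] & (n_gained == 1)
        cat[only] = f"only_{locus}"
    cat[n_gained == 2] = "two_of_three"
    cat[n_gained == 3] = "all_three"
    cat[utd] = "unable_to_determine"
    wide["gain_category"] = cat
    return wide


def category_counts(profiles: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Counts of the mutually exclusive categories, overall and by group."""
    if "gain_category" not in profiles.columns:
        profiles = profiles.assign(
            gain_category=[
                gain_category({l: row[l] for l in LOCI})
                for _, row in profiles.iterrows()
            ]
        )
    out = {}
    out["all"] = profiles["gain_category"].value_counts()
    if group_col in profiles.columns:
        for g, grp in profiles.groupby(group_col):
            out[g] = grp["gain_category"].value_counts()
    table = pd.DataFrame(out).reindex(GAIN_CATEGORIES).fillna(0).astype(int)
    return table


def tabulate_prevalence(
    profiles: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series | None = None,
    combos: Iterable[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Gain prevalence per locus and combination, overall and by group.

    Parameters
    ----------
    profiles
        One row per sample with per-locus status columns (as produced by
        :func:`assemble_profiles`); may carry a ``group`` column.
    labels
        Optional sample_id -> group mapping overriding the group column.
    combos
        Locus combinations to tabulate besides the four single loci;
        defaults to all pairs, triples and the full panel.

    Returns a frame indexed by marker with no_signal/no/yes counts (overall
    and per group), the percentage of each group carrying the gain, and
    ``pct_evaluable_gain`` — gained as a percentage of signal-evaluable
    samples, the convention used when quoting single-locus frequencies.
    """
    profiles = profiles.copy()
    if labels is not None:
        lab = pd.Series(labels)
        profiles["group"] = profiles["sample_id"].map(lab)
    if "group" not in profiles.columns:
        profiles["group"] = "all"
    groups = sorted(profiles["group"].dropna().unique())

    if combos is None:
        from itertools import combinations

        combos = [c for r in (2, 3, 4) for c in combinations(LOCI, r)]
    markers: list[tuple[str, ...]] = [(l,) for l in LOCI] + [tuple(c) for c in combos]

    rows = []
    for marker in markers:
        status = [
            combo_status({l: row[l] for l in LOCI}, marker)
            for _, row in profiles.iterrows()
        ]
        s = pd.Series(status, index=profiles.index)
        rec: dict[str, object] = {"marker": "+".join(marker)}
        for scope, mask in [("all", np.ones(len(s), bool))] + [
            (g, (profiles["group"] == g).to_numpy()) for g in groups
        ]:
            sub = s[mask]
            n_ns = int((sub == "no_signal").sum())
            n_no = int((sub == "no").sum())
            n_yes = int((sub == "yes").sum())
            rec[f"n_no_signal_{scope}"] = n_ns
            rec[f"n_no_{scope}"] = n_no
            rec[f"n_yes_{scope}"] = n_yes
            total = n_ns + n_no + n_yes
            rec[f"pct_yes_{scope}"] = 100.0 * n_yes / total if total else np.nan
            evaluable = n_no + n_yes
            if scope == "all":
                rec["pct_evaluable_gain"] = (
                    100.0 * n_yes / evaluable if evaluable else np.nan
                )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("marker")
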