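"""Synthetic DCIS cohorts with per-cell FISH signal counts.

Emulates the raw data of a tissue-microarray FISH study: for every sample
and locus a latent copy-number state (disomy, low gain, high gain,
deletion, a heterogeneous subclonal gain, or an assay failure) generates
per-cell probe counts — Poisson-distributed around the true copy number
with optional binomial signal dropout, control probes around two copies —
alongside case/control labels and clinicopathologic covariates drawn from
the published cohort marginals.

Two linkage modes tie genotype to the invasive label:

* ``state_first`` — each group gets its own state frequencies (defaults are
  the published per-locus prevalence of the DCIS-only and DCIS-with-IBC
  arms), so downstream calling recovers those frequencies.
* ``logistic_link`` — states are drawn from the control (DCIS-only)
  distribution for everyone and the case label is then drawn from a
  logistic model on the sample's true mutually exclusive gain category,
  enabling parameter-recovery experiments with known log-odds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference_data as ref
from .calling import LOCI, as_cell_array
from .profiles import TRIPLE_LOCI

__all__ = [
    "STATE_LABELS",
    "DEFAULT_STATE_MEANS",
    "TrueLocusState",
    "NoiseModel",
    "CohortConfig",
    "Cohort",
    "CohortConfigError",
    "CohortParseError",
    "generate_cell_signals",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

STATE_LABELS = (
    "disomy",
    "low_gain",
    "high_gain",
    "deletion",
    "heterogeneous_gain",
    "assay_failure",
)

#: Default true mean test-probe copies per state.  Low gain sits in the
#: reported one-to-two-extra-copies band; high gain is well above it.
DEFAULT_STATE_MEANS: dict[str, float] = {
    "disomy": 2.0,
    "low_gain": 3.5,
    "high_gain": 6.0,
    "deletion": 1.0,
    "heterogeneous_gain": 5.0,
}

GAIN_STATES = frozenset({"low_gain", "high_gain", "heterogeneous_gain"})


class CohortConfigError(ValueError):
    """Invalid generator configuration."""


class CohortParseError(ValueError):
    """Malformed cohort file; the message names the offending line."""


@dataclass(frozen=True)
class TrueLocusState:
    """Latent copy-number state of one sample-locus.

    ``subclone_fraction`` is the share of cells carrying the gain and is
    only meaningful (and required) for ``heterogeneous_gain``; the
    remaining cells are disomic.
    """

    label: str
    mean_test_copies: float | None = None
    subclone_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise CohortConfigError(f"unknown state label {self.label!r}")
        if self.label == "assay_failure":
            return
        mean = self.mean_test_copies
        if mean is None:
            object.__setattr__(
                self, "mean_test_copies", DEFAULT_STATE_MEANS[self.label]
            )
        elif mean <= 0:
            raise CohortConfigError("mean_test_copies must be positive")
        if self.label == "heterogeneous_gain":
            f = self.subclone_fraction if self.subclone_fraction is not None else 0.6
            if not 0.0 < f < 1.0:
                raise CohortConfigError("subclone_fraction must be in (0, 1)")
            object.__setattr__(self, "subclone_fraction", f)
        elif self.subclone_fraction is not None:
            raise CohortConfigError(
                "subclone_fraction only applies to heterogeneous_gain"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Per-cell count noise.

    ``poisson`` draws each channel Poisson around its mean; ``deterministic``
    uses the rounded mean exactly.  ``dropout_prob`` thins every observed
    copy independently (binomial thinning) in all channels.
    """

    count_dispersion: str = "poisson"
    dropout_prob: float = 0.0
    control_mean_copies: float = 2.0

    def __post_init__(self) -> None:
        if self.count_dispersion not in ("poisson", "deterministic"):
            raise CohortConfigError(
                "count_dispersion must be 'poisson' or 'deterministic'"
            )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise CohortConfigError("dropout_prob must be in [0, 1]")
        if self.control_mean_copies <= 0:
            raise CohortConfigError("control_mean_copies must be positive")


def generate_cell_signals(
    state: TrueLocusState,
    n_cells: int,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Draw per-cell (test, control_red, control_green) counts.

    ``assay_failure`` yields an empty array.  For ``heterogeneous_gain`` the
    first ``round(subclone_fraction * n_cells)`` cells carry the gained mean
    and the rest are disomic.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if state.label == "assay_failure" or n_cells == 0:
        return np.empty((0, 3), dtype=np.int64)

    if state.label == "heterogeneous_gain":
        n_sub = int(round(state.subclone_fraction * n_cells))
        means = np.full(n_cells, DEFAULT_STATE_MEANS["disomy"])
        means[:n_sub] = state.mean_test_copies
    else:
        means = np.full(n_cells, float(state.mean_test_copies))
    ctrl = np.full(n_cells, noise.control_mean_copies)

    if noise.count_dispersion == "deterministic":
        test = np.rint(means).astype(np.int64)
        red = np.rint(ctrl).astype(np.int64)
        green = red.copy()
    else:
        test = rng.poisson(means)
        red = rng.poisson(ctrl)
        green = rng.poisson(ctrl)
    if noise.dropout_prob > 0.0:
        keep = 1.0 - noise.dropout_prob
        test = rng.binomial(test, keep)
        red = rng.binomial(red, keep)
        green = rng.binomial(green, keep)
    return np.column_stack([test, red, green]).astype(np.int64)


def _default_link_log_odds() -> dict[str, float]:
    out = {"no_gains": 0.0, "unable_to_determine": 0.0}
    for cat, (or_, _, _) in ref.UNIVARIATE_OR_PRINTED.items():
        out[cat] = math.log(or_)
    return out


def _default_missing_rates() -> dict[str, float]:
    n = sum(ref.COVARIATE_MARGINALS["age_group"].values())  # 271 patients
    return {
        col: ref.COVARIATE_MARGINALS[col].get("missing", 0) / n
        for col in ("race", "hr_status", "grade")
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic cohort.

    Defaults reproduce the published study conditions: arm sizes 122 / 158,
    per-group per-locus state frequencies from the printed prevalence
    table, 40–100 scored cells per sample, Poisson counts without dropout,
    covariate marginals and missingness from the printed characteristics
    table, and (in ``logistic_link`` mode) category log-odds equal to the
    logs of the printed univariate odds ratios.
    """

    n_dcis_only: int = ref.N_DCIS_ONLY
    n_dcis_ibc: int = ref.N_DCIS_IBC
    state_probs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=ref.default_state_probs
    )
    state_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_MEANS)
    )
    subclone_fraction: float = 0.6
    cells_per_sample: tuple[int, int] = (40, 100)
    noise: NoiseModel = NoiseModel()
    covariate_marginals: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in ref.COVARIATE_MARGINALS.items()
        }
    )
    missing_rates: Mapping[str, float] = field(
        default_factory=_default_missing_rates
    )
    link_mode: str = "state_first"
    link_log_odds: Mapping[str, float] = field(
        default_factory=_default_link_log_odds
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dcis_only < 0 or self.n_dcis_ibc < 0:
            raise CohortConfigError("arm sizes must be nonnegative")
        if self.link_mode not in ("state_first", "logistic_link"):
            raise CohortConfigError(
                "link_mode must be 'state_first' or 'logistic_link'"
            )
        lo, hi = self.cells_per_sample
        if not (0 <= lo <= hi):
            raise CohortConfigError("cells_per_sample must be 0 <= low <= high")
        for group, by_locus in self.state_probs.items():
            for locus, probs in by_locus.items():
                bad = set(probs) - set(STATE_LABELS)
                if bad:
                    raise CohortConfigError(
                        f"unknown state(s) {sorted(bad)} for {group}/{locus}"
                    )
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise CohortConfigError(
                        f"state probabilities for {group}/{locus} sum to "
                        f"{total}, not 1"
                    )
                if any(p < 0 for p in probs.values()):
                    raise CohortConfigError("probabilities must be nonnegative")


@dataclass(eq=False)
class Cohort:
    """A generated (or loaded) cohort.

    ``samples``: one row per sample (sample_id, group, age_group, race,
    hr_status, grade; empty string marks a missing covariate).
    ``cells``: (sample_id, locus) -> ``(n_cells, 3)`` signal-count array,
    empty for assay failures; every sample has an entry for every locus.
    ``true_states``: latent state labels per sample-locus (generation
    provenance; not serialized and not part of equality).
    """

    samples: pd.DataFrame
    cells: dict[tuple[str, str], np.ndarray]
    true_states: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            raise ValueError("sample_id values must be unique")
        for sid in ids:
            for locus in LOCI:
                if (sid, locus) not in self.cells:
                    raise ValueError(f"missing cells entry for ({sid}, {locus})")

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        a = self.samples.reset_index(drop=True)
        b = other.samples.reset_index(drop=True)
        if not a.equals(b):
            return False
        if set(self.cells) != set(other.cells):
            return False
        return all(
            np.array_equal(self.cells[k], other.cells[k]) for k in self.cells
        )

    def labels(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]

    def cells_frame(self) -> pd.DataFrame:
        """Long-format per-cell table (one row per scored cell)."""
        frames = []
        for sid in self.samples["sample_id"]:
            for locus in LOCI:
                arr = self.cells[(sid, locus)]
                if arr.shape[0] == 0:
                    continue
                frames.append(
                    pd.DataFrame(
                        {
                            "sample_id": sid,
                            "locus": locus,
                            "cell_index": np.arange(arr.shape[0]),
                            "test_count": arr[:, 0],
                            "control_red_count": arr[:, 1],
                            "control_green_count": arr[:, 2],
                        }
                    )
                )
        if not frames:
            return pd.DataFrame(
                columns=[
                    "sample_id",
                    "locus",
                    "cell_index",
                    "test_count",
                    "control_red_count",
                    "control_green_count",
                ]
            )
        return pd.concat(frames, ignore_index=True)


def _true_category(states: Mapping[str, str]) -> str:
    """Mutually exclusive category implied by latent states (risk loci)."""
    triple = [states[l] for l in TRIPLE_LOCI]
    if any(s == "assay_failure" for s in triple):
        return "unable_to_determine"
    gained = [l for l, s in zip(TRIPLE_LOCI, triple) if s in GAIN_STATES]
    if not gained:
        return "no_gains"
    if len(gained) == 1:
        return f"only_{gained[0]}"
    return "two_of_three" if len(gained) == 2 else "all_three"


def _make_state(config: CohortConfig, label: str) -> TrueLocusState:
    if label == "assay_failure":
        return TrueLocusState("assay_failure")
    if label == "heterogeneous_gain":
        return TrueLocusState(
            label,
            config.state_means.get(label),
            config.subclone_fraction,
        )
    return TrueLocusState(label, config.state_means.get(label))


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Generate a cohort; deterministic given ``config.seed``.

    One master seed spawns independent substreams for states, cells, labels
    and covariates, so e.g. enlarging the cohort does not perturb earlier
    draws' streams.
    """
    master = np.random.SeedSequence(config.seed)
    s_states, s_cells, s_labels, s_cov = (
        np.random.default_rng(c) for c in master.spawn(4)
    )
    n = config.n_dcis_only + config.n_dcis_ibc
    sample_ids = [f"s{i:04d}" for i in range(n)]

    # --- latent states ----------------------------------------------------
    state_rows = []
    if config.link_mode == "state_first":
        groups = ["dcis_only"] * config.n_dcis_only + [
            "dcis_ibc"
        ] * config.n_dcis_ibc
        for sid, group in zip(sample_ids, groups):
            row = {"sample_id": sid}
            for locus in LOCI:
                probs = config.state_probs[group][locus]
                labels = list(probs)
                row[locus] = s_states.choice(
                    labels, p=np.asarray([probs[l] for l in labels])
                )
            state_rows.append(row)
    else:  # logistic_link: states from the control distribution for all
        intercept = (
            math.log(config.n_dcis_ibc / config.n_dcis_only)
            if config.n_dcis_only > 0 and config.n_dcis_ibc > 0
            else 0.0
        )
        groups = []
        for sid in sample_ids:
            row = {"sample_id": sid}
            for locus in LOCI:
                probs = config.state_probs["dcis_only"][locus]
                labels = list(probs)
                row[locus] = s_states.choice(
                    labels, p=np.asarray([probs[l] for l in labels])
                )
            state_rows.append(row)
            category = _true_category(row)
            logit = intercept + config.link_log_odds.get(category, 0.0)
            p_case = 1.0 / (1.0 + math.exp(-logit))
            groups.append(
                "dcis_ibc" if s_labels.random() < p_case else "dcis_only"
            )
    true_states = pd.DataFrame(
        state_rows, columns=["sample_id", *LOCI]
    )

    # --- cells ------------------------------------------------------------
    lo, hi = config.cells_per_sample
    state_cache = {label: _make_state(config, label) for label in STATE_LABELS}
    state_cols = {locus: true_states[locus].to_numpy() for locus in LOCI}
    cells: dict[tuple[str, str], np.ndarray] = {}
    for i, sid in enumerate(sample_ids):
        for locus in LOCI:
            n_cells = int(s_cells.integers(lo, hi + 1)) if hi > 0 else 0
            cells[(sid, locus)] = generate_cell_signals(
                state_cache[state_cols[locus][i]], n_cells, config.noise, s_cells
            )

    # --- covariates -------------------------------------------------------
    cov_cols = {}
    for col, marg in config.covariate_marginals.items():
        levels = [k for k in marg if k != "missing"]
        weights = np.asarray([marg[k] for k in levels], float)
        weights /= weights.sum()
        draws = s_cov.choice(levels, size=n, p=weights) if n else np.array([])
        rate = config.missing_rates.get(col, 0.0)
        if rate > 0 and n:
            draws = np.where(s_cov.random(n) < rate, "", draws)
        cov_cols[col] = [str(v) for v in draws]

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups if n else [],
            **{k: v for k, v in cov_cols.items()},
        },
        columns=["sample_id", "group", "age_group", "race", "hr_status", "grade"],
    ).astype(object)
    return Cohort(samples=samples, cells=cells, true_states=true_states)


# ---------------------------------------------------------------------------
# Serialization

CELL_COLUMNS = [
    "sample_id",
    "locus",
    "cell_index",
    "test_count",
    "control_red_count",
    "control_green_count",
]
SAMPLE_COLUMNS = ["sample_id", "group", "age_group", "race", "hr_status", "grade"]


def write_cohort(cohort: Cohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``cohort.csv`` and ``cells.csv`` under ``out_dir``.

    A sample-locus with zero rows in ``cells.csv`` is an assay failure.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = out_dir / "cohort.csv"
    cells_path = out_dir / "cells.csv"
    cohort.samples[SAMPLE_COLUMNS].to_csv(cohort_path, index=False)
    cohort.cells_frame().to_csv(cells_path, index=False)
    return cohort_path, cells_path


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    in_dir = Path(in_dir)
    samples = pd.read_csv(
        in_dir / "cohort.csv", dtype=str, keep_default_na=False
    )
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise CohortParseError(f"cohort.csv lacks column(s) {missing_cols}")
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise CohortParseError(f"duplicate sample_id {dup!r} in cohort.csv")

    raw = pd.read_csv(in_dir / "cells.csv", dtype=str, keep_default_na=False)
    missing_cols = [c for c in CELL_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortParseError(f"cells.csv lacks column(s) {missing_cols}")
    count_cols = ["test_count", "control_red_count", "control_green_count"]
    parsed = {}
    for col in count_cols + ["cell_index"]:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after the header line
            raise CohortParseError(
                f"cells.csv line {line}: invalid {col} value "
                f"{raw.loc[bad.idxmax(), col]!r} (need nonnegative integer)"
            )
        parsed[col] = vals.astype(np.int64)
    for col in count_cols + ["cell_index"]:
        raw[col] = parsed[col]

    known = set(samples["sample_id"])
    unknown = set(raw["sample_id"]) - known
    if unknown:
        raise CohortParseError(
            f"cells.csv references unknown sample(s) {sorted(unknown)[:3]}"
        )

    cells: dict[tuple[str, str], np.ndarray] = {
        (sid, locus): np.empty((0, 3), dtype=np.int64)
        for sid in samples["sample_id"]
        for locus in LOCI
    }
    for (sid, locus), grp in raw.groupby(["sample_id", "locus"], sort=False):
        grp = grp.sort_values("cell_index")
        cells[(sid, locus)] = as_cell_array(grp[count_cols].to_numpy())
    return Cohort(samples=samples, cells=cells)
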