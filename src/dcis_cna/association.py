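"""Odds-ratio association analysis of gain categories with invasive cancer.

Two estimation routes mirror the study design:

* **Univariate** cross-product odds ratios from 2x2 counts with Wald
  95 % confidence intervals, ``OR = ad/bc``, ``SE(log OR) =
  sqrt(1/a + 1/b + 1/c + 1/d)``.
* A **multivariable logistic model** of the invasive label on the mutually
  exclusive gain category plus age group, race, hormone-receptor status,
  grade and HER2 gain, fitted by maximum likelihood on complete cases
  (iteratively reweighted least squares).  Coefficients exponentiate to
  adjusted odds ratios; term significance uses two-sided Wald tests.

The fitted-model surface follows the Model/Results convention of
statsmodels: ``fit_logistic`` returns a :class:`LogisticFit` carrying
coefficients, their covariance, per-iteration log-likelihoods and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ORResult",
    "ZeroCellError",
    "odds_ratio_wald",
    "ModelSpec",
    "default_model_spec",
    "collapse_race",
    "filter_complete_cases",
    "build_design",
    "LogisticFit",
    "fit_logistic",
    "wald_test_term",
    "univariate_or_table",
]

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


class ZeroCellError(ValueError):
    """A 2x2 cell is zero, so the cross-product odds ratio is undefined."""


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with Wald 95 % confidence interval."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    se_log_or: float
    p_wald: float


def odds_ratio_wald(
    a: int, b: int, c: int, d: int, haldane: bool = False
) -> ORResult:
    """Cross-product odds ratio with Wald CI from a 2x2 table.

    Layout: ``a`` exposed cases, ``b`` exposed controls, ``c`` reference
    cases, ``d`` reference controls.  With ``haldane=True`` a zero cell is
    handled by adding 0.5 to every cell (Haldane–Anscombe); otherwise a zero
    cell raises :class:`ZeroCellError`.
    """
    cells = [a, b, c, d]
    if any(v < 0 for v in cells):
        raise ValueError("cell counts must be nonnegative")
    if any(v == 0 for v in cells):
        if not haldane:
            raise ZeroCellError(f"zero cell in table {tuple(cells)}")
        a, b, c, d = (v + 0.5 for v in cells)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    return ORResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        se_log_or=se,
        p_wald=2.0 * stats.norm.sf(abs(z)),
    )


# ---------------------------------------------------------------------------
# Model specification and design


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus categorical terms with explicit reference levels.

    ``terms`` maps a data column to ``(reference_level, other_levels)``;
    dummies are created for the non-reference levels in the given order.
    """

    outcome: str = "group"
    case_label: str = "dcis_ibc"
    terms: tuple[tuple[str, tuple[str, tuple[str, ...]]], ...] = ()

    def columns(self) -> list[str]:
        return [col for col, _ in self.terms]


def default_model_spec(gain_column: str = "gain_category") -> ModelSpec:
    """The study's multivariable model: gain category plus clinicopathologic
    covariates, with the published reference levels."""
    return ModelSpec(
        outcome="group",
        case_label="dcis_ibc",
        terms=(
            (
                gain_column,
                (
                    "no_gains",
                    ("only_1q", "only_8q24", "only_11q13", "two_of_three", "all_three"),
                ),
            ),
            ("age_group", ("50-64", ("<40", "40-49", ">=65"))),
            ("race", ("other", ("nh_white", "nh_api"))),
            ("hr_status", ("positive", ("negative",))),
            ("grade", ("1", ("2", "3"))),
            ("her2_gain", ("no", ("yes",))),
        ),
    )


def collapse_race(race: pd.Series) -> pd.Series:
    """Collapse race to NH white / NH Asian-Pacific Islander / other."""
    out = race.copy()
    keep = {"nh_white", "nh_api"}
    out[~out.isin(keep) & out.notna() & (out != "")] = "other"
    return out


def filter_complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Retain samples with data on every model variable and a determinable
    gain category (complete-case analysis)."""
    mask = pd.Series(True, index=data.index)
    for col in spec.columns() + [spec.outcome]:
        if col not in data.columns:
            raise KeyError(f"model column {col!r} not in data")
        v = data[col]
        s = v.astype(str)
        mask &= v.notna() & (s != "") & (s != "missing") & (s != "unable_to_determine")
    return data.loc[mask]


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, list[int]]]:
    """Build (X, y, names, term_slices) with an intercept and treatment
    (reference-level) coding; empty levels are dropped."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {}
    for col, (ref, levels) in spec.terms:
        v = data[col].astype(str)
        observed = set(v.unique())
        idxs = []
        for lev in levels:
            if lev not in observed:
                continue
            cols.append((v == lev).to_numpy(float))
            names.append(f"{col}[{lev}]")
            idxs.append(len(names) - 1)
        term_cols[col] = idxs
    X = np.column_stack(cols)
    y = (data[spec.outcome].astype(str) == spec.case_label).to_numpy(float)
    return X, y, names, term_cols


# ---------------------------------------------------------------------------
# Maximum-likelihood logistic fit (IRLS)


@dataclass
class LogisticFit:
    """Results of a maximum-likelihood logistic regression.

    Carries coefficient estimates on the log-odds scale, their
    variance-covariance matrix, the per-iteration log-likelihood path and
    convergence diagnostics.
    """

    names: list[str]
    params: np.ndarray
    cov: np.ndarray
    n_used: int
    converged: bool
    log_likelihood: float
    loglik_path: np.ndarray
    n_iter: int
    term_cols: dict[str, list[int]] = field(default_factory=dict)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def odds_ratios(self) -> pd.DataFrame:
        """Per-coefficient OR, Wald 95 % CI and two-sided p (intercept kept
        on the log-odds scale in ``coef``)."""
        se = self.bse
        z = self.params / se
        with np.errstate(over="ignore"):  # separation -> infinite CI bound
            return pd.DataFrame(
                {
                    "coef": self.params,
                    "se": se,
                    "or": np.exp(self.params),
                    "ci_low": np.exp(self.params - Z_95 * se),
                    "ci_high": np.exp(self.params + Z_95 * se),
                    "p_wald": 2.0 * stats.norm.sf(np.abs(z)),
                },
                index=self.names,
            )

    def summary(self) -> str:
        lines = [
            "Logistic regression (maximum likelihood, IRLS)",
            f"n = {self.n_used}   log-likelihood = {self.log_likelihood:.4f}   "
            f"converged = {self.converged} ({self.n_iter} iterations)",
            "",
        ]
        table = self.odds_ratios()
        lines.append(table.to_string(float_format=lambda v: f"{v:10.4f}"))
        return "\n".join(lines)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    term_cols: Mapping[str, list[int]] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic model by IRLS.

    Convergence: maximum absolute coefficient change < ``tol`` (default
    1e-8) within ``max_iter`` iterations.  Quasi-complete separation is
    flagged (``converged=False``) when coefficients diverge.  A
    rank-deficient design raises, naming the collinear columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(set(np.round(y, 12))) < 2:
        raise ValueError("outcome is constant; model is degenerate")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns by greedy QR-style elimination
        bad = []
        kept: list[int] = []
        for j in range(p):
            trial = kept + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                kept.append(j)
        raise np.linalg.LinAlgError(
            f"design is rank deficient; collinear term(s): {bad}"
        )

    beta = np.zeros(p)
    ll_path = []
    converged = False
    it = 0
    separated = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = special.expit(eta)
        ll_path.append(float(np.sum(y * eta - np.logaddexp(0.0, eta))))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 30.0:
            separated = True  # diverging coefficients: (quasi-)separation
            break
        if step < tol:
            converged = True
            break
    eta = X @ beta
    mu = special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll_path.append(ll)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    return LogisticFit(
        names=list(names),
        params=beta,
        cov=cov,
        n_used=n,
        converged=converged and not separated,
        log_likelihood=ll,
        loglik_path=np.asarray(ll_path),
        n_iter=it,
        term_cols=dict(term_cols or {}),
    )


def fit_logistic_df(
    data: pd.DataFrame, spec: ModelSpec | None = None, complete_cases: bool = True
) -> LogisticFit:
    """Convenience: complete-case filter, design build and fit in one step."""
    spec = spec or default_model_spec()
    if complete_cases:
        data = filter_complete_cases(data, spec)
    X, y, names, term_cols = build_design(data, spec)
    return fit_logistic(X, y, names=names, term_cols=term_cols)


def wald_test_term(model: LogisticFit, term: str | Sequence[int]) -> float:
    """Multi-degree-of-freedom Wald chi-square p-value for a model term.

    ``term`` is either a term name known to the fit or an explicit list of
    coefficient indices.
    """
    if isinstance(term, str):
        idx = model.term_cols.get(term)
        if not idx:
            raise KeyError(f"unknown term {term!r}")
    else:
        idx = list(term)
        if any(i < 0 or i >= len(model.params) for i in idx):
            raise IndexError("coefficient index out of range")
    b = model.params[idx]
    V = model.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, df=len(idx)))


def univariate_or_table(
    category_counts: pd.DataFrame | Mapping[str, tuple[int, int]],
    reference: str = "no_gains",
    case_col: str = "dcis_ibc",
    control_col: str = "dcis_only",
    haldane: bool = False,
) -> pd.DataFrame:
    """Univariate ORs for each gain category against the reference.

    ``category_counts`` is either a frame with case/control count columns
    indexed by category, or a mapping category -> (n_cases, n_controls).
    A category with a zero cell yields a missing (NaN) row unless
    ``haldane`` applies the +0.5 correction.
    """
    if isinstance(category_counts, pd.DataFrame):
        counts = {
            cat: (int(row[case_col]), int(row[control_col]))
            for cat, row in category_counts.iterrows()
        }
    else:
        counts = {k: (int(v[0]), int(v[1])) for k, v in category_counts.items()}
    c_ref, d_ref = counts[reference]
    rows = {}
    for cat, (a, b) in counts.items():
        if cat in (reference, "unable_to_determine"):
            continue
        try:
            r = odds_ratio_wald(a, b, c_ref, d_ref, haldane=haldane)
        except ZeroCellError:
            rows[cat] = dict.fromkeys(
                ("or", "ci_low", "ci_high", "se_log_or", "p_wald"), float("nan")
            )
            continue
        rows[cat] = {
            "or": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "se_log_or": r.se_log_or,
            "p_wald": r.p_wald,
        }
    return pd.DataFrame(rows).T
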