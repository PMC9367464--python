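"""Per-parent exact risk analysis and confounding-adjusted logistic modelling.

For each dam (or sire) with affected offspring, the offspring born up to a
cutoff year are cross-tabulated against the offspring of all other parents of
the same role and tested with Fisher's exact test; the conditional-MLE odds
ratio and its exact CI are reported.  Parents are then classified high risk
(OR > 1 and p < 0.05) or low risk, and the high/low label enters a logistic
regression together with sire and year of birth so that the sire effect can be
judged after correcting for the dams (dams were usually mated to a single
sire, so the two are confounded).  A prevalence-by-parental-phenotype summary
completes the reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .exact import (
    ContingencyTable2x2,
    ExactTestResult,
    cole_format,
    exact_test,
)
from .pedigree import Pedigree

__all__ = [
    "build_parent_table",
    "classify_parent",
    "parent_risk_table",
    "parental_phenotype_summary",
    "LogisticFit",
    "LrtResult",
    "fit_logistic",
    "likelihood_ratio_test",
    "sire_dam_design",
]

#: offspring born after this year are excluded (the youngest affected animals
#: in the source cattery were born in 2019)
DEFAULT_MAX_BIRTH_YEAR = 2019


class DegenerateTableError(ValueError):
    """The focal parent has no eligible offspring (or no comparison group)."""


def _offspring_case_control(
    ped: Pedigree,
    max_birth_year: int | None,
    unknown_as_control: bool = True,
):
    """(parent-of-role -> (cases, controls)) helper over eligible offspring."""
    rows = []
    for rec in ped:
        if rec.sire is None and rec.dam is None:
            continue
        if rec.birth_year is None:
            continue  # no year, cannot apply the cutoff: excluded
        if max_birth_year is not None and rec.birth_year > max_birth_year:
            continue
        if rec.status == "unknown" and not unknown_as_control:
            continue
        case = rec.status == "affected"
        rows.append((rec.sire, rec.dam, case))
    return rows


def build_parent_table(
    ped: Pedigree,
    parent_id: str,
    parent_role: str,
    max_birth_year: int | None = DEFAULT_MAX_BIRTH_YEAR,
    unknown_as_control: bool = True,
) -> ContingencyTable2x2:
    """2x2 table: the focal parent's offspring vs all other offspring.

    Offspring born after ``max_birth_year`` are excluded.  Offspring with
    unknown status count as controls (they were classified healthy when no
    information was available), unless ``unknown_as_control`` is off.
    """
    if parent_role not in ("dam", "sire"):
        raise ValueError("parent_role must be 'dam' or 'sire'")
    if parent_id not in ped:
        raise KeyError(f"parent {parent_id!r} not in pedigree")
    rows = _offspring_case_control(ped, max_birth_year, unknown_as_control)
    pick = 0 if parent_role == "sire" else 1
    a = b = c = d = 0
    for row in rows:
        if row[pick] == parent_id:
            if row[2]:
                a += 1
            else:
                b += 1
        else:
            if row[2]:
                c += 1
            else:
                d += 1
    if a + b == 0:
        raise DegenerateTableError(
            f"{parent_role} {parent_id!r} has no eligible offspring"
        )
    return ContingencyTable2x2(a, b, c, d)


def classify_parent(result: ExactTestResult) -> str:
    """'high' iff OR > 1 and p < 0.05 (p exactly 0.05 is low), else 'low'."""
    return "high" if (result.or_cmle > 1.0 and result.p_value < 0.05) else "low"


def parent_risk_table(
    ped: Pedigree,
    role: str,
    max_birth_year: int | None = DEFAULT_MAX_BIRTH_YEAR,
    only_with_cases: bool = True,
    level: float = 0.95,
    unknown_as_control: bool = True,
) -> pd.DataFrame:
    """Per-parent exact results, one row per dam or sire.

    By default only parents with at least one affected offspring are listed
    (the convention of the source tables).  Rows are ordered by p-value, then
    descending OR, then id, which reproduces the familiar table layout.
    """
    rows = _offspring_case_control(ped, max_birth_year, unknown_as_control)
    pick = 0 if role == "sire" else 1
    parents = sorted({r[pick] for r in rows if r[pick] is not None})
    out = []
    for pid in parents:
        t = build_parent_table(ped, pid, role, max_birth_year, unknown_as_control)
        if only_with_cases and t.a == 0:
            continue
        res = exact_test(t, level)
        out.append(
            {
                "parent": pid,
                "role": role,
                "cases": t.a,
                "controls": t.b,
                "other_cases": t.c,
                "other_controls": t.d,
                "or_cmle": res.or_cmle,
                "or_sample": res.or_sample,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "or_display": cole_format(res.or_cmle),
                "ci_display": f"{cole_format(res.ci_low)} to {cole_format(res.ci_high)}",
                "label": classify_parent(res),
            }
        )
    df = pd.DataFrame(out)
    if not df.empty:
        df = df.sort_values(
            ["p_value", "or_cmle", "parent"], ascending=[True, False, True]
        ).reset_index(drop=True)
    return df


def parental_phenotype_summary(
    ped: Pedigree, max_birth_year: int | None = None
) -> pd.DataFrame:
    """Prevalence of the trait among progeny by number of affected parents.

    Rows are the 2/1/0-affected-parent categories; unknown parental status
    counts as unaffected (healthy unless reported otherwise).  Empty
    categories keep zero totals and a blank percentage.
    """
    counts = {k: [0, 0] for k in (2, 1, 0)}  # affected, total
    for rec in ped:
        if rec.sire is None and rec.dam is None:
            continue
        if max_birth_year is not None and (
            rec.birth_year is None or rec.birth_year > max_birth_year
        ):
            continue
        n_aff_parents = 0
        for parent in (rec.sire, rec.dam):
            if parent is not None and ped.record(parent).status == "affected":
                n_aff_parents += 1
        counts[n_aff_parents][1] += 1
        if rec.status == "affected":
            counts[n_aff_parents][0] += 1
    rows = []
    for k in (2, 1, 0):
        aff, tot = counts[k]
        rows.append(
            {
                "affected_parents": k,
                "affected_progeny": aff,
                "total_progeny": tot,
                "percent": 100.0 * aff / tot if tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic regression + likelihood-ratio tests
# ---------------------------------------------------------------------------


class RankDeficientError(ValueError):
    """Design matrix does not have full column rank."""


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with separation diagnostics."""

    params: pd.Series
    llf: float
    n: int
    converged: bool
    separation: bool

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.params.index)

    @property
    def n_params(self) -> int:
        return len(self.params)


@dataclass(frozen=True)
class LrtResult:
    term: str
    statistic: float
    df: int
    p_value: float


def fit_logistic(design: pd.DataFrame, response) -> LogisticFit:
    """Fit a binomial GLM with logit link by IRLS.

    The design must include its own intercept column.  Rank deficiency is
    detected up front; quasi-complete separation is flagged (fitted
    probabilities indistinguishable from the outcomes, diverging
    coefficients) rather than silently reported as converged inference.
    """
    X = pd.DataFrame(design)
    y = np.asarray(response, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response lengths differ")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise RankDeficientError(
            f"design has rank {rank} < {X.shape[1]} columns"
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    mu = np.asarray(res.fittedvalues)
    separation = bool(
        np.all(np.abs(y - mu) < 1e-6) or np.any(np.abs(res.params) > 30)
    )
    return LogisticFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        llf=float(res.llf),
        n=len(y),
        converged=bool(res.converged),
        separation=separation,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> LrtResult:
    """Chi-square LRT of nested logistic fits; deviance difference 2*dll."""
    if not set(reduced.names) < set(full.names):
        raise ValueError(
            "models are not nested: reduced parameters must be a strict "
            "subset of the full model's"
        )
    if full.n != reduced.n:
        raise ValueError("models were fit on different numbers of observations")
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = full.n_params - reduced.n_params
    dropped = sorted(set(full.names) - set(reduced.names))
    return LrtResult(
        term="+".join(dropped),
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
    )


def sire_dam_design(
    ped: Pedigree,
    high_risk_dams: set[str] | list[str],
    reference_sire: str,
    max_birth_year: int | None = DEFAULT_MAX_BIRTH_YEAR,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (intercept, sire factor, binary dam risk, centered year).

    Sires enter as a factor with ``reference_sire`` as the baseline; the dam
    variable is the binary high/low-risk label; year of birth is centered.
    Returns (design, response) over eligible offspring.
    """
    high = set(high_risk_dams)
    rows, ys = [], []
    for rec in ped:
        if rec.sire is None or rec.dam is None or rec.birth_year is None:
            continue
        if max_birth_year is not None and rec.birth_year > max_birth_year:
            continue
        rows.append((rec.sire, rec.dam, rec.birth_year))
        ys.append(1.0 if rec.status == "affected" else 0.0)
    if not rows:
        raise ValueError("no eligible offspring for the design")
    sires = sorted({r[0] for r in rows})
    if reference_sire not in sires:
        raise ValueError(f"reference sire {reference_sire!r} has no offspring")
    year_mean = float(np.mean([r[2] for r in rows]))
    data = {"intercept": np.ones(len(rows))}
    for s in sires:
        if s == reference_sire:
            continue
        data[f"sire[{s}]"] = np.array([1.0 if r[0] == s else 0.0 for r in rows])
    data["dam_high_risk"] = np.array([1.0 if r[1] in high else 0.0 for r in rows])
    data["year_c"] = np.array([r[2] - year_mean for r in rows])
    return pd.DataFrame(data), np.array(ys)
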