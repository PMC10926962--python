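"""Small-sample group statistics for LC metrics.

Mirrors the statistics layer of a responder/non-responder imaging study:
each LC metric is modelled by a linear model on either the response group or
the therapy duration, controlling for age, sex, antiseizure-medication (ASM)
count, epilepsy duration and benzodiazepine intake.  Benjamini–Hochberg FDR
adjustment is applied within configurable metric families, predictors are
screened with the variance inflation factor (VIF < 5), and demographic
tables are compared with Mann–Whitney U (numeric) or Fisher exact
(categorical) tests.  The stimulation duty cycle is
``(ON time + 4 s) / (ON time + OFF time)``.

All tests are two-sided.  Rows with a missing outcome or covariate are
dropped listwise per model and the effective n is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COVARIATES",
    "LMRow",
    "DutyCycle",
    "fit_covariate_lm",
    "lm_report",
    "bh_fdr",
    "vif",
    "fisher_exact",
    "mann_whitney",
    "duty_cycle",
]

DEFAULT_COVARIATES = (
    "age",
    "sex",
    "asm_count",
    "epilepsy_duration_y",
    "benzodiazepine",
)

# total-n threshold below which the Mann-Whitney p is computed by exact
# enumeration of all group assignments
EXACT_MW_MAX_N = 12

VIF_THRESHOLD = 5.0


# --------------------------------------------------------------------------
# linear models
# --------------------------------------------------------------------------

@dataclass
class LMRow:
    """One fitted model: the predictor-of-interest coefficient and its test."""

    outcome: str
    predictor: str
    coef: float
    se: float
    t: float
    p: float
    n: int
    n_dropped: int
    vif: dict[str, float]

    @property
    def vif_ok(self) -> bool:
        return all(v < VIF_THRESHOLD for v in self.vif.values())


def _encode(col: pd.Series) -> pd.Series:
    """Binary-encode two-level categoricals (alphabetical reference level)."""
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.dropna().unique())
        if len(levels) > 2:
            raise ValueError(
                f"column '{col.name}' has {len(levels)} levels; expected <= 2"
            )
        return col.map({lv: i for i, lv in enumerate(levels)}).astype(float)
    return col.astype(float)


def fit_covariate_lm(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates=DEFAULT_COVARIATES,
) -> LMRow:
    """OLS of ``outcome ~ predictor + covariates`` with a t test on the predictor.

    ``predictor`` is a column name (e.g. the response group or therapy
    duration); group labels are binary-encoded.  Raises if the design is
    singular (naming the collinear columns) or n is too small.
    """
    import statsmodels.api as sm

    cols = [outcome, predictor, *covariates]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = table[cols].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n = len(sub)
    if n <= len(covariates) + 2:
        raise ValueError(
            f"n={n} too small for {len(covariates) + 1} predictors plus intercept"
        )
    y = sub[outcome].astype(float)
    x = pd.DataFrame({c: _encode(sub[c]) for c in [predictor, *covariates]})
    vifs = vif(x)
    xc = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(xc.to_numpy())
    if rank < xc.shape[1]:
        collinear = [c for c, v in vifs.items() if not np.isfinite(v)]
        raise ValueError(f"singular design; collinear columns: {collinear}")
    fit = sm.OLS(y, xc).fit()
    return LMRow(
        outcome=outcome,
        predictor=predictor,
        coef=float(fit.params[predictor]),
        se=float(fit.bse[predictor]),
        t=float(fit.tvalues[predictor]),
        p=float(fit.pvalues[predictor]),
        n=n,
        n_dropped=n_before - n,
        vif=vifs,
    )


def lm_report(
    table: pd.DataFrame,
    outcomes,
    predictor: str,
    covariates=DEFAULT_COVARIATES,
    fdr_families: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Fit one LM per outcome and FDR-adjust within metric families.

    ``fdr_families`` maps a family name (one LC metric) to the outcome
    columns belonging to it (its subpart/side variants); by default all
    outcomes form a single family.
    """
    rows = {o: fit_covariate_lm(table, o, predictor, covariates) for o in outcomes}
    families = fdr_families or {"all": list(outcomes)}
    assigned = [o for members in families.values() for o in members]
    if sorted(assigned) != sorted(outcomes):
        raise ValueError("FDR families must partition the outcome list")
    records = []
    for family, members in families.items():
        adj = bh_fdr([rows[m].p for m in members])
        for m, p_fdr in zip(members, adj):
            r = rows[m]
            records.append(
                {
                    "outcome": m,
                    "family": family,
                    "predictor": predictor,
                    "coef": r.coef,
                    "se": r.se,
                    "t": r.t,
                    "p": r.p,
                    "p_fdr": p_fdr,
                    "n": r.n,
                    "n_dropped": r.n_dropped,
                    "max_vif": max(r.vif.values()),
                    "vif_ok": r.vif_ok,
                }
            )
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# multiplicity and collinearity
# --------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def vif(design: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor 1/(1-R²) per predictor.

    Each predictor is regressed on the others (with intercept).  Perfectly
    collinear columns report ``inf``.
    """
    x = design.to_numpy(dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than predictors ({k})")
    out = {}
    for j, name in enumerate(design.columns):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss == 0:
            raise ValueError(f"predictor '{name}' is constant")
        r2 = 1.0 - float(resid @ resid) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# --------------------------------------------------------------------------
# nonparametric two-group tests
# --------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("counts must be non-negative integers")
        t = np.round(t).astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _exact_mw_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments of group a.

    Midranks are held fixed, so ties are handled consistently.  The
    two-sided p is twice the smaller tail, capped at 1.
    """
    n = len(pooled_ranks)
    offset = n_a * (n_a + 1) / 2.0
    us = np.array(
        [sum(pooled_ranks[list(c)]) - offset for c in combinations(range(n), n_a)]
    )
    tol = 1e-9
    lo = np.mean(us <= u_obs + tol)
    hi = np.mean(us >= u_obs - tol)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann–Whitney U (for group a) with a two-sided p.

    Exact enumeration over all group assignments when the pooled sample has
    at most 12 observations; tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)
    if len(pooled) <= EXACT_MW_MAX_N:
        p = _exact_mw_p(ranks, len(a), u_a)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[1]
        )
    return u_a, p


# --------------------------------------------------------------------------
# stimulation schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DutyCycle:
    """Duty cycle of a stimulation schedule with rapid-cycling flag."""

    value: float
    rapid: bool
    valid: bool


def duty_cycle(
    on_s: float,
    off_s: float,
    rapid_off_max_s: float = 66.0,
    rapid_duty_max: float = 0.5,
) -> DutyCycle:
    """Duty cycle ``(ON + 4 s) / (ON + OFF)``.

    The 4 s accounts for the stimulation ramp-up/down.  A schedule is flagged
    rapid-cycling when OFF time is at most ``rapid_off_max_s`` (1.1 min)
    while the duty cycle stays at or below ``rapid_duty_max``.  A value
    above 1 (OFF shorter than the 4 s ramp) is flagged invalid.
    """
    if on_s <= 0:
        raise ValueError("ON time must be positive")
    if off_s < 0:
        raise ValueError("OFF time must be non-negative")
    if on_s + off_s == 0:
        raise ValueError("ON + OFF must be positive")
    value = (on_s + 4.0) / (on_s + off_s)
    valid = value <= 1.0
    rapid = valid and off_s <= rapid_off_max_s and value <= rapid_duty_max
    return DutyCycle(value=float(value), rapid=rapid, valid=valid)
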