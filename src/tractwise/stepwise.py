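"""Hierarchical stepwise multiple regression.

Forward selection with backward removal over a candidate set (age, sex, and
cognitive predictors), the procedure behind the behavioral tables relating
phonological awareness and visual-spatial ability to reading skill in each
language. At each step the candidate with the smallest entry p-value enters
if it clears the entry threshold (probability-of-F 0.05 by default); any
retained predictor whose p rises to or above the removal threshold (0.10)
is then dropped. Coefficients are standardized (variables z-scored on the
complete cases), so a lone predictor's beta equals its Pearson correlation
with the outcome.

Reported per step: standardized beta and t per retained predictor, model
R-squared, its change from the previous step, and the overall
F = (R2/k) / ((1-R2)/(n-k-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionStep",
    "StepwiseModel",
    "stepwise_select",
    "model_f_from_r2",
    "r2_change_f",
]


def model_f_from_r2(r2: float, k: int, n: int) -> float:
    """Overall model F from R-squared, predictor count k, and sample size n."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R-squared must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def r2_change_f(
    r2_full: float, r2_reduced: float, p_added: int, k_full: int, n: int
) -> float:
    """F for the R-squared increment of adding ``p_added`` predictors.

    For a single added predictor this equals the square of that
    predictor's t statistic in the full model.
    """
    if r2_full < r2_reduced:
        raise ValueError("full-model R-squared cannot be below the reduced one")
    if r2_full >= 1.0:
        raise ValueError("R-squared of 1 gives an infinite F")
    if n <= k_full + 1:
        raise ValueError("need n > k_full + 1")
    return ((r2_full - r2_reduced) / p_added) / ((1.0 - r2_full) / (n - k_full - 1))


@dataclass
class RegressionStep:
    index: int
    entered: str
    removed: tuple[str, ...]
    retained: tuple[str, ...]
    beta: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r2: float
    r2_change: float
    f: float
    f_p: float
    n: int
    k: int


@dataclass
class StepwiseModel:
    dependent: str
    candidates: tuple[str, ...]
    entry_p: float
    removal_p: float
    steps: list[RegressionStep] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)
    n: int = 0

    @property
    def retained(self) -> tuple[str, ...]:
        return self.steps[-1].retained if self.steps else ()

    @property
    def entry_order(self) -> tuple[str, ...]:
        return tuple(s.entered for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for i, var in enumerate(s.retained):
                rows.append(
                    {
                        "step": s.index,
                        "variable": var,
                        "beta": s.beta[var],
                        "t": s.t[var],
                        "r2": s.r2 if i == 0 else np.nan,
                        "r2_change": s.r2_change if i == 0 else np.nan,
                        "F": s.f if i == 0 else np.nan,
                        "n": s.n,
                    }
                )
        return pd.DataFrame(
            rows, columns=["step", "variable", "beta", "t", "r2", "r2_change", "F", "n"]
        )


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def _fit(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_select(
    cohort: pd.DataFrame,
    dependent: str,
    candidates: tuple[str, ...],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_condition: float = 1e8,
) -> StepwiseModel:
    """Forward stepwise selection with backward removal.

    Listwise deletion over {dependent} + candidates fixes the analysis
    sample before selection, so every step shares one n. Zero steps (no
    candidate clears the entry threshold) is a valid outcome, not an error;
    collinear candidates (condition number above ``max_condition`` on the
    z-scored design) are.
    """
    cols = [dependent, *candidates]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks column(s) {missing}")
    data = cohort[cols].astype(float).dropna()
    n = len(data)
    if n < len(candidates) + 3:
        raise ValueError(f"need at least {len(candidates) + 3} complete cases, have {n}")
    zdata = _zscore(data)
    if zdata.isna().any().any():
        const = [c for c in cols if data[c].std(ddof=1) == 0]
        raise ValueError(f"constant variable(s) {const} cannot be standardized")
    cond = np.linalg.cond(zdata[list(candidates)].to_numpy())
    if cond > max_condition:
        raise ValueError(
            f"candidate set {candidates} is near-collinear (condition number {cond:.3g})"
        )

    y = zdata[dependent].to_numpy()
    model = StepwiseModel(
        dependent=dependent,
        candidates=tuple(candidates),
        entry_p=entry_p,
        removal_p=removal_p,
        n=n,
    )
    retained: list[str] = []
    r2_prev = 0.0
    step_idx = 0
    while True:
        # entry: smallest p among candidates that clear entry_p
        best_var, best_p = None, np.inf
        for var in candidates:
            if var in retained:
                continue
            fit = _fit(y, zdata[retained + [var]])
            pval = float(fit.pvalues[var])
            if pval < best_p:
                best_var, best_p = var, pval
        if best_var is None or best_p > entry_p:
            break
        if step_idx >= 2 * len(candidates):  # entry/removal cycling guard
            break
        retained.append(best_var)
        # removal: drop anything whose p rose to the removal threshold
        removed: list[str] = []
        while True:
            fit = _fit(y, zdata[retained])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] >= removal_p and len(retained) > 1:
                retained.remove(worst)
                removed.append(worst)
            else:
                break
        fit = _fit(y, zdata[retained])
        k = len(retained)
        r2 = float(fit.rsquared)
        step_idx += 1
        model.steps.append(
            RegressionStep(
                index=step_idx,
                entered=best_var,
                removed=tuple(removed),
                retained=tuple(retained),
                beta={v: float(fit.params[v]) for v in retained},
                t={v: float(fit.tvalues[v]) for v in retained},
                p={v: float(fit.pvalues[v]) for v in retained},
                r2=r2,
                r2_change=r2 - r2_prev,
                f=model_f_from_r2(r2, k, n),
                f_p=float(fit.f_pvalue),
                n=n,
                k=k,
            )
        )
        r2_prev = r2
    for var in candidates:
        if var not in retained:
            model.excluded[var] = "did not meet the entry criterion"
    return model
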