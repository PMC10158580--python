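"""Node-wise (partial) correlation maps and their conjunction.

The core quantity is the partial correlation between a behavioral outcome
and FA at each node of a tract profile, controlling linearly for covariates
(age, sex, and optionally the other language's reading score): residualize
both variables on the covariates (with intercept) and correlate the
residuals. Two-tailed p-values come from the t transform with
df = n - 2 - n_covariates.

Missing data are handled by subject-level listwise deletion over
{outcome} + covariates intersected with profile availability, so n is
constant across the nodes of a tract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ProfileMatrix

__all__ = ["NodewiseResult", "partial_corr", "nodewise_partial_map", "conjunction_nodes"]


@dataclass
class NodewiseResult:
    """Per-node r, df, p for one tract map."""

    tract: str
    r: np.ndarray
    df: int
    p: np.ndarray
    n: int
    outcome: str = ""
    covariates: tuple[str, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.r.size

    def significant_nodes(self, alpha: float = 0.05) -> np.ndarray:
        """1-based indices of nodes with p < alpha."""
        return np.nonzero(self.p < alpha)[0] + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tract": self.tract,
                "node": np.arange(1, self.n_nodes + 1),
                "r": self.r,
                "df": self.df,
                "p": self.p,
                "n": self.n,
            }
        )


def _design(Z: np.ndarray, n: int) -> np.ndarray:
    if Z.size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), Z])


def _residualize(M: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Residuals of each column of M after least-squares projection on D."""
    beta, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ beta


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    rr = np.clip(np.abs(r), 0.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = rr * np.sqrt(df / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(t, df)


def partial_corr(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Partial correlation of x and y controlling for the columns of Z.

    Rows with any missing value across x, y, Z are dropped (listwise).
    Returns ``(r, df, p)`` with df = n - 2 - n_covariates. With ``Z=None``
    this is the plain Pearson correlation. Raises on zero residual
    variance, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if Z is None:
        Z = np.empty((x.size, 0))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if Z.shape[0] != x.size:
        raise ValueError("covariates must align with x and y")
    keep = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[keep], y[keep], Z[keep]
    k = Z.shape[1]
    n = x.size
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} complete cases, have {n}")
    D = _design(Z, n)
    rx = _residualize(x[:, None], D).ravel()
    ry = _residualize(y[:, None], D).ravel()
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance after residualization; correlation undefined")
    r = float(np.clip(rx @ ry / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    p = float(_r_to_p(np.array([r]), df)[0])
    return r, df, p


def _nodewise_r(Y: np.ndarray, x: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Vectorized per-column partial correlation of Y's columns with x.

    Y is (n, nodes), x is (n,), D the design matrix including intercept.
    Shared by the observed map and the permutation engine.
    """
    Ry = _residualize(Y, D)
    rx = _residualize(x[:, None], D).ravel()
    num = Ry.T @ rx
    den = np.linalg.norm(Ry, axis=0) * np.linalg.norm(rx)
    if np.any(den == 0.0):
        bad = np.nonzero(den == 0.0)[0] + 1
        raise ValueError(f"zero residual variance at node(s) {bad.tolist()}")
    return np.clip(num / den, -1.0, 1.0)


def _complete_case_frame(
    profiles: ProfileMatrix,
    outcome: str,
    covariates: tuple[str, ...],
    cohort: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    missing_cols = [c for c in (outcome, *covariates) if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort lacks column(s) {missing_cols}")
    cohort = cohort.set_index(cohort["subject_id"].astype(str)) if "subject_id" in cohort else cohort
    ids = [sid for sid in profiles.available_ids if sid in cohort.index]
    sub = cohort.loc[ids, [outcome, *covariates]].astype(float)
    ok = sub.notna().all(axis=1)
    ids = [sid for sid, flag in zip(ids, ok) if flag]
    Y = profiles.data.loc[ids].to_numpy(dtype=float)
    x = sub.loc[ids, outcome].to_numpy()
    Z = sub.loc[ids, list(covariates)].to_numpy()
    return Y, x, Z, ids


def nodewise_partial_map(
    profiles: ProfileMatrix,
    outcome: str,
    covariates: tuple[str, ...],
    cohort: pd.DataFrame,
) -> NodewiseResult:
    """(r, df, p) at every node of a tract for one outcome and covariate set."""
    Y, x, Z, ids = _complete_case_frame(profiles, outcome, covariates, cohort)
    k = len(covariates)
    n = len(ids)
    if n < k + 3:
        raise ValueError(
            f"tract {profiles.label.name}: only {n} complete subjects for "
            f"outcome {outcome!r} with covariates {covariates}; need {k + 3}"
        )
    D = _design(Z, n)
    r = _nodewise_r(Y, x, D)
    df = n - 2 - k
    return NodewiseResult(
        tract=profiles.label.name,
        r=r,
        df=df,
        p=_r_to_p(r, df),
        n=n,
        outcome=outcome,
        covariates=tuple(covariates),
    )


def conjunction_nodes(
    a: NodewiseResult, b: NodewiseResult, alpha: float = 0.05
) -> np.ndarray:
    """Nodes significant in both maps with the same sign of r (1-based).

    Symmetric in its arguments; the result is a subset of each map's
    marginal significant set. Requiring sign agreement keeps a node from
    counting as "common" when the two outcomes relate to FA in opposite
    directions.
    """
    if a.tract != b.tract or a.n_nodes != b.n_nodes:
        raise ValueError(f"conjunction across different tracts: {a.tract} vs {b.tract}")
    both = (a.p < alpha) & (b.p < alpha) & (np.sign(a.r) == np.sign(b.r))
    return np.nonzero(both)[0] + 1
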