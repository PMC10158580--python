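"""Follow-up statistics on significant clusters.

Once a cluster of nodes is tied to reading skill, its interpretation is
probed by (a) averaging FA over the cluster per subject, (b) partially
correlating that mean with candidate cognitive abilities (phonological
awareness, visual-spatial ability, tone discrimination) controlling age and
sex, (c) attaching percentile-bootstrap 95% confidence intervals computed on
the residualized pairs, and (d) comparing correlation coefficients with
Fisher's r-to-z test to ask whether one ability tracks the cluster more
strongly than another.

The Fisher comparison treats the two correlations as independent with
standard error 1/sqrt(n-3) and no degrees-of-freedom adjustment for
partialled covariates; with the study's printed (r, n) pairs this choice
reproduces every printed z statistic to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .clusters import Cluster
from .nodewise import partial_corr
from .profiles import ProfileMatrix

__all__ = [
    "FisherZComparison",
    "BootstrapCI",
    "cluster_mean_value",
    "fisher_z_independent",
    "fisher_z_dependent",
    "percentile_bootstrap_ci",
    "followup_partial_corr",
]


@dataclass(frozen=True)
class FisherZComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: int


def cluster_mean_value(profiles: ProfileMatrix, cluster: Cluster) -> pd.Series:
    """Per-subject unweighted mean FA over the cluster's nodes.

    Indexed over all cohort subjects; NaN where the tract is unavailable.
    """
    if cluster.start < 1 or cluster.end > profiles.n_nodes:
        raise ValueError(
            f"cluster {cluster.start}-{cluster.end} outside the "
            f"{profiles.n_nodes}-node tract {profiles.label.name}"
        )
    cols = profiles.data.columns[cluster.start - 1 : cluster.end]
    means = profiles.data[cols].mean(axis=1)
    return means.reindex(profiles.subject_ids)


def fisher_z_independent(r1: float, n1: int, r2: float, n2: int) -> FisherZComparison:
    """Compare two correlations from independent samples via the r-to-z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); p two-tailed
    from the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("Fisher transform is infinite at |r| = 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return FisherZComparison(r1=r1, n1=n1, r2=r2, n2=n2, z=float(z), p=float(p))


def fisher_z_dependent(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Steiger's test for two correlations sharing a variable in one sample.

    Offered for completeness; the independent-sample comparison above is the
    default. ``r12`` is the correlation between the two non-shared variables.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    rbar2 = (r1**2 + r2**2) / 2.0
    f = (1.0 - r12) / (2.0 * (1.0 - rbar2))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _boot_r(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson r for each row of resample indices (rows with zero variance -> nan)."""
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    den = np.linalg.norm(xs, axis=1) * np.linalg.norm(ys, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, np.einsum("ij,ij->i", xs, ys) / den, np.nan)


def percentile_bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI for the Pearson correlation of paired data.

    Pairs are resampled with replacement; a resample with zero variance in
    either coordinate is redrawn (policy: such resamples carry no
    information about r). Deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    point = float(np.corrcoef(x, y)[0, 1])
    rng = child_rng(seed, "bootstrap")
    idx = rng.integers(0, n, size=(n_boot, n))
    rs = _boot_r(x, y, idx)
    for _ in range(100):  # degenerate resamples are redrawn
        bad = ~np.isfinite(rs)
        if not bad.any():
            break
        idx_bad = rng.integers(0, n, size=(int(bad.sum()), n))
        rs[bad] = _boot_r(x, y, idx_bad)
    else:
        raise RuntimeError("could not draw non-degenerate bootstrap resamples")
    lo, hi = np.quantile(rs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(
        point=point,
        lower=float(max(lo, -1.0)),
        upper=float(min(hi, 1.0)),
        n_boot=n_boot,
        seed=seed,
    )


def followup_partial_corr(
    cluster_means: pd.Series,
    cognitive: str,
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_years", "sex"),
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, int, float, BootstrapCI]:
    """Partial correlation of cluster-mean FA with a cognitive score + bootstrap CI.

    The CI is computed on the residualized pairs (FA and score after
    removing the covariates), matching how such relations are plotted.
    Returns ``(r, df, p, ci)``.
    """
    cohort = cohort.set_index(cohort["subject_id"].astype(str)) if "subject_id" in cohort else cohort
    ids = [sid for sid in cluster_means.index if sid in cohort.index]
    df_ = pd.DataFrame(
        {
            "fa": cluster_means.loc[ids].astype(float),
            "score": cohort.loc[ids, cognitive].astype(float),
            **{c: cohort.loc[ids, c].astype(float) for c in covariates},
        }
    ).dropna()
    x = df_["fa"].to_numpy()
    y = df_["score"].to_numpy()
    Z = df_[list(covariates)].to_numpy()
    r, dof, p = partial_corr(x, y, Z)
    # residualize once so the bootstrap resamples the plotted pairs
    D = np.column_stack([np.ones(len(df_)), Z])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    ci = percentile_bootstrap_ci(rx, ry, n_boot=n_boot, seed=seed)
    return r, dof, p, ci
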