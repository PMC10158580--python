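"""Suprathreshold clusters and max-cluster-size permutation FWE correction.

Adjacent tract nodes are strongly correlated, so per-node multiple-testing
correction (Bonferroni) is far too conservative. Instead, contiguous runs of
nodes with p below the cluster-forming threshold (and a constant sign of r)
form clusters, and family-wise error is controlled by comparing each
observed cluster's size with the permutation distribution of the *maximum*
cluster size obtained by re-running the whole node-wise analysis with the
outcome shuffled across subjects (covariates staying with their subjects).

The FWE critical size c* is the smallest integer such that the proportion
of permutation maxima >= c* is at most alpha; an observed cluster of size
>= c* is significant at the stringent level. A descriptive lenient rule
(>= 9 adjacent nodes on 100-node tracts, >= 3 on 30-node tracts) is also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .nodewise import NodewiseResult, _design, _r_to_p, _complete_case_frame, _residualize
from .profiles import ProfileMatrix

__all__ = [
    "Cluster",
    "PermutationNull",
    "find_clusters",
    "lenient_filter",
    "permutation_fwe",
    "classify_clusters",
    "clusters_to_frame",
]

LENIENT_MIN_NODES = {100: 9, 30: 3}


@dataclass(frozen=True)
class Cluster:
    """A maximal run of adjacent suprathreshold nodes with a constant sign."""

    tract: str
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    sign: int   # +1 or -1
    min_p: float
    label: Literal["stringent", "lenient", "subthreshold", ""] = ""

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def nodes(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class PermutationNull:
    """Permutation distribution of the maximum cluster size and its c*."""

    n_perm: int
    alpha: float
    max_sizes: np.ndarray
    critical_size: int

    def __post_init__(self) -> None:
        self.max_sizes = np.asarray(self.max_sizes, dtype=int)
        if self.max_sizes.size != self.n_perm:
            raise ValueError("null vector length must equal n_perm")


def find_clusters(result: NodewiseResult, alpha: float = 0.05) -> list[Cluster]:
    """Maximal runs of adjacent nodes with p < alpha and constant sign of r."""
    supra = result.p < alpha
    sign = np.sign(result.r).astype(int)
    clusters: list[Cluster] = []
    i = 0
    m = result.n_nodes
    while i < m:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and supra[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        clusters.append(
            Cluster(
                tract=result.tract,
                start=i + 1,
                end=j + 1,
                sign=int(sign[i]) or 1,
                min_p=float(result.p[i : j + 1].min()),
            )
        )
        i = j + 1
    return clusters


def _max_cluster_size(p: np.ndarray, r: np.ndarray, alpha: float) -> int:
    """Largest run of adjacent suprathreshold nodes with constant sign (0 if none)."""
    supra = p < alpha
    if not supra.any():
        return 0
    sign = np.sign(r)
    best = run = 0
    prev_sign = 0.0
    for ok, s in zip(supra, sign):
        if ok and (run == 0 or s == prev_sign):
            run += 1
        elif ok:
            run = 1
        else:
            run = 0
        prev_sign = s
        best = max(best, run)
    return best


def _critical_size(max_sizes: np.ndarray, alpha: float, n_nodes: int) -> int:
    """Smallest c with P(max >= c) <= alpha under the empirical null."""
    for c in range(1, n_nodes + 2):
        if np.mean(max_sizes >= c) <= alpha:
            return c
    return n_nodes + 1


def lenient_filter(clusters: Sequence[Cluster], n_nodes: int) -> list[Cluster]:
    """Keep clusters meeting the descriptive adjacency rule (>=9 of 100, >=3 of 30)."""
    if n_nodes not in LENIENT_MIN_NODES:
        raise ValueError(f"lenient rule defined only for 100- or 30-node tracts, got {n_nodes}")
    cut = LENIENT_MIN_NODES[n_nodes]
    return [c for c in clusters if c.size >= cut]


def permutation_fwe(
    profiles: ProfileMatrix,
    outcome: str,
    covariates: tuple[str, ...],
    cohort: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: Literal["shuffle", "freedman-lane"] = "shuffle",
) -> PermutationNull:
    """Max-cluster-size permutation null for one tract/outcome analysis.

    ``shuffle`` permutes the outcome across subjects, keeping covariates
    attached to their subjects; ``freedman-lane`` permutes the residuals of
    the outcome after regression on the covariates and adds them back to the
    covariate fit, preserving the covariate structure under the null.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable null tail", stacklevel=2)
    Y, x, Z, ids = _complete_case_frame(profiles, outcome, covariates, cohort)
    n, k = x.size, Z.shape[1]
    if n < k + 3:
        raise ValueError(f"tract {profiles.label.name}: too few complete subjects ({n})")
    D = _design(Z, n)
    df = n - 2 - k
    rng = child_rng(seed, "permutation")

    # All permutations as one (n, n_perm) matrix; the node-wise map for every
    # permutation then reduces to one residualization + one matmul.
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1).T  # (n, n_perm)
    if scheme == "shuffle":
        Xp = x[perm_idx]
    elif scheme == "freedman-lane":
        fit = D @ np.linalg.lstsq(D, x, rcond=None)[0]
        resid = x - fit
        Xp = fit[:, None] + resid[perm_idx]
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    Ry = _residualize(Y, D)
    Rx = _residualize(Xp, D)
    ny = np.linalg.norm(Ry, axis=0)
    nx = np.linalg.norm(Rx, axis=0)
    if np.any(ny == 0.0):
        raise ValueError("zero residual variance in a node column")
    R = np.clip((Ry.T @ Rx) / np.outer(ny, nx), -1.0, 1.0)  # (nodes, n_perm)
    P = _r_to_p(R, df)

    max_sizes = np.fromiter(
        (_max_cluster_size(P[:, b], R[:, b], alpha) for b in range(n_perm)),
        dtype=int,
        count=n_perm,
    )
    cstar = _critical_size(max_sizes, alpha, profiles.n_nodes)
    return PermutationNull(n_perm=n_perm, alpha=alpha, max_sizes=max_sizes, critical_size=cstar)


def classify_clusters(
    clusters: Sequence[Cluster], null: PermutationNull, n_nodes: int
) -> list[Cluster]:
    """Label clusters stringent (size >= c*), lenient (adjacency rule), or subthreshold."""
    lenient = {(c.start, c.end) for c in lenient_filter(clusters, n_nodes)}
    out = []
    for c in clusters:
        if c.size >= null.critical_size:
            label = "stringent"
        elif (c.start, c.end) in lenient:
            label = "lenient"
        else:
            label = "subthreshold"
        out.append(replace(c, label=label))
    return out


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tract": c.tract,
                "start": c.start,
                "end": c.end,
                "size": c.size,
                "sign": c.sign,
                "min_p": c.min_p,
                "label": c.label,
            }
            for c in clusters
        ],
        columns=["tract", "start", "end", "size", "sign", "min_p", "label"],
    )
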