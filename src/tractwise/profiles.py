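"""Tract-profile data types and a lite fiber-quantification path.

A tract is represented as a fixed number of equidistant *nodes* along its
core, each carrying a fractional-anisotropy (FA) summary per subject
(``TractProfile`` for one subject, ``ProfileMatrix`` for a cohort). The
module also provides the standard quantification steps for turning a bundle
of streamlines into a profile: outlier cleaning against the bundle core,
equal-arc-length resampling, and distance-weighted node averaging.

FA is computed from the diffusion-tensor eigenvalues as the normalized
standard deviation of (lambda1, lambda2, lambda3):

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

which is scale-invariant and lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TensorEigenvalues",
    "Streamline",
    "StreamlineBundle",
    "TractLabel",
    "TractProfile",
    "ProfileMatrix",
    "fa_from_eigenvalues",
    "resample_to_nodes",
    "clean_streamline_bundle",
    "weighted_node_average",
    "gaussian_core_weights",
    "bundle_profile",
    "read_profile_csv",
    "write_profile_csv",
    "read_streamline_text",
]

Hemisphere = Literal["left", "right"]
Segment = Literal["direct", "anterior", "posterior"]

#: node counts per segment: the posterior segment is shorter and uses 30.
SEGMENT_NODES = {"direct": 100, "anterior": 100, "posterior": 30}


# ---------------------------------------------------------------------------
# FA

@dataclass(frozen=True)
class TensorEigenvalues:
    """Sorted diffusion-tensor eigenvalues (lambda1 >= lambda2 >= lambda3 >= 0)."""

    l1: float
    l2: float
    l3: float

    def __post_init__(self) -> None:
        vals = sorted((float(self.l1), float(self.l2), float(self.l3)), reverse=True)
        object.__setattr__(self, "l1", vals[0])
        object.__setattr__(self, "l2", vals[1])
        object.__setattr__(self, "l3", vals[2])
        if not all(np.isfinite(vals)):
            raise ValueError("eigenvalues must be finite")
        if vals[2] < 0:
            raise ValueError("eigenvalues must be non-negative after sorting")

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.l3], dtype=float)


def fa_from_eigenvalues(e: TensorEigenvalues | Sequence[float]) -> float:
    """Fractional anisotropy of one tensor.

    Accepts a :class:`TensorEigenvalues` or any 3-sequence of eigenvalues.
    Raises ``ValueError`` on an all-zero tensor, where FA is undefined.
    """
    lam = e.as_array() if isinstance(e, TensorEigenvalues) else np.asarray(e, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected exactly three eigenvalues")
    if not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be finite")
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        raise ValueError("FA undefined for an all-zero tensor")
    fa = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm
    # guard rounding just past 1 for degenerate tensors like (1, 0, 0)
    return float(min(fa, 1.0))


# ---------------------------------------------------------------------------
# streamline geometry

@dataclass
class Streamline:
    """Ordered 3D polyline in millimetres with optional per-point scalars."""

    points: np.ndarray
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] < 2:
            raise ValueError("a streamline needs at least two points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("streamline coordinates must be finite")
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.shape != (self.points.shape[0],):
                raise ValueError("samples must align with points")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class StreamlineBundle:
    label: str
    streamlines: list[Streamline] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise ValueError(f"bundle {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.streamlines)


def resample_to_nodes(s: Streamline, n_nodes: int) -> Streamline:
    """Resample to ``n_nodes`` points at equal arc-length spacing.

    Endpoints are preserved exactly; scalar samples are linearly
    interpolated in arc length.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes")
    seglen = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    if total == 0.0:
        raise ValueError("zero-length streamline cannot be resampled")
    t = np.linspace(0.0, total, n_nodes)
    pts = np.column_stack([np.interp(t, arc, s.points[:, k]) for k in range(3)])
    pts[0], pts[-1] = s.points[0], s.points[-1]
    samples = None if s.samples is None else np.interp(t, arc, s.samples)
    return Streamline(pts, samples)


def _core_and_distances(
    streamlines: Sequence[Streamline], n_nodes: int
) -> tuple[np.ndarray, np.ndarray, list[Streamline]]:
    """Pointwise-mean core and each streamline's mean distance to it."""
    res = [resample_to_nodes(s, n_nodes) for s in streamlines]
    stack = np.stack([s.points for s in res])          # (m, n_nodes, 3)
    core = stack.mean(axis=0)
    dist = np.linalg.norm(stack - core, axis=2).mean(axis=1)  # (m,)
    return core, dist, res


def _loo_outliers(values: np.ndarray, n_sd: float) -> np.ndarray:
    """Flag entries exceeding the leave-one-out mean + n_sd * SD of the rest.

    Leave-one-out statistics are used because a gross outlier inflates the
    plain sample SD enough to mask itself in small bundles.
    """
    m = values.size
    if m < 3:
        return np.zeros(m, dtype=bool)
    total, total_sq = values.sum(), np.sum(values**2)
    loo_mean = (total - values) / (m - 1)
    loo_var = np.maximum((total_sq - values**2) / (m - 1) - loo_mean**2, 0.0)
    loo_sd = np.sqrt(loo_var)
    excess = values - loo_mean
    with np.errstate(invalid="ignore"):
        flag = np.where(loo_sd > 0, excess > n_sd * loo_sd, excess > 1e-12)
    return flag


def clean_streamline_bundle(
    b: StreamlineBundle,
    core_sd: float = 5.0,
    length_sd: float = 4.0,
    n_nodes: int = 100,
) -> StreamlineBundle:
    """Iteratively drop streamlines far from the bundle core or too long.

    A streamline is removed when its mean Euclidean distance to the core
    (the pointwise mean of all node-resampled streamlines) exceeds
    ``core_sd`` SDs of the distance distribution, or its length exceeds
    ``length_sd`` SDs above the mean length; both criteria use
    leave-one-out mean/SD. Removal repeats until no outlier remains.
    Never errors on small bundles: below 3 streamlines a warning is issued
    and the remainder returned.
    """
    keep = list(b.streamlines)
    while True:
        if len(keep) < 3:
            warnings.warn(
                f"bundle {b.label!r} reduced to {len(keep)} streamlines; "
                "cleaning stopped",
                stacklevel=2,
            )
            break
        _, dist, _ = _core_and_distances(keep, n_nodes)
        lengths = np.array([s.length for s in keep])
        bad = _loo_outliers(dist, core_sd) | _loo_outliers(lengths, length_sd)
        if not bad.any():
            break
        keep = [s for s, flag in zip(keep, bad) if not flag]
    return StreamlineBundle(b.label, keep)


def weighted_node_average(samples: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-node weighted mean over streamlines.

    ``samples`` and ``weights`` are (n_streamlines, n_nodes); weights must be
    non-negative with at least one positive weight per node.
    """
    samples = np.asarray(samples, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if samples.shape != weights.shape:
        raise ValueError("samples and weights must share a shape")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    totals = weights.sum(axis=0)
    dead = np.nonzero(totals == 0)[0]
    if dead.size:
        raise ValueError(f"all-zero weights at node(s) {(dead + 1).tolist()} (1-based)")
    return (weights * samples).sum(axis=0) / totals


def gaussian_core_weights(resampled: Sequence[Streamline]) -> np.ndarray:
    """Gaussian weights in per-node distance from the bundle core.

    Bandwidth at each node is the SD of streamline positions about the core
    at that node (the local bundle spread); zero spread gives equal weights.
    """
    stack = np.stack([s.points for s in resampled])
    core = stack.mean(axis=0)
    d = np.linalg.norm(stack - core, axis=2)  # (m, nodes)
    bw = d.std(axis=0)
    w = np.ones_like(d)
    pos = bw > 0
    w[:, pos] = np.exp(-0.5 * (d[:, pos] / bw[pos]) ** 2)
    return w


# ---------------------------------------------------------------------------
# labels and profiles

@dataclass(frozen=True)
class TractLabel:
    """Hemisphere + segment of the arcuate fasciculus, with its node count."""

    hemisphere: Hemisphere
    segment: Segment

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.segment not in SEGMENT_NODES:
            raise ValueError(f"unknown segment {self.segment!r}")

    @property
    def n_nodes(self) -> int:
        return SEGMENT_NODES[self.segment]

    @property
    def name(self) -> str:
        return f"{self.hemisphere}_{self.segment}"

    @classmethod
    def from_name(cls, name: str) -> "TractLabel":
        hemi, _, seg = name.partition("_")
        return cls(hemi, seg)  # type: ignore[arg-type]


@dataclass
class TractProfile:
    """One subject's FA value at each node of one tract."""

    label: TractLabel
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.label.n_nodes,):
            raise ValueError(
                f"{self.label.name} expects {self.label.n_nodes} nodes, "
                f"got {self.values.shape}"
            )
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("FA values must lie in [0, 1]")


@dataclass
class ProfileMatrix:
    """Subjects x nodes FA for one tract, with per-subject availability.

    ``data`` holds one row per *available* subject, indexed by subject id;
    subjects listed in ``subject_ids`` but absent from ``data`` are the
    unavailable ones (tract not tracked for them).
    """

    label: TractLabel
    data: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.label.n_nodes:
            raise ValueError(
                f"{self.label.name}: expected {self.label.n_nodes} node columns, "
                f"got {self.data.shape[1]}"
            )
        unknown = set(self.data.index) - set(self.subject_ids)
        if unknown:
            raise ValueError(f"profile rows for unlisted subjects: {sorted(unknown)}")
        vals = self.data.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.label.n_nodes

    @property
    def available_ids(self) -> list[str]:
        return list(self.data.index)

    def availability(self) -> pd.Series:
        return pd.Series(
            [sid in self.data.index for sid in self.subject_ids],
            index=self.subject_ids,
            name=self.label.name,
        )


def _node_columns(n_nodes: int) -> list[str]:
    return [f"node_{i:03d}" for i in range(1, n_nodes + 1)]


def write_profile_csv(pm: ProfileMatrix, path: str | Path) -> None:
    """Wide delimited text: subject_id, node_001 ... node_NNN (available rows only)."""
    out = pm.data.copy()
    out.columns = _node_columns(pm.n_nodes)
    out.index.name = "subject_id"
    out.to_csv(path)


def read_profile_csv(
    path: str | Path, label: TractLabel, subject_ids: Iterable[str] | None = None
) -> ProfileMatrix:
    df = pd.read_csv(path, index_col="subject_id")
    df.index = df.index.astype(str)
    expected = _node_columns(label.n_nodes)
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: node columns do not match the {label.n_nodes}-node layout "
            f"of {label.name}"
        )
    ids = list(subject_ids) if subject_ids is not None else list(df.index)
    return ProfileMatrix(label, df, ids)


# ---------------------------------------------------------------------------
# bundle -> profile

def _orient_bundle(
    resampled: list[Streamline], anchor: np.ndarray | None
) -> list[Streamline]:
    # Flip each streamline so node 1 sits nearest the anchor. Default anchor:
    # the first streamline's start (which end of a tract is node 1 is a
    # convention; expose it, take no anatomical position).
    ref = resampled[0].points[0] if anchor is None else np.asarray(anchor, dtype=float)
    out = []
    for s in resampled:
        if np.linalg.norm(s.points[0] - ref) <= np.linalg.norm(s.points[-1] - ref):
            out.append(s)
        else:
            samples = None if s.samples is None else s.samples[::-1].copy()
            out.append(Streamline(s.points[::-1].copy(), samples))
    return out


def bundle_profile(
    bundle: StreamlineBundle,
    label: TractLabel,
    weighting: Literal["gaussian", "uniform"] = "gaussian",
    anchor: Sequence[float] | None = None,
    clean: bool = True,
) -> TractProfile:
    """Quantify a streamline bundle into a per-node FA profile.

    Steps: optional outlier cleaning, orientation toward ``anchor``,
    resampling to the tract's node count, then a distance-weighted (or
    uniform) average of the per-point FA samples at each node.
    """
    if any(s.samples is None for s in bundle.streamlines):
        raise ValueError("bundle_profile requires per-point scalar samples")
    b = clean_streamline_bundle(bundle, n_nodes=label.n_nodes) if clean else bundle
    res = [resample_to_nodes(s, label.n_nodes) for s in b.streamlines]
    res = _orient_bundle(res, None if anchor is None else np.asarray(anchor))
    samples = np.stack([s.samples for s in res])
    if weighting == "gaussian":
        weights = gaussian_core_weights(res)
    elif weighting == "uniform":
        weights = np.ones_like(samples)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    values = np.clip(weighted_node_average(samples, weights), 0.0, 1.0)
    return TractProfile(label, values)


def read_streamline_text(path: str | Path) -> list[Streamline]:
    """Read the plain-text streamline fixture format.

    One polyline per record: whitespace-delimited ``x y z [sample]`` rows,
    records separated by blank lines. Used only by tests and examples.
    """
    streamlines: list[Streamline] = []
    block: list[list[float]] = []

    def flush() -> None:
        if not block:
            return
        arr = np.array(block, dtype=float)
        if arr.shape[1] == 3:
            streamlines.append(Streamline(arr))
        elif arr.shape[1] == 4:
            streamlines.append(Streamline(arr[:, :3], arr[:, 3]))
        else:
            raise ValueError("rows must be 'x y z' or 'x y z sample'")
        block.clear()

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            flush()
        else:
            block.append([float(tok) for tok in line.split()])
    flush()
    return streamlines
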