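"""Synthetic bilingual-reading cohorts with along-tract FA profiles.

The generator emulates the statistical shape of a developmental tractometry
study: ~40 children (8-12 y) with two reading scores, two phonological-
awareness scores, a visual-spatial score, tone discrimination and nonverbal
IQ; spatially autocorrelated FA profiles over 100-node (direct/anterior) or
30-node (posterior) arcuate segments; subject-level missingness with overlap
constraints; per-tract availability below 1; and node-window effects embedded
at a target partial correlation. Everything is seeded and deterministic.

Behavioral scores are drawn from a multivariate normal on standardized
scales, mapped affinely to the target mean/SD, and clipped to the published
score ranges. Because clipping biases the moments, the pre-clipping mean/SD
are first calibrated by root-finding on the closed-form clipped-normal
moments, so the *post*-clipping moments hit the targets.

FA noise is a Gaussian process over nodes with a squared-exponential
kernel, corr(node_i, node_j) = exp(-(i-j)^2 / (2 ell^2)); an effect of
target partial correlation rho adds beta * u_i over its node window, where
u_i is the subject's standardized behavioral residual after the stated
covariates and beta = noise_sd * rho / sqrt(1 - rho^2), so the realized
partial correlation approaches rho as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from ._rng import child_rng
from .profiles import ProfileMatrix, TractLabel, _node_columns

__all__ = [
    "BehaviorMoments",
    "MissingRule",
    "TractSpec",
    "EffectSpec",
    "SimulationSpec",
    "default_spec",
    "demo_spec",
    "default_behavior_corr",
    "simulate_behavior",
    "simulate_profiles",
    "write_cohort_csv",
    "read_cohort_csv",
    "spec_to_yaml",
    "spec_from_yaml",
]

COHORT_COLUMNS = (
    "subject_id",
    "age_years",
    "sex",
    "en_read",
    "cn_read",
    "en_pa",
    "cn_pa",
    "vis_spatial",
    "tone",
    "iq_percentile",
)

#: continuous variables drawn from the correlated normal (order matters)
BEHAVIOR_VARS = (
    "age_years",
    "en_read",
    "cn_read",
    "en_pa",
    "cn_pa",
    "vis_spatial",
    "tone",
    "iq_percentile",
)


@dataclass(frozen=True)
class BehaviorMoments:
    """Target post-clipping mean/SD and the admissible score range."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        if not self.lo < self.hi:
            raise ValueError("range must be non-empty")
        if not self.lo <= self.mean <= self.hi:
            raise ValueError("mean must lie inside the range")


@dataclass(frozen=True)
class MissingRule:
    """Make ``n_missing`` subjects miss ``variable``.

    If ``within`` names another variable, the missing subjects are drawn
    from that variable's already-missing set (overlap constraint), so rules
    are applied in list order.
    """

    variable: str
    n_missing: int
    within: str | None = None


@dataclass(frozen=True)
class TractSpec:
    """One tract segment's profile model."""

    label: TractLabel
    mean_profile: np.ndarray | None = None  # default arch if None
    noise_sd: float = 0.05
    corr_length: float = 5.0  # ell, in nodes
    availability: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if self.corr_length <= 0:
            raise ValueError("autocorrelation length must be positive")
        if not 0.0 < self.availability <= 1.0:
            raise ValueError("availability must lie in (0, 1]")
        if self.mean_profile is not None:
            mp = np.asarray(self.mean_profile, dtype=float)
            if mp.shape != (self.label.n_nodes,):
                raise ValueError(
                    f"mean profile must have {self.label.n_nodes} nodes for "
                    f"{self.label.name}"
                )
            if np.any((mp < 0) | (mp > 1)):
                raise ValueError("mean FA profile must lie in [0, 1]")
            object.__setattr__(self, "mean_profile", mp)


@dataclass(frozen=True)
class EffectSpec:
    """Embedded node-window association with a behavioral variable.

    ``r`` is the target partial correlation (after the stated covariates)
    between FA in the window and the variable.
    """

    tract: str
    node_start: int  # 1-based, inclusive
    node_end: int
    variable: str
    r: float
    covariates: tuple[str, ...] = ("age_years", "sex")

    def __post_init__(self) -> None:
        if not abs(self.r) < 1.0:
            raise ValueError("|effect| must be below 1")
        if not 1 <= self.node_start <= self.node_end:
            raise ValueError("invalid node range")


@dataclass
class SimulationSpec:
    n_subjects: int = 40
    behavior_moments: dict[str, BehaviorMoments] = field(default_factory=dict)
    behavior_corr: pd.DataFrame | None = None
    missing_rules: list[MissingRule] = field(default_factory=list)
    tract_specs: list[TractSpec] = field(default_factory=list)
    effects: list[EffectSpec] = field(default_factory=list)
    male_fraction: float = 25.0 / 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 5:
            raise ValueError("need at least 5 subjects")
        if not self.behavior_moments:
            self.behavior_moments = dict(_TABLE_MOMENTS)
        if self.behavior_corr is None:
            self.behavior_corr = default_behavior_corr()
        self.validate()

    def validate(self) -> None:
        corr = self.behavior_corr
        if list(corr.index) != list(BEHAVIOR_VARS) or list(corr.columns) != list(BEHAVIOR_VARS):
            raise ValueError(f"behavior_corr must be indexed by {BEHAVIOR_VARS}")
        C = corr.to_numpy(dtype=float)
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("behavior_corr is not symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("behavior_corr must have a unit diagonal")
        w = np.linalg.eigvalsh(C)
        if w.min() < -1e-10:
            raise ValueError(
                "behavior_corr is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3g}):\n{corr.round(3)}"
            )
        for var in BEHAVIOR_VARS:
            if var not in self.behavior_moments:
                raise ValueError(f"missing moments for {var!r}")
        names = {t.label.name for t in self.tract_specs}
        if len(names) != len(self.tract_specs):
            raise ValueError("duplicate tract labels")
        total_missing: dict[str, int] = {}
        for rule in self.missing_rules:
            if rule.variable not in COHORT_COLUMNS:
                raise ValueError(f"missing rule names unknown variable {rule.variable!r}")
            if rule.within is not None and total_missing.get(rule.within, 0) < rule.n_missing:
                raise ValueError(
                    f"rule for {rule.variable!r} requires {rule.n_missing} subjects "
                    f"already missing {rule.within!r}; apply that rule first"
                )
            total_missing[rule.variable] = total_missing.get(rule.variable, 0) + rule.n_missing
        for eff in self.effects:
            if eff.tract not in names:
                raise ValueError(f"effect references unknown tract {eff.tract!r}")
            if eff.variable not in COHORT_COLUMNS:
                raise ValueError(f"effect references unknown variable {eff.variable!r}")
            for cov in eff.covariates:
                if cov not in COHORT_COLUMNS:
                    raise ValueError(f"effect covariate {cov!r} unknown")
            n_nodes = next(t.label.n_nodes for t in self.tract_specs if t.label.name == eff.tract)
            if eff.node_end > n_nodes:
                raise ValueError(
                    f"effect window {eff.node_start}-{eff.node_end} exceeds the "
                    f"{n_nodes} nodes of {eff.tract}"
                )


# --- published score moments (raw-score units; IQ in percentiles) -----------

_TABLE_MOMENTS: dict[str, BehaviorMoments] = {
    "age_years": BehaviorMoments(10.1, 1.1, 8.2, 12.0),
    "en_read": BehaviorMoments(16.6, 4.6, 6, 24),
    "cn_read": BehaviorMoments(111.1, 17.2, 70, 140),
    "en_pa": BehaviorMoments(5.6, 2.1, 1, 8),
    "cn_pa": BehaviorMoments(13.9, 4.1, 3, 19),
    "vis_spatial": BehaviorMoments(43.9, 12.3, 21, 79),
    "tone": BehaviorMoments(13.9, 4.3, 5, 20),
    "iq_percentile": BehaviorMoments(75.9, 15.4, 50, 95),
}

# Default inter-variable correlations. Only the two age->reading entries are
# anchored by published step-1 standardized betas (0.633 Chinese, 0.426
# English); the rest are plausible, configurable defaults chosen to mirror
# the regression tables' structure (PA and visual-spatial incremental for
# Chinese reading; PA strong for English reading; see docs/methods.md).
_DEFAULT_CORR = np.array(
    [
        # age   en_rd  cn_rd  en_pa  cn_pa  vs     tone   iq
        [1.000, 0.426, 0.633, 0.300, 0.300, 0.250, 0.250, 0.200],  # age
        [0.426, 1.000, 0.450, 0.583, 0.350, 0.250, 0.200, 0.300],  # en_read
        [0.633, 0.450, 1.000, 0.400, 0.549, 0.481, 0.300, 0.350],  # cn_read
        [0.300, 0.583, 0.400, 1.000, 0.450, 0.200, 0.250, 0.250],  # en_pa
        [0.300, 0.350, 0.549, 0.450, 1.000, 0.250, 0.300, 0.250],  # cn_pa
        [0.250, 0.250, 0.481, 0.200, 0.250, 1.000, 0.200, 0.400],  # vis_spatial
        [0.250, 0.200, 0.300, 0.250, 0.300, 0.200, 1.000, 0.200],  # tone
        [0.200, 0.300, 0.350, 0.250, 0.250, 0.400, 0.200, 1.000],  # iq
    ]
)


def default_behavior_corr() -> pd.DataFrame:
    return pd.DataFrame(_DEFAULT_CORR.copy(), index=BEHAVIOR_VARS, columns=BEHAVIOR_VARS)


def default_mean_profile(n_nodes: int) -> np.ndarray:
    """Gentle mid-tract FA arch around 0.45, a typical along-tract shape."""
    u = np.linspace(0.0, 1.0, n_nodes)
    return 0.42 + 0.08 * np.sin(np.pi * u)


def default_tract_specs() -> list[TractSpec]:
    """Six arcuate segments at the study's per-tract availability rates (of 37)."""
    rates = {
        ("left", "direct"): 35 / 37,
        ("right", "direct"): 30 / 37,
        ("left", "anterior"): 36 / 37,
        ("right", "anterior"): 30 / 37,
        ("left", "posterior"): 37 / 37,
        ("right", "posterior"): 37 / 37,
    }
    return [
        TractSpec(label=TractLabel(h, s), availability=rate)
        for (h, s), rate in rates.items()
    ]


def default_missing_rules() -> list[MissingRule]:
    # four subjects miss the visual-spatial score; the one subject missing
    # Chinese PA is among them
    return [
        MissingRule("vis_spatial", 4),
        MissingRule("cn_pa", 1, within="vis_spatial"),
    ]


def default_spec(seed: int = 0) -> SimulationSpec:
    return SimulationSpec(
        n_subjects=40,
        missing_rules=default_missing_rules(),
        tract_specs=default_tract_specs(),
        effects=[],
        seed=seed,
    )


def demo_spec(seed: int = 0) -> SimulationSpec:
    """Default cohort plus illustrative embedded effects.

    The effect windows mirror the kind of geography such a study reports —
    a language-common window on the left direct segment, an English-unique
    caudal window there, Chinese-unique windows on the right direct and
    anterior segments, and a negative posterior window — at moderate target
    partial correlations. Sizes and windows are generator plumbing, not
    estimates of any real effect.
    """
    spec = default_spec(seed)
    # clearer predictor separation for the Chinese regression demo: age
    # strongest, PA clearly ahead of visual-spatial, modest intercorrelation
    corr = spec.behavior_corr
    for a, b, v in [
        ("age_years", "cn_read", 0.70),
        ("cn_read", "cn_pa", 0.52),
        ("cn_read", "vis_spatial", 0.40),
        ("age_years", "cn_pa", 0.25),
        ("age_years", "vis_spatial", 0.20),
        ("cn_pa", "vis_spatial", 0.15),
    ]:
        corr.loc[a, b] = corr.loc[b, a] = v
    unique_cn = ("age_years", "sex", "en_read")
    unique_en = ("age_years", "sex", "cn_read")
    spec.effects = [
        EffectSpec("left_direct", 37, 45, "cn_read", 0.50),
        EffectSpec("left_direct", 37, 45, "en_read", 0.50),
        EffectSpec("left_direct", 80, 95, "en_read", 0.60, covariates=unique_en),
        EffectSpec("right_anterior", 8, 48, "cn_read", 0.60, covariates=unique_cn),
        EffectSpec("right_direct", 53, 61, "cn_read", 0.50, covariates=unique_cn),
        EffectSpec("right_posterior", 6, 10, "cn_read", -0.50, covariates=unique_cn),
    ]
    spec.validate()
    return spec


# --- clipped-normal moment calibration --------------------------------------

def _clipped_moments(mu: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mass = Fb - Fa
    m1 = lo * Fa + hi * (1 - Fb) + mu * mass - sd * (fb - fa)
    # E[X^2] on the interior: integral of (mu + sd z)^2 phi(z)
    int_z = fa - fb
    int_z2 = mass + a * fa - b * fb
    m2 = (
        lo**2 * Fa
        + hi**2 * (1 - Fb)
        + mu**2 * mass
        + 2 * mu * sd * int_z
        + sd**2 * int_z2
    )
    var = m2 - m1**2
    return m1, float(np.sqrt(max(var, 0.0)))


@lru_cache(maxsize=256)
def _calibrate_clipped(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Pre-clipping (mu, sd) whose clipped-normal moments equal the targets."""
    half = (hi - lo) / 2.0
    if sd >= half:
        raise ValueError(
            f"target SD {sd} is infeasible on [{lo}, {hi}] (clipped SD < {half:.3g})"
        )

    def loss(theta: np.ndarray) -> np.ndarray:
        m1, s1 = _clipped_moments(theta[0], np.exp(theta[1]), lo, hi)
        return np.array([m1 - mean, s1 - sd])

    sol = optimize.root(loss, x0=np.array([mean, np.log(sd)]), method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise RuntimeError(
            f"clipped-normal calibration failed for mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


# --- behavior ---------------------------------------------------------------

def simulate_behavior(spec: SimulationSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table (one row per subject, NaN for missing scores)."""
    seed = spec.seed if seed is None else seed
    n = spec.n_subjects
    rng = child_rng(seed, "behavior")

    C = spec.behavior_corr.to_numpy(dtype=float)
    w, V = np.linalg.eigh(C)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, len(BEHAVIOR_VARS))) @ L.T

    data: dict[str, np.ndarray] = {}
    for j, var in enumerate(BEHAVIOR_VARS):
        m = spec.behavior_moments[var]
        mu, sd = _calibrate_clipped(m.mean, m.sd, m.lo, m.hi)
        data[var] = np.clip(mu + sd * z[:, j], m.lo, m.hi)

    # sex: exact counts per the configured proportion, independent of scores
    n_male = int(round(spec.male_fraction * n))
    sex = np.zeros(n, dtype=int)
    sex[child_rng(seed, "behavior", 1).choice(n, size=n_male, replace=False)] = 1

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(1, n + 1)],
            "age_years": data["age_years"],
            "sex": sex,
            **{v: data[v] for v in BEHAVIOR_VARS if v != "age_years"},
        }
    )[list(COHORT_COLUMNS)]

    # missingness: random subjects subject to overlap constraints, exact counts
    mrng = child_rng(seed, "missingness")
    missing_sets: dict[str, np.ndarray] = {}
    for rule in spec.missing_rules:
        pool = missing_sets[rule.within] if rule.within else np.arange(n)
        if rule.n_missing > pool.size:
            raise ValueError(
                f"cannot make {rule.n_missing} subjects miss {rule.variable!r} "
                f"from a pool of {pool.size}"
            )
        chosen = mrng.choice(pool, size=rule.n_missing, replace=False)
        prev = missing_sets.get(rule.variable, np.array([], dtype=int))
        missing_sets[rule.variable] = np.union1d(prev, chosen)
        cohort.loc[chosen, rule.variable] = np.nan
    return cohort


# --- profiles ---------------------------------------------------------------

def _sq_exp_chol(n_nodes: int, ell: float) -> np.ndarray:
    d = np.arange(n_nodes)
    K = np.exp(-0.5 * ((d[:, None] - d[None, :]) / ell) ** 2)
    return np.linalg.cholesky(K + 1e-9 * np.eye(n_nodes))


def _standardized_residual(
    cohort: pd.DataFrame, variable: str, covariates: Sequence[str]
) -> np.ndarray:
    """Z-scored residual of the variable after the covariates; 0 where missing."""
    cols = [variable, *covariates]
    sub = cohort[cols].astype(float)
    ok = sub.notna().all(axis=1).to_numpy()
    u = np.zeros(len(cohort))
    if ok.sum() < len(covariates) + 3:
        raise ValueError(f"too few complete cases to residualize {variable!r}")
    y = sub.loc[ok, variable].to_numpy()
    D = np.column_stack([np.ones(int(ok.sum()))] + [sub.loc[ok, c].to_numpy() for c in covariates])
    res = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    sd = res.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{variable!r} has zero residual variance")
    u[ok] = res / sd
    return u


def simulate_profiles(
    spec: SimulationSpec, cohort: pd.DataFrame, seed: int | None = None
) -> list[ProfileMatrix]:
    """Draw one ProfileMatrix per tract spec, with effects and availability."""
    seed = spec.seed if seed is None else seed
    n = len(cohort)
    ids = cohort["subject_id"].astype(str).tolist()
    out: list[ProfileMatrix] = []
    for t_idx, tspec in enumerate(spec.tract_specs):
        nn = tspec.label.n_nodes
        rng = child_rng(seed, "profiles", t_idx)
        mean = (
            tspec.mean_profile
            if tspec.mean_profile is not None
            else default_mean_profile(nn)
        )
        Lk = _sq_exp_chol(nn, tspec.corr_length)
        noise = tspec.noise_sd * (rng.standard_normal((n, nn)) @ Lk.T)
        fa = mean[None, :] + noise
        for eff in spec.effects:
            if eff.tract != tspec.label.name:
                continue
            u = _standardized_residual(cohort, eff.variable, eff.covariates)
            beta = tspec.noise_sd * eff.r / np.sqrt(1.0 - eff.r**2)
            fa[:, eff.node_start - 1 : eff.node_end] += beta * u[:, None]
        fa = np.clip(fa, 0.0, 1.0)
        avail = child_rng(seed, "availability", t_idx).random(n) < tspec.availability
        df = pd.DataFrame(
            fa[avail],
            index=pd.Index([sid for sid, a in zip(ids, avail) if a], name="subject_id"),
            columns=_node_columns(nn),
        )
        out.append(ProfileMatrix(tspec.label, df, ids))
    return out


# --- I/O --------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Delimited text with header; missing values as empty fields."""
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort file lacks column(s) {missing}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def spec_to_yaml(spec: SimulationSpec, path: str | Path | None = None) -> str:
    doc = {
        "n_subjects": spec.n_subjects,
        "male_fraction": spec.male_fraction,
        "seed": spec.seed,
        "behavior_moments": {
            v: {"mean": m.mean, "sd": m.sd, "lo": m.lo, "hi": m.hi}
            for v, m in spec.behavior_moments.items()
        },
        "behavior_corr": [
            [float(x) for x in row] for row in spec.behavior_corr.to_numpy()
        ],
        "missing_rules": [
            {"variable": r.variable, "n_missing": r.n_missing, "within": r.within}
            for r in spec.missing_rules
        ],
        "tracts": [
            {
                "hemisphere": t.label.hemisphere,
                "segment": t.label.segment,
                "noise_sd": t.noise_sd,
                "corr_length": t.corr_length,
                "availability": t.availability,
                "mean_profile": None
                if t.mean_profile is None
                else [float(x) for x in t.mean_profile],
            }
            for t in spec.tract_specs
        ],
        "effects": [
            {
                "tract": e.tract,
                "node_start": e.node_start,
                "node_end": e.node_end,
                "variable": e.variable,
                "r": e.r,
                "covariates": list(e.covariates),
            }
            for e in spec.effects
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def spec_from_yaml(source: str | Path) -> SimulationSpec:
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    moments = {
        v: BehaviorMoments(d["mean"], d["sd"], d["lo"], d["hi"])
        for v, d in doc.get("behavior_moments", {}).items()
    }
    corr = doc.get("behavior_corr")
    return SimulationSpec(
        n_subjects=doc["n_subjects"],
        behavior_moments=moments,
        behavior_corr=None
        if corr is None
        else pd.DataFrame(np.asarray(corr, dtype=float), index=BEHAVIOR_VARS, columns=BEHAVIOR_VARS),
        missing_rules=[
            MissingRule(d["variable"], d["n_missing"], d.get("within"))
            for d in doc.get("missing_rules", [])
        ],
        tract_specs=[
            TractSpec(
                label=TractLabel(d["hemisphere"], d["segment"]),
                mean_profile=d.get("mean_profile"),
                noise_sd=d.get("noise_sd", 0.05),
                corr_length=d.get("corr_length", 5.0),
                availability=d.get("availability", 1.0),
            )
            for d in doc.get("tracts", [])
        ],
        effects=[
            EffectSpec(
                tract=d["tract"],
                node_start=d["node_start"],
                node_end=d["node_end"],
                variable=d["variable"],
                r=d["r"],
                covariates=tuple(d.get("covariates", ("age_years", "sex"))),
            )
            for d in doc.get("effects", [])
        ],
        male_fraction=doc.get("male_fraction", 25.0 / 40.0),
        seed=doc.get("seed", 0),
    )
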