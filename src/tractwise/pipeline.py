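"""End-to-end analysis pipeline.

Stages, in order: obtain data (simulate or load) -> node-wise covariate-
controlled maps per tract for each outcome -> conjunction of the two
languages' maps -> language-unique maps (other language's reading added as a
covariate) -> max-cluster-size permutation FWE -> stringent/lenient labeling
-> cluster follow-up (mean-FA correlations with cognitive scores, bootstrap
CIs, Fisher comparisons) -> hierarchical stepwise regressions. Every stage
calls the module-level functions directly, so a value in the report equals
what the standalone function returns.

All tabular outputs are header-bearing delimited text with floats at 6
decimals; a full-precision (17 significant digits) sidecar accompanies each
table. A manifest records the seed, config hash, and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import (
    PermutationNull,
    _critical_size,
    classify_clusters,
    clusters_to_frame,
    find_clusters,
    permutation_fwe,
)
from .followup import cluster_mean_value, fisher_z_independent, followup_partial_corr
from .nodewise import conjunction_nodes, nodewise_partial_map
from .profiles import ProfileMatrix, read_profile_csv, TractLabel
from .simulate import (
    SimulationSpec,
    read_cohort_csv,
    simulate_behavior,
    simulate_profiles,
    spec_from_yaml,
    spec_to_yaml,
    write_cohort_csv,
)
from .profiles import write_profile_csv

__all__ = ["AnalysisConfig", "run_pipeline", "load_config"]

log = logging.getLogger("tractwise")

#: cognitive follow-up measures probed per outcome
DEFAULT_FOLLOWUP = {
    "en_read": ("en_pa", "vis_spatial"),
    "cn_read": ("vis_spatial", "cn_pa", "tone"),
}


@dataclass
class AnalysisConfig:
    """Recipe for one full run.

    Either ``simulation`` (a :class:`SimulationSpec`) or ``cohort_path`` +
    ``profile_paths`` must be provided. The conjunction pair is analyzed
    with the shared covariates; each unique analysis adds the other
    language's reading score to the covariates.
    """

    simulation: SimulationSpec | None = None
    cohort_path: str | None = None
    profile_paths: dict[str, str] = field(default_factory=dict)
    conjunction_pair: tuple[str, str] = ("cn_read", "en_read")
    covariates: tuple[str, ...] = ("age_years", "sex")
    unique_analyses: list[tuple[str, str]] = field(
        default_factory=lambda: [("en_read", "cn_read"), ("cn_read", "en_read")]
    )
    followup_measures: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FOLLOWUP.items()}
    )
    regressions: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "cn_read": ("age_years", "sex", "cn_pa", "vis_spatial"),
            "en_read": ("age_years", "sex", "en_pa", "vis_spatial"),
        }
    )
    n_perm: int = 1000
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    scheme: str = "shuffle"
    family_correction: str = "pooled"  # or "per-analysis"
    out_dir: str = "tractwise_out"

    def validate(self) -> None:
        if self.simulation is None and (
            self.cohort_path is None or not self.profile_paths
        ):
            raise ValueError("config needs either a simulation spec or data paths")
        for outcome, extra in self.unique_analyses:
            covs = (*self.covariates, extra)
            if "age_years" not in covs or "sex" not in covs:
                raise ValueError("unique analyses must control age and sex")


def load_config(path: str | Path) -> AnalysisConfig:
    doc = yaml.safe_load(Path(path).read_text())
    sim = doc.get("simulation")
    cfg = AnalysisConfig(
        simulation=None if sim is None else spec_from_yaml(yaml.safe_dump(sim)),
        cohort_path=doc.get("cohort_path"),
        profile_paths=doc.get("profile_paths", {}),
        conjunction_pair=tuple(doc.get("conjunction_pair", ("cn_read", "en_read"))),
        covariates=tuple(doc.get("covariates", ("age_years", "sex"))),
        unique_analyses=[tuple(u) for u in doc.get("unique_analyses", [("en_read", "cn_read"), ("cn_read", "en_read")])],
        followup_measures={k: tuple(v) for k, v in doc.get("followup_measures", DEFAULT_FOLLOWUP).items()},
        regressions={k: tuple(v) for k, v in doc.get("regressions", {}).items()}
        or AnalysisConfig().regressions,
        n_perm=doc.get("n_perm", 1000),
        alpha=doc.get("alpha", 0.05),
        n_boot=doc.get("n_boot", 1000),
        seed=doc.get("seed", 0),
        scheme=doc.get("scheme", "shuffle"),
        out_dir=doc.get("out_dir", "tractwise_out"),
    )
    cfg.validate()
    return cfg


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = path.with_suffix(".full.csv")
    df.to_csv(sidecar, index=False, float_format="%.17g")


def _stage(name: str):
    start = time.perf_counter()
    log.info("stage %s ...", name)
    return lambda: log.info("stage %s done in %.2fs", name, time.perf_counter() - start)


def _load_data(cfg: AnalysisConfig) -> tuple[pd.DataFrame, list[ProfileMatrix]]:
    if cfg.simulation is not None:
        cohort = simulate_behavior(cfg.simulation, seed=cfg.seed)
        profiles = simulate_profiles(cfg.simulation, cohort, seed=cfg.seed)
        return cohort, profiles
    cohort = read_cohort_csv(cfg.cohort_path)
    ids = cohort["subject_id"].tolist()
    profiles = [
        read_profile_csv(path, TractLabel.from_name(name), ids)
        for name, path in cfg.profile_paths.items()
    ]
    return cohort, profiles


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute every stage and write the report bundle under ``cfg.out_dir``.

    Returns the report as a dict of DataFrames / objects for programmatic
    use; identical config + seed reproduce identical files.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    done = _stage("data")
    cohort, profiles = _load_data(cfg)
    write_cohort_csv(cohort, out / "cohort.csv")
    for pm in profiles:
        write_profile_csv(pm, out / f"profile_{pm.label.name}.csv")
    done()

    a_out, b_out = cfg.conjunction_pair
    nodewise_rows, cluster_rows, conj_rows, followup_rows, fisher_rows = [], [], [], [], []

    # conjunction maps, then the language-unique maps with their permutation nulls
    unique_runs: list[tuple[ProfileMatrix, str, object, object]] = []
    for pm in profiles:
        done = _stage(f"maps[{pm.label.name}]")
        try:
            map_a = nodewise_partial_map(pm, a_out, cfg.covariates, cohort)
            map_b = nodewise_partial_map(pm, b_out, cfg.covariates, cohort)
        except ValueError as err:
            raise RuntimeError(f"stage maps, tract {pm.label.name}: {err}") from err
        for m, tag in ((map_a, a_out), (map_b, b_out)):
            df = m.to_frame()
            df.insert(1, "analysis", f"{tag}|{'+'.join(cfg.covariates)}")
            nodewise_rows.append(df)
        conj = conjunction_nodes(map_a, map_b, cfg.alpha)
        conj_rows.append(pd.DataFrame({"tract": pm.label.name, "node": conj}))

        for outcome, extra in cfg.unique_analyses:
            covs = (*cfg.covariates, extra)
            try:
                m = nodewise_partial_map(pm, outcome, covs, cohort)
                null = permutation_fwe(
                    pm, outcome, covs, cohort,
                    n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed,
                    scheme=cfg.scheme,  # type: ignore[arg-type]
                )
            except ValueError as err:
                raise RuntimeError(
                    f"stage permtest, tract {pm.label.name}, outcome {outcome}: {err}"
                ) from err
            df = m.to_frame()
            df.insert(1, "analysis", f"{outcome}|{'+'.join(covs)}")
            nodewise_rows.append(df)
            unique_runs.append((pm, outcome, m, null))
            (out / "null_distributions").mkdir(exist_ok=True)
            pd.Series(null.max_sizes).to_csv(
                out / "null_distributions" / f"{pm.label.name}_{outcome}.txt",
                index=False, header=False,
            )
        done()

    # family correction: pool the per-permutation maxima over all analyses
    # sharing a node count, so one critical size governs each family and the
    # run-level error rate stays near alpha despite many tract/outcome maps
    done = _stage("clusters")
    if cfg.family_correction == "pooled":
        pooled: dict[int, PermutationNull] = {}
        for nn in {pm.n_nodes for pm, *_ in unique_runs}:
            stacked = np.stack(
                [null.max_sizes for pm, _, _, null in unique_runs if pm.n_nodes == nn]
            )
            family_max = stacked.max(axis=0)
            pooled[nn] = PermutationNull(
                n_perm=cfg.n_perm,
                alpha=cfg.alpha,
                max_sizes=family_max,
                critical_size=_critical_size(family_max, cfg.alpha, nn),
            )
        nulls = {id(run): pooled[run[0].n_nodes] for run in unique_runs}
    elif cfg.family_correction == "per-analysis":
        nulls = {id(run): run[3] for run in unique_runs}
    else:
        raise ValueError(f"unknown family_correction {cfg.family_correction!r}")
    done()

    for run in unique_runs:
        pm, outcome, m, _ = run
        null = nulls[id(run)]
        clusters = classify_clusters(find_clusters(m, cfg.alpha), null, pm.n_nodes)
        cdf = clusters_to_frame(clusters)
        cdf.insert(1, "analysis", outcome)
        cdf["critical_size"] = null.critical_size
        cluster_rows.append(cdf)

        # follow-up on clusters that pass at least the lenient level
        for cl in clusters:
            if cl.label == "subthreshold":
                continue
            means = cluster_mean_value(pm, cl)
            measures = cfg.followup_measures.get(outcome, ())
            results = {}
            for meas in measures:
                r, dof, p, ci = followup_partial_corr(
                    means, meas, cohort,
                    covariates=cfg.covariates, n_boot=cfg.n_boot, seed=cfg.seed,
                )
                results[meas] = (r, dof, p, ci)
                followup_rows.append(
                    {
                        "tract": pm.label.name,
                        "analysis": outcome,
                        "cluster": f"{cl.start}-{cl.end}",
                        "label": cl.label,
                        "measure": meas,
                        "r": r,
                        "df": dof,
                        "p": p,
                        "ci_low": ci.lower,
                        "ci_high": ci.upper,
                        "n": dof + 2 + len(cfg.covariates),
                    }
                )
            for i, m1 in enumerate(measures):
                for m2 in measures[i + 1:]:
                    r1, d1, *_ = results[m1]
                    r2, d2, *_ = results[m2]
                    n1 = d1 + 2 + len(cfg.covariates)
                    n2 = d2 + 2 + len(cfg.covariates)
                    cmp_ = fisher_z_independent(r1, n1, r2, n2)
                    fisher_rows.append(
                        {
                            "tract": pm.label.name,
                            "analysis": outcome,
                            "cluster": f"{cl.start}-{cl.end}",
                            "measure_1": m1,
                            "measure_2": m2,
                            "r1": r1, "n1": n1, "r2": r2, "n2": n2,
                            "z": cmp_.z, "p": cmp_.p,
                        }
                    )

    done = _stage("regressions")
    from .stepwise import stepwise_select

    regress_rows = []
    for dep, candidates in cfg.regressions.items():
        model = stepwise_select(cohort, dep, candidates)
        df = model.to_frame()
        df.insert(0, "dependent", dep)
        regress_rows.append(df)
        report[f"regression_{dep}"] = model
    done()

    tables = {
        "nodewise.csv": pd.concat(nodewise_rows, ignore_index=True),
        "conjunction.csv": pd.concat(conj_rows, ignore_index=True),
        "clusters.csv": pd.concat(
            [df for df in cluster_rows if len(df)], ignore_index=True
        )
        if any(len(df) for df in cluster_rows)
        else clusters_to_frame([]),
        "followup.csv": pd.DataFrame(followup_rows),
        "fisher.csv": pd.DataFrame(fisher_rows),
        "regressions.csv": pd.concat(regress_rows, ignore_index=True),
    }
    for name, df in tables.items():
        _write_table(df, out / name)
        report[name.removesuffix(".csv")] = df

    cfg_text = yaml.safe_dump(
        {
            "conjunction_pair": list(cfg.conjunction_pair),
            "covariates": list(cfg.covariates),
            "unique_analyses": [list(u) for u in cfg.unique_analyses],
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
            "scheme": cfg.scheme,
            "simulation": None if cfg.simulation is None else yaml.safe_load(spec_to_yaml(cfg.simulation)),
        },
        sort_keys=True,
    )
    manifest = {
        "package": "tractwise",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "tables": sorted(tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report["manifest"] = manifest
    return report


def setup_logging(quiet: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.WARNING if quiet else logging.INFO,
        format="%(asctime)s %(name)s %(message)s",
    )
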