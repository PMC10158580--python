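"""Follow-up statistics on the surviving clusters.

For every cluster that passed at least the lenient threshold: per-subject
mean FA over the cluster, partial correlation (age and sex controlled) with
the candidate cognitive measures for that language, percentile-bootstrap 95%
CIs on the residualized pairs, and Fisher r-to-z comparisons between the
measures. Writes results/followup/{followup,fisher}.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from tractwise.clusters import Cluster
from tractwise.followup import cluster_mean_value, fisher_z_independent, followup_partial_corr
from tractwise.profiles import TractLabel, read_profile_csv
from tractwise.simulate import read_cohort_csv

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "followup"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
MEASURES = {
    "en_read": ("en_pa", "vis_spatial"),
    "cn_read": ("vis_spatial", "cn_pa", "tone"),
}
COVS = ("age_years", "sex")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(BASE / "cohort" / "cohort.csv")
    ids = cohort["subject_id"].tolist()
    clusters = pd.read_csv(BASE / "clusters" / "clusters.csv")
    surviving = clusters[clusters["label"] != "subthreshold"]

    rows, fisher_rows = [], []
    for _, c in surviving.iterrows():
        label = TractLabel.from_name(c["tract"])
        pm = read_profile_csv(BASE / "cohort" / f"profile_{c['tract']}.csv", label, ids)
        cl = Cluster(c["tract"], int(c["start"]), int(c["end"]), int(c["sign"]), float(c["min_p"]))
        means = cluster_mean_value(pm, cl)
        results = {}
        for meas in MEASURES[c["analysis"]]:
            r, dof, p, ci = followup_partial_corr(means, meas, cohort, covariates=COVS, seed=SEED)
            n = dof + 2 + len(COVS)
            results[meas] = (r, n)
            rows.append({"tract": c["tract"], "analysis": c["analysis"],
                         "cluster": f"{cl.start}-{cl.end}", "label": c["label"],
                         "measure": meas, "r": r, "df": dof, "p": p,
                         "ci_low": ci.lower, "ci_high": ci.upper, "n": n})
            star = "*" if p < 0.05 else " "
            print(f"{c['tract']} {cl.start}-{cl.end} x {meas}: r={r:.3f} p={p:.3f}{star} "
                  f"CI[{ci.lower:.3f},{ci.upper:.3f}] n={n}")
        meas_list = list(MEASURES[c["analysis"]])
        for i, m1 in enumerate(meas_list):
            for m2 in meas_list[i + 1:]:
                (r1, n1), (r2, n2) = results[m1], results[m2]
                cmp_ = fisher_z_independent(r1, n1, r2, n2)
                fisher_rows.append({"tract": c["tract"], "cluster": f"{cl.start}-{cl.end}",
                                    "measure_1": m1, "measure_2": m2,
                                    "r1": r1, "n1": n1, "r2": r2, "n2": n2,
                                    "z": cmp_.z, "p": cmp_.p})
                print(f"  Fisher z ({m1} vs {m2}): z={cmp_.z:.2f} p={cmp_.p:.3f}")

    pd.DataFrame(rows).to_csv(OUT / "followup.csv", index=False, float_format="%.6f")
    pd.DataFrame(fisher_rows).to_csv(OUT / "fisher.csv", index=False, float_format="%.6f")
    print(f"wrote follow-up tables for {len(surviving)} clusters to {OUT}")


if __name__ == "__main__":
    main()
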