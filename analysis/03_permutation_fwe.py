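"""Cluster formation and max-cluster-size permutation FWE correction.

For each language-unique analysis on each tract: form suprathreshold
clusters (node p < 0.05, constant sign), build the 1,000-permutation null of
the maximum cluster size, pool the per-permutation maxima across analyses
sharing a node count, and label each cluster stringent (size >= pooled c*),
lenient (>= 9 of 100 or >= 3 of 30 adjacent nodes), or subthreshold.
Writes results/clusters/clusters.csv and the null distributions.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tractwise.clusters import (
    PermutationNull,
    _critical_size,
    classify_clusters,
    clusters_to_frame,
    find_clusters,
    permutation_fwe,
)
from tractwise.nodewise import nodewise_partial_map
from tractwise.profiles import TractLabel, read_profile_csv
from tractwise.simulate import read_cohort_csv

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "clusters"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_PERM = 1000
ALPHA = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(BASE / "cohort" / "cohort.csv")
    ids = cohort["subject_id"].tolist()

    runs = []
    for path in sorted((BASE / "cohort").glob("profile_*.csv")):
        label = TractLabel.from_name(path.stem.removeprefix("profile_"))
        pm = read_profile_csv(path, label, ids)
        for outcome, covs in [
            ("cn_read", ("age_years", "sex", "en_read")),
            ("en_read", ("age_years", "sex", "cn_read")),
        ]:
            m = nodewise_partial_map(pm, outcome, covs, cohort)
            null = permutation_fwe(pm, outcome, covs, cohort, n_perm=N_PERM, alpha=ALPHA, seed=SEED)
            runs.append((pm, outcome, m, null))
            np.savetxt(OUT / f"null_{label.name}_{outcome}.txt", null.max_sizes, fmt="%d")

    # pooled family correction per node count
    pooled = {}
    for nn in {pm.n_nodes for pm, *_ in runs}:
        fam = np.stack([null.max_sizes for pm, _, _, null in runs if pm.n_nodes == nn]).max(axis=0)
        pooled[nn] = PermutationNull(N_PERM, ALPHA, fam, _critical_size(fam, ALPHA, nn))
        print(f"{nn}-node family: stringent critical size c* = {pooled[nn].critical_size}")

    frames = []
    for pm, outcome, m, _ in runs:
        labeled = classify_clusters(find_clusters(m, ALPHA), pooled[pm.n_nodes], pm.n_nodes)
        df = clusters_to_frame(labeled)
        df.insert(1, "analysis", outcome)
        df["critical_size"] = pooled[pm.n_nodes].critical_size
        frames.append(df)
        for cl in labeled:
            if cl.label != "subthreshold":
                print(f"  {pm.label.name} / {outcome}: nodes {cl.start}-{cl.end} "
                      f"(size {cl.size}, sign {cl.sign:+d}) -> {cl.label}")

    all_df = pd.concat([f for f in frames if len(f)], ignore_index=True) if any(len(f) for f in frames) else clusters_to_frame([])
    all_df.to_csv(OUT / "clusters.csv", index=False, float_format="%.6f")
    print(f"wrote {len(all_df)} clusters to {OUT / 'clusters.csv'}")


if __name__ == "__main__":
    main()
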