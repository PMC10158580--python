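"""Node-wise correlation maps and the two-language conjunction.

For every tract: partial correlation of FA at each node with Chinese and
English reading (controlling age and sex), the conjunction of the two maps,
and the language-unique maps that additionally control the other language's
reading score. Writes results/nodewise/{nodewise,conjunction}.csv.
"""

from pathlib import Path

import pandas as pd

from tractwise.nodewise import conjunction_nodes, nodewise_partial_map
from tractwise.profiles import TractLabel, read_profile_csv
from tractwise.simulate import read_cohort_csv

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "nodewise"
ALPHA = 0.05


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(BASE / "cohort" / "cohort.csv")
    ids = cohort["subject_id"].tolist()

    rows, conj_rows = [], []
    for path in sorted((BASE / "cohort").glob("profile_*.csv")):
        label = TractLabel.from_name(path.stem.removeprefix("profile_"))
        pm = read_profile_csv(path, label, ids)
        maps = {}
        for outcome, covs in [
            ("cn_read", ("age_years", "sex")),
            ("en_read", ("age_years", "sex")),
            ("cn_read", ("age_years", "sex", "en_read")),
            ("en_read", ("age_years", "sex", "cn_read")),
        ]:
            m = nodewise_partial_map(pm, outcome, covs, cohort)
            maps[(outcome, covs)] = m
            df = m.to_frame()
            df.insert(1, "analysis", f"{outcome}|{'+'.join(covs)}")
            rows.append(df)
        conj = conjunction_nodes(
            maps[("cn_read", ("age_years", "sex"))],
            maps[("en_read", ("age_years", "sex"))],
            ALPHA,
        )
        conj_rows.append(pd.DataFrame({"tract": label.name, "node": conj}))
        if len(conj):
            print(f"{label.name}: {len(conj)} conjunction nodes "
                  f"({conj.min()}-{conj.max()})")

    pd.concat(rows, ignore_index=True).to_csv(OUT / "nodewise.csv", index=False, float_format="%.6f")
    pd.concat(conj_rows, ignore_index=True).to_csv(OUT / "conjunction.csv", index=False)
    print(f"wrote node-wise maps for {len(conj_rows)} tracts to {OUT}")


if __name__ == "__main__":
    main()
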