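"""Hierarchical stepwise regressions predicting reading skill.

Chinese reading on {age, sex, Chinese PA, visual-spatial} and English
reading on {age, sex, English PA, visual-spatial}, forward entry at
probability-of-F 0.05 with backward removal at 0.10, standardized
coefficients. Writes results/regression/regressions.csv.
"""

from pathlib import Path

import pandas as pd

from tractwise.simulate import read_cohort_csv
from tractwise.stepwise import stepwise_select

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "regression"
MODELS = {
    "cn_read": ("age_years", "sex", "cn_pa", "vis_spatial"),
    "en_read": ("age_years", "sex", "en_pa", "vis_spatial"),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(BASE / "cohort" / "cohort.csv")
    frames = []
    for dep, candidates in MODELS.items():
        model = stepwise_select(cohort, dep, candidates)
        print(f"{dep} (n={model.n}): entry order {' -> '.join(model.entry_order) or '(none)'}; "
              f"excluded {sorted(model.excluded)}")
        for s in model.steps:
            print(f"  step {s.index}: R2={s.r2:.3f} dR2={s.r2_change:.3f} F={s.f:.3f}")
        df = model.to_frame()
        df.insert(0, "dependent", dep)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(OUT / "regressions.csv", index=False, float_format="%.6f")
    print(f"wrote regression tables to {OUT / 'regressions.csv'}")


if __name__ == "__main__":
    main()
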