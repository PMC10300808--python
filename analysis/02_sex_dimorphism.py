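#!/usr/bin/env python
"""Compare the eight proportions between the sexes.

Reads results/cohort.csv, measures per-specimen proportions, screens each
sex x proportion distribution with a KS normality test, and compares the
sexes with Welch t-tests under Benjamini-Hochberg correction.  Writes
results/proportions.csv, results/normality.csv and
results/sex_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from cephalomorph import compare_groups, measure_proportions, normality_report, read_landmarks

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    specimens = read_landmarks(ROOT / "cohort.csv")
    rows = []
    by_sex = {"female": [], "male": []}
    for lm in specimens:
        p = measure_proportions(lm)
        by_sex[lm.sex].append(p)
        rows.append({"specimen_id": lm.specimen_id, "sex": lm.sex, **p.as_dict()})
    pd.DataFrame(rows).to_csv(ROOT / "proportions.csv", index=False)

    screen = normality_report(by_sex)
    screen.to_csv(ROOT / "normality.csv", index=False)
    n_normal = int(screen["normal_assumed"].sum())

    table = compare_groups(
        by_sex["female"], by_sex["male"], label_a="female", label_b="male"
    )
    table.table.to_csv(ROOT / "sex_comparison.csv")

    print(f"normality screen: {n_normal}/{len(screen)} sex x proportion cells "
          "consistent with a normal distribution")
    print(f"{table.n_significant}/8 proportions differ significantly between "
          "the sexes after BH correction:")
    print(table.to_text())


if __name__ == "__main__":
    main()
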