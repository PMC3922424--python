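"""Within-group lateralization patterns and connection-group contrasts.

One-sample t-tests of the lateralization index against zero (BH-FDR per
group over the 91-connection family) describe each group's lateralization
pattern; paired t-tests compare the mean degree of lateralization across
the three connection groups (left-language, left-nonlanguage, right) on a
common magnitude scale.  Writes results/one_sample_patterns.csv,
results/group_means.csv and results/group_contrasts.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hemiflip.lateralize import connection_group_means
from hemiflip.stats import one_sample_lateralization, paired_group_contrasts

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    li_table = pd.read_csv(RESULTS / "li_table.csv")
    phenotypes = pd.read_csv(RESULTS / "phenotypes.csv")
    groups = pd.Series(
        np.where(phenotypes["diagnosis"] == "control", "control", "autism"),
        index=phenotypes["subject_id"])

    patterns = one_sample_lateralization(li_table, q=0.05, by_group=groups)
    patterns.to_csv(RESULTS / "one_sample_patterns.csv", index=False)
    for grp, sub in patterns.groupby("dx_group"):
        left = sub[sub["laterality_class"] == "left-lateralized"]
        right = sub[sub["laterality_class"] == "right-lateralized"]
        print(f"{grp:8s} mean LI: left connections {left['mean_li'].mean():+.3f}, "
              f"right connections {right['mean_li'].mean():+.3f}; "
              f"{int(sub['fdr_significant'].sum())}/{len(sub)} FDR-significant")

    triples = connection_group_means(li_table)
    triples.to_csv(RESULTS / "group_means.csv", index=False)
    contrasts = paired_group_contrasts(triples, groups)
    contrasts.to_csv(RESULTS / "group_contrasts.csv", index=False)
    print("\nconnection-group contrasts (positive t: first group more lateralized):")
    for _, r in contrasts.iterrows():
        print(f"  {r['dx_group']:8s} {r['contrast']:36s} "
              f"t({r['df']:.0f}) = {r['t']:6.2f}, p = {r['p']:.4f}")


if __name__ == "__main__":
    main()
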