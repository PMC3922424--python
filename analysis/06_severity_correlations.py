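"""Brain-behaviour correlations on the abnormal connections.

For every connection flagged by 04_group_differences.py: Pearson r between
the lateralization index and symptom severity (ADOS social + communication
totals) in the autism group (and in everyone with ADOS scores), plus
Spearman rho against age and quantitative handedness per group.  Since the
demo generator draws phenotypes independently of the planted connectivity
deficit, these correlations are expected to be null — the script documents
the machinery, not an effect.  Writes results/phenotype_correlations.csv.
"""

from pathlib import Path

import pandas as pd

from hemiflip.stats import phenotype_correlations

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    li_table = pd.read_csv(RESULTS / "li_table.csv")
    phenotypes = pd.read_csv(RESULTS / "phenotypes.csv")
    tests = pd.read_csv(RESULTS / "connection_tests.csv")
    flagged = list(tests.loc[tests["fdr_significant"], "connection"])
    if not flagged:
        print("no FDR-significant connections; nothing to correlate")
        return

    corr = phenotype_correlations(li_table, phenotypes, flagged)
    corr.to_csv(RESULTS / "phenotype_correlations.csv", index=False)
    for _, r in corr.iterrows():
        rv = "n/a" if pd.isna(r["r"]) else f"{r['r']:+.3f}"
        pv = "n/a" if pd.isna(r["p"]) else f"{r['p']:.3f}"
        print(f"  {r['connection']:10s} {r['variable']:17s} "
              f"[{r['dx_group']:13s}] {r['method']:8s} r = {rv}, p = {pv}, "
              f"n = {r['n']}")


if __name__ == "__main__":
    main()
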