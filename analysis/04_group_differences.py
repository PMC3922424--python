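"""Group differences in lateralization under the base inclusion criteria.

Two-sample t-tests (control minus autism) per ipsilateral hub connection
with BH-FDR at q < 0.05 over the 91-connection family, under preset A.
The planted Wernicke--posterior-cingulate deficit should be the flagged
connection.  Writes results/connection_tests.csv and results/report.txt.
"""

from pathlib import Path

import pandas as pd

from hemiflip.pipeline import analyze_lateralization, make_report
from hemiflip.stats import criteria_preset

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    li_table = pd.read_csv(RESULTS / "li_table.csv")
    qc = pd.read_csv(RESULTS / "qc.csv")
    phenotypes = pd.read_csv(RESULTS / "phenotypes.csv")

    criteria = criteria_preset("A", min_site_n=10)
    result = analyze_lateralization(li_table, qc, phenotypes, criteria, q=0.05)
    result.connection_tests.to_csv(RESULTS / "connection_tests.csv", index=False)
    (RESULTS / "report.txt").write_text(make_report(result))

    print(f"included {result.n_control} control / {result.n_autism} autism subjects")
    sig = result.connection_tests.query("fdr_significant")
    print(f"FDR-significant group differences ({len(sig)}):")
    for _, r in sig.iterrows():
        print(f"  {r['connection']:10s} [{r['group']}] "
              f"t({r['df']:.0f}) = {r['t']:.2f}, p = {r['p']:.2e} "
              f"({r['direction']})")


if __name__ == "__main__":
    main()
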