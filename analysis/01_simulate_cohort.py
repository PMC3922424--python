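"""Simulate the demo cohort and write it to disk.

Produces the synthetic study the later scripts analyze: 30 + 30 subjects
over two sites with a planted Fisher-z -0.5 deficit on the
Wernicke--posterior-cingulate connection in the autism group.  Per-subject
4-D NIfTI runs, realignment-parameter text files and nuisance traces go to
scratch/demo_cohort/ (bulky, regenerable); the phenotype table, hub table
and atlas centroids go to results/.
"""

from pathlib import Path

from hemiflip.io import save_atlas, save_bold, save_nuisance
from hemiflip.pipeline import RunConfig
from hemiflip.synthdata import cohort_stream

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "demo_cohort"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = RunConfig.from_yaml(ROOT / "analysis" / "demo_config.yaml")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    atlas, hubs, phenotypes, stream = cohort_stream(cfg.cohort)
    save_atlas(atlas, SCRATCH / "atlas.nii.gz", RESULTS / "atlas_centroids.csv")
    hubs.to_csv(RESULTS / "hubs.csv")
    phenotypes.to_csv(RESULTS / "phenotypes.csv", index=False)

    n = 0
    for record, bold, nuisance in stream:
        save_bold(bold, SCRATCH / f"{record.subject_id}_bold.nii.gz",
                  SCRATCH / f"rp_{record.subject_id}.txt")
        save_nuisance(nuisance, SCRATCH / f"nuisance_{record.subject_id}.csv")
        n += 1

    counts = phenotypes["dx_group"].value_counts()
    print(f"wrote {n} subjects to {SCRATCH}")
    print(f"  groups: {counts.get('control', 0)} control / "
          f"{counts.get('autism', 0)} autism spectrum")
    print(f"  sites: {sorted(phenotypes['site_id'].unique())}")
    print(f"  atlas: {atlas.n_rois} ROIs ({len(hubs.table)} hubs + mirror homologues)")


if __name__ == "__main__":
    main()
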