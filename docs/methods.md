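# Methods

## The lateralization model

For a template-space BOLD run, connectivity between ROIs a and b is the
Fisher z-transformed Pearson correlation of their mean time courses,
z(a, b) = atanh(r(a, b)), with r clipped to |r| ≤ 1 − 10⁻¹² so degenerate
perfect correlations stay finite.  The run is mirrored across the
midsagittal plane — on an even-x grid the mirror plane lies exactly between
the two central voxel columns, so the flip is the index reversal
(i, j, k) ↔ (X−1−i, j, k), an exact involution with no interpolation — and
the same extraction is repeated on the flipped run.  The lateralization
index of a connection is

    LI(a, b) = z_unflipped(a, b) − z_flipped(a, b)

**evaluated at the connection's left-hemisphere ROI instances**: the hubs'
own ROIs for left-network pairs, their mirror homologues for right-network
pairs, and the mirrored position of the right member for mixed pairs.  In
this single frame, positive LI always means "more left-lateralized"; a
right-network connection is right-lateralized when LI < 0, so its degree of
lateralization toward its own hemisphere is −LI.  This convention puts the
three connection groups (left-language, left-nonlanguage, right) on one
magnitude scale for the paired contrasts, and makes mixed pairs
interpretable.  LI is exactly antisymmetric under flipping the input run
(verified bitwise for single-voxel ROIs).

Only ipsilateral hub pairs enter group statistics: with 9 left- and 11
right-network hubs that is C(9,2) = 36 + C(11,2) = 55 = 91 connections, of
which 15 involve a language hub (Broca or Wernicke area) and 21 do not.
Mixed pairs (9 × 11 = 99) are computed on request for pattern maps only.

## Preprocessing

The pipeline consumes already-normalized 4-D runs plus per-volume
realignment parameters and implements only the temporal half of a
resting-state pipeline:

1. **Nuisance extraction** — mean time course over CSF, white-matter and
   soft-tissue restriction masks (for synthetic cohorts the generator
   supplies these traces directly).
2. **Confound regression** — per-voxel least squares on
   [intercept, csf, wm, soft tissue, 6 motion].  Rank-deficient designs are
   not fatal: the minimum-norm solution is used and the dependent columns
   are reported.  Regression is idempotent to numerical precision.
3. **Detrend + band-pass** — linear detrend, then a zero-phase
   frequency-domain brick-wall band-pass with corners 0.001 and 0.1 Hz
   (rejected if the high corner reaches Nyquist).  The filter is linear and
   length-preserving.
4. **Scrubbing** — framewise displacement FD(t) is the sum of absolute
   differenced realignment parameters with rotations converted to arc
   length on a 50-mm-radius sphere (an RMS-of-six-parameters variant is
   available behind `mode="rms"`; the sum-of-absolute-values form is the
   default because it is the standard FD definition).  DVARS(t) is the RMS
   volume-to-volume signal change over a brain mask, expressed as percent
   of the run's mean in-mask intensity; it is computed on the raw,
   unregressed series because regression and detrending remove the mean
   that defines the percent scale.  Any transition with FD or DVARS above
   0.2 flags the two volumes spanning it (t−1 and t); kept volumes are
   concatenated in order.  A run whose volumes are all flagged is an error,
   handled by the inclusion criteria downstream.
5. **No spatial smoothing, ever** (no smoothing operation exists in the
   package — smoothing would mix signal across the midsagittal plane), and
   no global-signal or grey-matter regression.

ROI SNR is the temporal mean over temporal standard deviation of the ROI
mean signal on the *raw* run (before regression removes the mean); a
zero-variance ROI is reported as infinite with a warning.

**Processing order.**  Regression and filtering are both linear projections
but do not commute: measured on synthetic runs, swapping the order changes
individual connectivity values by up to ~0.17 in z while leaving the LI
statistically unchanged (correlation 0.98 between orders, mean difference
≈ 0.002).  The pipeline therefore fixes one order — regression, then
detrend + filter, then scrubbing — and treats the choice as a convention,
not a no-op.

## ROI lattices and hubs

For real grey-matter masks, `build_lattice` places seeds on a regular grid
at 5-mm spacing restricted to mask voxels within the closed z range
[−35, 70] mm, assigns every in-mask voxel to its nearest seed (ties broken
by the lowest seed id after lexicographic (x, y, z) seed ordering, for
determinism), drops empty seeds and renumbers contiguously.  Hub
coordinates are a required input table (name, hemisphere, x, y, z, network,
is_language); each hub maps to the lattice ROI with the nearest centroid,
and the distance is logged.  The package never invents template-space hub
coordinates: the shipped 20-hub table is a synthetic fixture on the test
grid, and `data/hub_template.csv` documents the expected columns for a real
configuration.

## The synthetic cohort generator

The generator defines the study conditions the test suites run under.  Each
hub is a small ROI (a single voxel at the default 5-mm spacing on a 3-mm
grid) placed so that the label field, with every hub's mirror ROI added, is
exactly mirror-symmetric.  Hub signals are latent unit-variance Gaussians
whose correlation structure encodes the couplings: within-network hub pairs
(and their mirror pairs) couple at tanh(base_edge_z); a planted
lateralization effect raises one named pair to tanh(base_edge_z + dz) for
one group while its mirror pair keeps the baseline — so with no effects the
LI distribution is symmetric about zero on every connection by
construction.  Voxel series are latent signal + independent Gaussian noise
on a constant baseline intensity.

Couplings are specified on the *observed* (ROI-mean) scale: the latent
correlation is inflated by the attenuation factor
√((1 + σ²/V_a)(1 + σ²/V_b)) so the expected measured coupling equals the
requested Fisher-z value; requested structures whose latent matrix is not
positive definite (or leaves no room for noise) are rejected with the
offending connections named — never silently repaired, so an injected dz is
recovered without bias.

Realignment traces are random-walk drifts (sd 0.01 mm / 2×10⁻⁴ rad per
step) plus single-volume displacement spikes of 0.4–1.0 mm at a per-volume
group-specific probability (defaults 0.02 control, 0.05 autism group),
reproducing the usual group motion difference; nuisance traces are AR(1)
series independent of the hub signals.  Phenotypes are drawn uniformly
within the printed ranges of the emulated sample (ages ~6.5–64 y, verbal IQ
50–149, ADOS social+communication 2–22 in the autism group, quantitative
handedness −100..100 with a right-handed majority, ~1.5% missing both
handedness measures), with site labels assigned uniformly.  Everything is
keyed off one integer seed through spawned generators, so a spec + seed
reproduces a cohort bit for bit.

Defaults: TR 2 s, 120 volumes, base_edge_z 0.3, noise sd 0.3, baseline
intensity 2000 (spike-free DVARS ≈ 0.07%, far below the 0.2 threshold —
the intensity scale is calibrated to the percent DVARS units, which real
scanners do not share; hub SNR on this scale is correspondingly high and
the 72–110 band of real data is exercised by dedicated tuned tests).  What
the generator does **not** emulate: scanner artifacts, slice-timing and
distortion effects, spatially structured physiological noise, site-specific
pulse sequences, haemodynamic autocorrelation beyond the band-pass, and any
dependence of phenotype on connectivity unless explicitly planted.  Passing
tests therefore demonstrate the correctness and calibration of the
machinery under a known symmetric-null model, not robustness to real-data
confounds.

## Statistics

Per connection: two-sided one-sample t (pattern maps, BH-FDR within each
group's 91-connection family) and two-sided two-sample t, control minus
autism (pooled-variance Student form, df = n₁ + n₂ − 2 minus per-connection
missingness; Welch optional), BH-FDR jointly over the tested family at
q < 0.05.  P values are reported uncorrected with FDR flags separate.
Degenerate inputs are handled explicitly: zero-variance one-sample
connections are reported as such; identical groups give t = 0, p = 1;
all-missing connections are untested.  Paired t-tests compare the three
per-subject connection-group means (the right group entering as −LI) within
each diagnostic group.  Severity is ADOS social + communication; severity
correlations are Pearson (within the autism group, and optionally everyone
with ADOS scores), age and quantitative-handedness correlations are
Spearman, all pairwise-complete with n < 3 untested.

**Inclusion presets.**  All presets keep only subjects from sites with at
least `min_site_n` processable subjects (20 at full scale; desk-scale demos
use 10, and unit fixtures 1–2, since a 60-subject cohort cannot contain a
20-subject site by accident).  A = base; B = post-scrub retention ≥ 50%;
C = exclusion of a caller-supplied list of possible-overlap sites; D = B∧C;
E = right-handed only (after recoding: when categorical handedness is
missing, positive quantitative values become R, negative L, zero
ambidextrous; subjects missing both are retained except under E);
F = males only; G = strict autism diagnosis (Asperger/PDD-NOS excluded);
H = verbal IQ 80–130 (autism) / 70–120 (controls).  Added restrictions are
monotone by construction.

## Calibration checks and their expected outcomes

The acceptance suite runs the full pipeline, not shortcuts: 200
symmetric-null cohorts (n = 30/30, 8×8×4 grid, 120 volumes) give a pooled
per-connection two-sample rejection rate statistically indistinguishable
from the nominal 0.05 (exact binomial 99% interval); a planted z = −0.15
deficit on the Wernicke–posterior-cingulate connection (n = 60/60) is
recovered with essentially no false positives.  One quantitative note: at
120 volumes inside a 0.001–0.1 Hz band the effective temporal degrees of
freedom give a per-subject LI standard deviation of ≈ 0.23, and the
noncentral-t power of a −0.15 effect at n = 60/60 through a 91-test BH
family is then ≈ 0.55 — the suite verifies that the Monte-Carlo detection
rate matches this theoretical power, which is the property under the
package's control; pushing detection above 0.8 would require materially
longer runs (LI sd ≲ 0.19), not a different implementation.

## Numerical conventions

Template mm coordinates place the origin at the grid centre (negative x =
left hemisphere); voxel indices are 0-based; the z range is closed at both
ends.  Correlations are clipped at 1 − 10⁻¹² before atanh.  Zero-variance
ROIs propagate as missing LI, counted per subject in QC.  FD[0] and
DVARS[0] are defined as 0 (they are transition quantities).  All Monte-Carlo
suites fix their seeds in the test code; the acceptance script derives every
stream from its `--seed` via spawned `SeedSequence`s.
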