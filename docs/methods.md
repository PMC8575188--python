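# Methods

## Scope and model

`acinostereo` implements the quantitative core of acinar morphometry on 3D
image stacks: extraction of individual acini by stopper-bounded region
growing, design-based estimation of acinar volume (Cavalieri) and alveolar
number (physical disector), and the derived developmental metrics and
nonparametric group comparisons reported for postnatal days 4, 10, 21 and
60. Tomographic acquisition and reconstruction, interactive stopper
placement, and 3D surface rendering are out of scope; stoppers and seed
points are supplied as data (JSON/YAML), and stacks are read as multi-page
TIFF or single-frame DICOM series with mandatory voxel-size metadata.

All volumes are indexed `(z, y, x)`, 0-based, with isotropic voxel edge
length in µm (default 1.48 µm, matching the high-resolution tomography the
pipeline emulates). Slice designs are half-open `[offset, depth)`.

## Phantom generator

The synthetic-data module is first-class, tested code: it is what makes
every estimator verifiable without raw scan data.

A phantom is built from a binary-branching duct centreline tree (depth
`d` gives `2^d` tips; segment lengths and radii decay geometrically at
0.8/0.85 per generation, branch angle 35°, random azimuths). The tree is
rasterized as a union of capsules; alveoli are spheres whose centres sit
just outside the duct wall so that each sphere dips `0.5·min(r_alv,
r_duct)` into the lumen, carving a single circular mouth — the only wall
interruption of that alveolus. This mirrors the counting assumption of
entrance-ring disector counting (interruptions occur only at mouths).
Placement is rejection-sampled: a candidate is discarded if it would touch
another alveolus under 6-connectivity or leave the stack margin; after
`100·n` failed attempts a placement error reports how many alveoli were
placed (partial failure is never silent, because the manifest must be
exact). The margin keeps all air off the stack faces, so every alveolus
both appears and disappears inside the stack.

Ground truth is exact by construction and re-verified on every phantom:
manifest volume equals (nonzero-label voxel count) × voxel volume to
machine precision, manifest count equals the number of labels ≥ 2, and the
air region is one 6-connected component.

Cohorts: day-level acinar volume distributions are modelled log-normal,
moment-matched to the day's (mean, CV). The distribution family is a
modelling choice — only means, SDs and the direction of skew are published
— but the log-normal has positive support and reproduces the strong early
right skew and the near-symmetry at day 60 (CV 0.49). Day profiles
default to mean volumes 0.03/0.04/0.10/0.74 mm³ and CVs
1.26/1.25/0.90/0.49 for days 4/10/21/60. Each cohort phantom is rendered
at desk scale (depth-2 tree, ~8 alveoli, ≲10⁶ voxels) and its voxel size
is then set so the realized air volume equals the drawn target exactly;
the estimators under test are scale-free, so reduced-scale phantoms
exercise them exactly as full-scale acini would. Consequences worth
knowing: within a cohort the *geometry* varies only through the tree/
placement seed and the Poisson-jittered alveolus count (clipped to the
packing capacity of the small tree), while the volume spread is carried by
the grid scale; and rendered alveolar numbers (~8) are far below real
day-60 counts (~700), so cohort phantoms validate estimator behaviour, not
anatomical workload. Sample CVs of heavy-tailed log-normals are biased low
at moderate n — at the day-4 profile (CV 1.26) sample CVs at n = 200 can
sit 25% low — so distributional-recovery checks use the day-60 profile.

Grayscale rendering maps air (any nonzero label) to a dark level and
everything else to a bright tissue level (two-level image), plus optional
additive Gaussian noise; tomographic artifacts (rings, phase fringes) are
not simulated. Passing tests therefore demonstrate correctness of the
estimators and the pipeline plumbing on ideal contrast, not robustness to
scanner-specific artifacts or operator variability in threshold choice.

## Segmentation

Region growing selects the 6-connected component of
`{gray ≤ threshold} \ stoppers` containing the seed. 6-connectivity is
deliberate: diagonal adjacency would leak through one-voxel septal gaps.
Stoppers are solid oriented cylinders (radius in µm, thickness ≥ 2 voxels,
default 3), airtight under 6-connectivity by construction. The default
threshold is Otsu's, shifted to the midpoint of the gap between the two
classes it separates (so a two-level image thresholds strictly between the
levels); a per-acinus override is accepted because automatic thresholds
are known to bias volumes when gray values drift. A mask touching the
stack boundary is logged as a possible stopper leak but is not an error —
an undersized stopper is not detectable locally. Seeds are supplied
explicitly; a helper places one a stopper-thickness distal along the
stopper normal.

## Stereology

- `surs_slices`: systematic slice set with offset uniform on
  `{0,…,interval−1}`. Over all offsets the sets partition `[0, depth)`,
  which is what makes the Cavalieri estimator design-unbiased.
- `count_points`: square grid at `origin + k·spacing` (µm), a node counts
  if its nearest voxel is in the mask. With integer spacing and integer
  voxel origins, the exhaustive offset/origin average of
  `t·a_p·ΣP` equals voxel volume exactly (each voxel is counted by exactly
  one design); the test suite asserts < 0.5% and observes ~1e-14.
- Coefficient of error: Gundersen–Jensen smoothness class 0,
  `Var = (3A − 4B + C)/12` with `A = ΣPᵢ²`, `B = ΣPᵢPᵢ₊₁`, `C = ΣPᵢPᵢ₊₂`,
  `CE = √Var/ΣP`, reported when ≥ 3 sections were counted. This is
  auxiliary output (no CE is published for the study being emulated).
- Disector: bidirectional — both appearances and disappearances between
  consecutive sections are counted and the sum halved. On label volumes
  with exhaustive pairs this is exact for any phantom (each z-contiguous
  particle strictly inside the stack appears once and disappears once).
  Fractional pair designs scale by `pairs_total/pairs_examined` and are
  unbiased in expectation. Whether the original counting protocol was uni-
  or bidirectional is not published; bidirectional-exhaustive is the
  default and the sampling is exposed in the API.
- The grayscale wall-interruption detector (skeleton free-tip pairing) is
  explicitly best-effort and not on any quantitative path; counting runs
  on label volumes where identity is exact.
- Shrinkage: a single multiplicative factor per animal,
  `fresh displacement volume / processed Cavalieri volume`, applied to all
  of that animal's volume estimates. The published description names the
  two volumes but not the formula; the plain ratio is the simplest
  estimator consistent with a global linear correction. Phantom pipelines
  use factor 1.0 (no processing shrinkage to undo).
- Acinus subsampling: every k-th acinus (default k = 3) from a uniformly
  random start — the "one third of all extracted acini" protocol.

## Derived metrics

Day-level means are acinus-weighted (`Σnᵢmᵢ/Σnᵢ`), identical to pooled
per-acinus means. Pooled day variance is reconstructed from per-animal
`(n, mean, sd)` rows as `[Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²]/(Σnᵢ−1)`; CVs
recomputed this way from display-rounded table rows land at 1.28/0.50
against the published 1.26/0.49 — a rounding artifact, bounded at 0.03 in
the tests, not a hard equality.

Quintile ratio: tails of size `round(0.2·N)` (nearest integer). This
reproduces all four published tail sizes (25/12/8/9 for N = 125/58/42/43),
which `floor` would not.

Lung-level metrics: acini per lung = parenchymal volume (external scalar
from whole-lung stereology) / mean acinar volume; total alveoli = acini ×
mean alveolar number; individual alveolar volume = `f · V̄_acinus / N̄`
with the ductal fraction `f` the share of acinar volume in alveoli proper.
The per-day fractions (0.80/0.74/0.72/0.77) are not published directly;
they are back-solved from the published per-day alveolar-volume quotients
and shipped as configuration flagged as reverse-engineered. Diameters
assume spherical alveoli, `d = (6V/π)^(1/3)`.

Cross-study scale factors support both conventions: `ratio_of_sums`
(Σref/Σown — one global factor, used for per-lung alveolar totals, 5.04)
and `mean_of_ratios` (per-day factors averaged, used for alveolar volumes,
1.81).

## Group statistics

Two-sided Mann–Whitney U per day pair: exact null enumeration when both
groups have n ≤ 8 and no ties, otherwise the normal approximation with tie
and continuity correction (the switch point is a package choice; the
original software's variant is not published). The Šidák per-comparison
threshold `1 − (1 − α)^(1/m)` uses α = 0.01 and m = 6, back-solved from
the published 0.00167 (neither α nor m is stated explicitly). Shapiro–Wilk
is advisory only and never gates the rank tests. Kruskal–Wallis (tie
corrected) is the omnibus check. Acini are pooled across animals within a
day, as in the protocol being reproduced; this is pseudo-replication and
is documented rather than corrected. Empirical size of the pairwise test
at α = 0.05 is verified to lie in [0.03, 0.07] over 2000 null pairs of
n = 20.

## Problem sizes and numerics

Tests and the acceptance script run phantoms at ≤ ~10⁶ voxels (depth-2
trees, 6–12 alveoli, 1.48 µm voxels), 20+ phantom seeds for disector
exactness, a 216-design exhaustive Cavalieri grid on a 52-voxel-diameter
ball, 2000 null simulations for rank-test calibration, and a 4-day × 12
phantom end-to-end pipeline — the full suite completes in about a minute.
Degenerate inputs fail loudly: zero-size dimensions, missing voxel size,
constant images, empty slice designs, seeds in tissue or inside stoppers,
non-positive volumes. Ties in display rounding are Python's banker's
rounding; all internal math is double precision.

## Known limitations

- Phantoms are geometrically idealized (spherical alveoli, capsule ducts,
  uniform septa); they validate estimators, not biological realism, and
  include no imaging artifacts.
- The interruption detector on grayscale sections is a heuristic and is
  excluded from quantitative claims.
- Ductal fractions and the log-normal size law are reverse-engineered /
  modelling choices, clearly flagged in configuration and here.
- Undersized stoppers leak silently except for the boundary-contact
  warning; stopper calibers are the operator's responsibility.
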