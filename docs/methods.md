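# Methods

## The movement measure

All motion quantities derive from per-volume rigid poses (three
translations in mm, three rotations in radians, relative to the first
volume) of the kind FSL `eddy` writes to its `*_parameters` file. The
scalar movement measure between two poses is the RMS over intracerebral
voxels of the displacement each voxel undergoes between them. With
rotation R and translation t acting as T(x) = R·x + t about the mask
coordinate origin, the mask average collapses exactly:

    RMS(a,b)² = tr(MᵀM·S) + 2 dᵀM x̄ + |d|² ,
    M = R_b − R_a,  d = t_b − t_a,
    S = mean(x xᵀ),  x̄ = mean(x) over mask voxels.

No small-angle approximation is made; the identity is algebraic, so the
implementation is O(1) per pose pair once the mask moments are cached.
A pure translation gives RMS = |t| independent of the mask; a pure
rotation of a single voxel at radius r gives the chord length
2r·sin(θ/2). The unit tests verify the closed form against a literal
per-voxel loop to 1e-10.

Conventions the package fixes (the upstream estimator's internal
conventions are not published alongside its text outputs, so the
package defines one self-consistent set used by both the simulator and
the oracle): rotations compose as Rx·Ry·Rz; the rotation center is the
mask coordinate origin, and masks are constructed centered on it; the
default mask is a solid sphere of radius 80 mm (adult head scale)
sampled on a 4 mm grid. These choices affect absolute rotation-driven
displacements slightly but cancel from every within-package comparison.

## Descriptors

- **mean / median relative movement per volume** (mm/vol): mean/median
  of the volume-to-volume RMS series, *excluding volume 0* — it has no
  predecessor, and counting its structural zero would deflate every
  rate by 1/N.
- **per minute** (mm/min): per-volume value × 60/TR, using nominal scan
  time n_volumes × TR. Dead time between volumes is not modeled.
- **per-axis rates**: mean absolute volume-to-volume difference of each
  translation (mm/vol) and rotation (deg/vol; stored in radians,
  converted only at reporting). Axis order is (L/R, P/A, I/S) with the
  default mapping x→LR, y→PA, z→IS, overridable because scanner axes
  follow image orientation.
- **cumulative displacement**: running sum of the relative RMS series,
  resampled by linear interpolation onto a 0.1-minute grid; the cohort
  average curve is a LOESS smooth (local linear, tricube weights,
  span 0.3 by default) of the pooled points.

## Statistics

Rank tests use exact null distributions whenever the data are tie-free.
For the signed-rank test the exact CDF of W⁺ is built once per sample
size by dynamic programming and cached, so exactness costs a table
lookup even at n = 120 pairs; this matters because the normal tail
approximation is conservative at the far tail, which would visibly
depress the family-wise null behavior of the FDR step across a
200-test grid. With ties, the normal approximation with tie and
continuity corrections is used. Zero differences are dropped before
ranking (the classical Wilcoxon treatment, not Pratt's). The rank-sum
test uses exact enumeration when min(n) ≤ 12 without ties, otherwise
the tie/continuity-corrected normal approximation.

Benjamini–Hochberg correction is applied per feature domain (the
4×50 microstructural grid, the 7×50 macrostructural grid, and the
5-metric connectome set are each corrected separately), reproducing
the design's per-domain test counts of 200 and 350. Percent change is
computed per subject as 100·(more−less)/less and then averaged
(subjects with a zero baseline are excluded from that mean only, with
a logged count); a group-level-ratio variant is available behind a
flag. Features whose paired differences are all zero are reported with
p = 1 rather than an error: a degenerate feature carries no evidence
of bias.

The mover/non-mover comparison uses OLS with intercept + group + age +
sex (sex as a binary indicator; listwise deletion of missing
covariates with a logged count), the group coefficient being the
effect of interest. Three-group diagnosis comparisons run as pairwise
rank-sum tests pooled into one BH correction across comparisons and
cohorts.

The lifespan age–motion fit offers two forms: a least-squares
quadratic (the default) and a gamma-type curve y = a + b·t·exp(−c·t)
fit by nonlinear least squares (initialized at a₀ = min y, c₀ =
0.1/yr, b₀ from the youngest observation). Both are exposed because
lifespan-curve conventions differ across the developmental literature;
nothing downstream depends on the choice.

## Graph metrics

Connectomes are symmetric non-negative matrices with zero diagonal
(default 84 nodes). Distances use edge length 1/weight (the common
connectomics convention) with Dijkstra; characteristic path length
averages finite pairwise distances only, while disconnected pairs
contribute 0 to global efficiency — both documented conventions of the
prevailing toolboxes. Clustering is the Onnela weighted form (weights
normalized by the network maximum; binary variant exposed).
Assortativity is the Pearson correlation of endpoint strengths over
edges (both orientations); graphs with zero strength variance (e.g.
regular graphs) return NaN — undefined, not zero. An edgeless graph
likewise returns density 0 with NaN path length rather than raising,
keeping the five-metric record shape stable.

## The synthetic generators

The generators define the study conditions; they emulate the
statistical structure the analyses assume, not the imaging physics.

**Motion traces** are cumulative Gaussian random walks (drift) plus
sparse persistent jumps — pose changes that stay, modeling a head
repositioning — with per-axis anisotropy defaulting to 2× AP
translation and 2× LR-axis rotation, the directions least constrained
by head padding. Defaults (40 volumes, TR 4 s, drift 0.030 mm /
0.00045 rad per volume per axis before anisotropy, jump probability
0.03/volume with 0.35 mm / 0.0045 rad jump scales) were calibrated
once so the default adult scan lands near 0.1 mm/vol ≈ 1.5 mm/min —
mid-range for adult cohorts. The jump component makes within-scan
movement right-skewed, so cohort mean exceeds median.

**Cohorts** draw ages uniformly over the configured range and set each
subject's motion level as lifespan-curve(age) × diagnosis offset ×
lognormal frailty (σ = 0.3), with rare outliers (rate 2%, growing with
age, 4× motion). The lifespan curve is piecewise — exponential
childhood decay (amplitude 2.0, time-scale 5 yr) to an adult floor
plus a linear 1%/yr increase past age 60 — chosen to be qualitatively
U-shaped; no quantitative fit to any real cohort is claimed. Diagnosis
offsets default to CN 1.0 < CI 1.15 < AD 1.35 (LD 1.5). Scan–rescan
sessions share the subject level but draw independent traces and an
independent lognormal per-scan jitter (σ = 0.2), which produces the
within-subject motion gaps the selection stage ranks.

**Features** use a shared per-subject latent value (between-subject
sd) plus independent within-scan noise (within-subject sd, set near
1–2% of each measure's mean — typical same-session tractometry
repeatability); an injectable multiplicative bias on the more-motion
scan is the positive control. The 50-bundle list is 25 bilateral
pathway names in TractSeg nomenclature × left/right; the identity of
the bundles is a fixture choice. Connectome features are the five
global metrics of per-scan lognormally jittered copies of a
per-subject random 84-node weighted graph (edge density 0.3).

All generators are pure functions of (config, seed); substreams are
derived by hashing the operation name with the seed so adding a
generator never perturbs existing fixtures.

**What passing tests do and do not show.** The generators produce
independent Gaussian/lognormal features, uniform ages, and exactly two
scans per session. Real data have spatially correlated features,
site/protocol heterogeneity, non-uniform age distributions, and
missing sessions; the pipeline's error control is verified under the
synthetic independence assumptions and the qualitative reproductions
(skew, child > adult, AP/LR dominance) are properties built into the
generator defaults, not discoveries about real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the
package's own choice of problem size: cohorts of 120–300 scans at
30–40 volumes, 120 scan–rescan pairs (matching the design's selection
size), 2,000 replicates for the family-wise null check, and 60
replicates for the power/recovery check. Symmetry of connectome
matrices is enforced to 1e-12; rotation blocks are orthonormal to
1e-12; TSV round trips write floats as %.17g and read with round-trip
parsing, so file cycles are bit-exact. Selection ties break toward the
lexicographically smaller subject id, and the less/more tie within a
session toward scan 1 — both arbitrary but deterministic.

## Known limitations

- Motion is estimated upstream; nothing here re-estimates poses from
  images, and `eddy`'s other QC outputs (outlier maps, CNR) are not
  parsed.
- The per-minute normalization assumes nominal acquisition time.
- The exact signed-rank path assumes tie-free differences; heavily
  discretized features fall back to the corrected normal
  approximation.
- Edge-wise/nodal connectome statistics and along-tract profiles are
  out of scope; only global network measures are computed.
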