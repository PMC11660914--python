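# Methods

`glioloc` implements a lesion-location analysis for glioblastoma (GBM)
cohorts: given binary tumour masks normalized to a common template
grid, it asks where tumours sit with respect to labelled brain atlases
and whether that topology relates to MGMT promoter methylation,
treated both as a dichotomous status and as a continuous
pyrosequencing percentage. This note documents the models, the
numerical choices, and what the synthetic data generator does and does
not emulate.

## Data model

A subject contributes two binary masks on one `ImageGrid` (dims plus a
4x4 voxel-to-world affine): the tumour **core** (enhancing and
non-enhancing tumour plus necrosis) and the peritumoural **oedema**;
their voxel-wise union is the **global** lesion. Volumes are always
`voxel count x |det(affine_3x3)| / 1000` millilitres. Atlases are
integer label volumes with a TSV table assigning each label a region
name and a tissue class (`lobe`, `cortex`, `white_matter`,
`deep_grey`, `gm_network`, `wm_network`).

Grids are sacred: every downstream statistic counts voxels, and
nearest-neighbour resampling silently changes counts, so the pipeline
*refuses* grid mismatches (affine tolerance 1e-4 mm) instead of
resampling. `resample_nearest` exists for the user who explicitly
wants it.

## Overlap quantification

* **Lobar involvement** — a lobe is involved when the core overlaps at
  least 250 of its voxels. The threshold is inclusive (>= 250) and
  configurable.
* **Tissue compartments** — for cortex, white matter and deep grey
  nuclei the profile reports overlap voxels, mL, and the fraction of
  the lesion inside the class. Fractions need not sum to one: lesion
  voxels may fall outside all three classes. An empty lesion yields
  NaN fractions, never zero.
* **Network ratios** — for a functional-network atlas (grey- or
  white-matter), ratio(n) = lesion voxels in network n over lesion
  voxels in the union of all networks of that atlas. Background is
  excluded from the denominator, so defined ratios sum to 1 (checked
  to 1e-9). A lesion missing every network produces all-NaN ratios;
  such subjects are dropped listwise from network-level tests with a
  logged count.
* **Frequency maps** — voxel-wise counts of overlapping subjects per
  group; the display map zeroes voxels covered by fewer than 2
  subjects (configurable), the raw map is kept.

Overlap is computed on core masks by default, with oedema/global
available by flag.

## Cohort statistics

* Dichotomization: methylated iff percentage >= 8 (inclusive).
* Median split of the continuous percentage: values equal to the
  median go to the *low* group — a deterministic tie rule, logged.
* 2x2 contingency tests use the **uncorrected** Pearson chi-square.
  The continuity-corrected statistic is incompatible with the
  contingency structure this analysis targets (42/51 group sizes with
  ~64%/43% right-sided proportions give ~4.1 uncorrected vs ~3.3
  corrected), and the uncorrected form is the package default.
* Two-sample comparisons use the pooled-variance Student t; Welch is
  available by flag.
* Partial correlation is the first-order formula
  `r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))` with a
  t transform on n-3 df; it equals residual correlation to 1e-10 and
  is cross-checked against an independent implementation in the tests.
* The network repeated-measures ANOVA is the **multivariate**
  approach: the n x k profile matrix is reduced by k-1 orthonormal
  difference contrasts; Wilks' lambda = det(E)/det(E+H) is converted
  to an exact F (single-df hypotheses: (k-1, n-k+1) df for the
  flatness/condition effect, (k-1, n-k) for the condition x covariate
  interaction when a between-subject covariate such as methylation
  status is supplied). At k=2 the condition F reduces exactly to the
  paired-t squared. The "combined contribution" of the covariate is
  interpreted as this interaction test — the profile's dependence on
  the covariate — which is one reading of an under-specified model;
  it is flagged as an interpretation.
* Bonferroni correction: corrected p = min(1, p x m), adjusted alpha
  0.05/m. Family sizes are defined per analysis block in the pipeline
  configuration (e.g. m=6 for the pairwise comparisons among the four
  status x side categories, giving the 0.008 threshold) and recorded
  in the run log.

## Voxel-wise mapping

Voxels lesioned in at least `min_overlap` subjects (default 2) form
the analysis mask. Each voxel's binary lesion indicator is regressed
on [intercept, predictor, nuisance...]; the predictor's t statistic
(df = n - p) forms the map. With a binary predictor and no nuisance
this is exactly the two-sample t; with a continuous predictor, the
Pearson-r t transform; with nuisance, the partial-correlation t.

Family-wise error is controlled by the permutation max-statistic
method, default two-tailed on |t|:

    p_fwe(v) = (1 + #{perm max |t| >= |t_obs(v)|}) / (n_perm + 1)

so p_fwe >= 1/(n_perm+1) always. Without nuisance the predictor
labels are permuted; with nuisance the Freedman–Lane scheme permutes
reduced-model residuals (plain permutation by flag). When the
permutation space is no larger than `n_perm` (binary predictor:
C(n, n1) relabelings; otherwise n! orders) it is enumerated
exhaustively and the p-values are exact. Uncorrected p-values come
from the same permutations voxel-by-voxel. Everything is reproducible
bit-for-bit given the seed. A voxel with zero residual variance gets
t = 0 when the effect is zero and +/-inf when the indicator is
perfectly explained; infinities propagate through the max statistic
consistently. No TFCE or cluster inference is offered: the method is
plain voxel-level max-|t|.

The standard suite runs (a) methylated vs unmethylated, (b) continuous
percentage over the quantified methylated subset, (c) high vs low by
median split — each with and without core volume as nuisance, and each
repeated after flipping all lesions to one hemisphere. Which
hemisphere the original analysis unified on (or whether it
mirror-augmented) is not documented anywhere we could rely on, so
`mirror`, `unify_left` and `unify_right` are all provided;
`unify_left` is the default and none is claimed canonical. The flip
axis is the voxel axis most aligned with world x; a lesion centre of
mass exactly on the mid-sagittal plane counts as already unified
(logged). Volume correction enters as a GLM covariate — the natural
reading of "corrected for core volume" in a GLM framework.

## Synthetic cohort generator

The generator exists so that every stage is exercisable end-to-end
without patient data. Defaults encode the emulated study conditions:
93 subjects, 42 methylated, 41 with a quantified percentage (one
methylated subject deliberately lacks it, and correlation analyses use
the n=41 subset), methylation mean 33.9, SD 18.3, floor 8; core
volume 43.2 +/- 29.3 mL and oedema 54.8 +/- 43.4 mL (truncated
normals at > 0.5 mL — truncation raises the realized core mean by
roughly 4 mL, which is accepted rather than re-centred); 66 males;
age 62.3 +/- 11.3.

Geometry: an ellipsoidal, exactly mirror-symmetric brain on an
isotropic grid with a fixed 128 mm field of view (64^3 gives 2 mm
voxels; smaller grids coarsen the voxels so lesion volumes in mL stay
meaningful). Cortex is a 2-voxel outer ribbon, deep grey two blobs
paired across the midline, the rest white matter. Lobes are five
angular sectors; the grey-matter network atlas has 5 cortical sectors
plus 2 deep parcels (mirroring, at small scale, a cortical
parcellation extended with deep-grey parcels); the white-matter atlas
has 4 parcels. All parcels are functions of |x| and the (y, z) angle
only, hence invariant under mirroring.

Lesions grow by stochastic 6-connected region growing from a seed
voxel: a persistent frontier pool accepts random subsets (keep
probability 0.65) until the target voxel count is hit exactly (the
final shell is subsampled), guaranteeing a single 6-connected
component; oedema continues the same growth outward from the core,
disjoint by construction. Growth trapped below 90% of target retries
from a new seed voxel (6 attempts). Seed voxels are cortex-adjacent
with per-subject probability drawn from Beta(1.4, 0.9) and
deep-adjacent otherwise, giving the cohort a spread of cortical
involvement without a planted group difference in location — matching
the negative categorical findings the analysis should reproduce.

The planted effect: for the quantified methylated subset, methylation
percentage = mean + sd * (r z_c + sqrt(1-r^2) eps), where z_c is the
standardized *realized* cortical overlap fraction, eps is iid standard
normal, and r = +0.36 — i.e. noise calibrated by the closed form
sd_noise = sd_signal sqrt(1/r^2 - 1) so the population correlation
equals the target. Values are then clipped to [8, 100]; attenuation
from clipping is measured and logged, not corrected (it is small,
~0.01). The deep-grey anticorrelation is **not** planted: it emerges
from the compositional cortex/deep trade-off of lesion placement.
Note the structural ceiling: if methylation depends on deep
involvement only through cortical involvement, |r(meth, deep)| <=
|r(meth, cortex)|, so the emergent value (about -0.30 on average
across seeds, vs the -0.35 target) cannot exceed 0.36 in magnitude;
it is reported per run rather than enforced. The null-cohort variant
generates the identical lesion set and then permutes the molecular
columns across subjects, severing any location link by construction —
the calibration input for the permutation-FWE validity check.

What the generator does **not** emulate: MRI intensities, realistic
cortical folding, lesion mass effect, infiltrative growth along white
matter tracts, scanner/segmentation noise, or any survival process.
Passing tests therefore demonstrate the correctness and calibration of
the *statistical machinery* under the stated generative conditions,
not the biological claims themselves.

## Problem sizes and reproducibility

Parameter-recovery checks use 100 cohorts at the default 64^3 grid;
permutation-calibration checks use 200 null cohorts on a 32^3 grid
with 200 permutations each — sizes chosen so a complete verification
run finishes in minutes on a single CPU while keeping the binomial
confidence bands informative. The pipeline fans a single global seed
out to per-stage seeds by CRC-hashing stage names, so any stage can be
re-run in isolation; with a fixed seed every output (TSV and NIfTI) is
byte-identical across runs.

## Known limitations

* The repeated-measures covariate model is one interpretation of an
  under-specified original; the interaction test is clearly named.
* The emergent deep-grey correlation is bounded by the planted
  cortical one (see above).
* Truncated-normal volume sampling shifts realized means slightly
  above nominal.
* The synthetic brain's compartment proportions (cortex ribbon, small
  deep nuclei) are stylized; absolute overlap fractions are not meant
  to match human anatomy, only to exercise the estimators.
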