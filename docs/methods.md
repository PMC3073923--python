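# Methods

This note documents the models, estimators and design choices behind the
`csma` package: what the synthetic-data generator emulates, how the
measurement and scoring stages work, which defaults matter, and what the
validation experiments do and do not demonstrate.

## Array model

A CSMA plate is a rectangular lattice of printed spots. The reference
geometry is 108 rows × 36 columns at 500 µm pitch with 200 µm spots (3,888
spots in 18 × 54 mm; four wells give 15,552). Coordinates place the origin
at the top-left spot center, +x along columns, +y along rows; grid indices
are 0-based and raster→physical conversion uses pixel centers.

Printing pins deposit contiguous column blocks (column *c* → pin
`(c·n_pins)//n_cols`, 16 pins by default). This makes pin bias spatially
structured — the hardest case for normalization and therefore the right
test bed. Sample randomization is a seeded uniform shuffle; negative
controls (count = ⌈0.05 × n_targets⌉, i.e. at least the stated 5%) are
placed at random positions but balanced round-robin across pins, because
control-anchored pin normalization needs at least one control per pin.
Replicate arrays share one randomization, matching the "identical arrays"
production route; independent randomization is available by assigning with
different seeds.

## Synthetic cell populations

`simgen` draws, per spot:

- **cell count** ~ round(Normal(mean, sd)) truncated at 0 — defaults
  51 ± 3 for 200 µm spots (151 ± 8 and 21 ± 6 are the 400 µm and stromal
  reference settings). The rounded Normal is used because the reference
  statistics are reported as mean ± s.d. rather than as a count family.
- **positions** uniform in the spot disk; for image rendering, dart-throwing
  rejection enforces non-overlapping nuclei (a packing error is raised if
  the disk cannot host the requested density). Table-mode simulations skip
  the rejection step since positions do not enter table-level scoring.
- **cell-cycle phase** ∈ {G1/S, G2, M} with default probabilities
  (0.65, 0.28, 0.07) — the G2 fraction matches the reference control
  population (~28%), the mitotic index is set to a typical few-percent
  value for cycling cultures.
- **DNA content**: integrated nuclear DAPI ∝ content (2N in G1/S, 4N in
  G2/M) with multiplicative lognormal cell-to-cell variation (CV 15%).
  Nuclear radius is 5 µm in G1/S, grows ×1.1 in G2 and condenses ×0.7 in M,
  so mitotic figures have conserved integrated but strongly elevated mean
  DAPI — the physical basis of the M gate.
- **Ki-67** nuclear mean rises monotonically (1 : 1.6 : 2.2 across
  G1/S : G2 : M); the stated biology fixes the order, not the values, and
  these defaults give a clearly graded but overlapping distribution.
  Apoptotic cells drop to a Ki-67-negative floor (0.3× the G1/S level).
- **cPARP**: baseline in viable cells; apoptotic cells (default spontaneous
  fraction 5%, a typical culture value) draw a progression u ~ U(0,1) and
  carry (2 + 8u)× baseline, emulating the rise from apoptosis induction to
  apoptotic-body formation. Ki-67 and cPARP elevation are therefore
  mutually exclusive by construction.
- **TuGFP** cytoplasmic mean, scaled by (1 − knockdown) in transfected
  cells (default transfection fraction 0.9).
- **pin bias**: one multiplicative factor per (array, pin, channel),
  log-uniform in [0.8, 1.25].

All intensities are arbitrary fluorescence units; every draw is reproducible
from (parameters, seed). Rendering paints nuclei as lightly blurred disks
(DAPI pixel value = integrated/area so integration is conserved), a
cytoplasmic annulus (default 10 µm) carrying TuGFP, uniform background plus
additive Gaussian noise (sd 20 on a ~100 background at 0.65 µm pixels),
clipped at zero.

What the generator does **not** emulate: optics (PSF, shading, vignetting),
non-circular cell shapes, debris and sub-G1 particles, cell migration or
detachment dynamics, and staining batch effects beyond the per-pin factors.
Passing the validation experiments therefore demonstrates correctness of
the analysis logic under the assay's statistical structure, not robustness
to every artifact of real microscopy.

## Measurement

Nuclei are segmented from DAPI by median background subtraction, light
Gaussian smoothing (σ = 1 px), a global Otsu threshold guarded by a robust
noise floor (threshold must exceed 4× the MAD-based noise scale, so empty
fields yield empty masks), connected components, and a distance-transform
watershed to split touching nuclei; fragments below `min_area_px` (default
25 at 0.65 µm pixels) are removed. The recipe is deliberately the simplest
pipeline that passes the render-and-resegment round trip (≥95% count recall
and precision) and sits behind a single function so it can be swapped.

Per cell we record area, centroid, per-channel nuclear mean and integrated
(= area × mean) intensity, and the mean of a cytoplasmic ring of fixed
pixel width (default 15 px). Rings are built by nearest-label expansion, so
a ring never contains nuclear pixels — its own or a neighbor's — and
neighboring rings partition the shared territory. Per-channel background
(median outside all rings) is subtracted by default. Cells are assigned to
the nearest spot center and excluded beyond radius + margin; the default
margin of one mean nuclear radius admits cells whose centroid sits
marginally outside the printed disk. Exact ties go to the lowest spot id.

## Cytometry

**Cell cycle.** Integrated DAPI = nuclear area × mean DAPI. With automatic
gating (≥50 cells) the G1 peak is the mode of a Freedman–Diaconis
histogram; the 2N window is [0.75, 1.5)× and the 4N window [1.5, 2.5]× the
mode. M is separated from G2 within the 4N window by chromatin
condensation: mean DAPI above twice the 0.95 quantile of mean DAPI in the
2N window. The reference population is the 2N window (which contains no
mitoses) rather than the whole population because a whole-population
quantile at level q caps the recoverable M fraction at 1 − q regardless of
the true mitotic index; anchoring on the 2N cells and doubling to the 4N
scale (a 4N nucleus at unchanged geometry has exactly twice the mean) makes
the gate sensitive to condensation only. All gates scale with the data, so
classification is exactly invariant to global intensity rescaling.

**Phenotypes.** Thresholds come from negative-control cells: cPARP at
their 0.99 quantile (a 1% false-positive bound by construction), Ki-67 at
their median. Cells above both thresholds go to the channel with the larger
fold-over-threshold, honoring the markers' mutually exclusive biology.

**Knockdown efficacy.** Per cell, signal (nuclear mean or ring mean) is
normalized by nuclear DAPI mean; efficacy = 100 × (1 − median_t/median_c).
Medians are used because the lognormal intensity tail makes means fragile;
the estimator is invariant to global multiplicative scaling. Uncertainty is
a seeded percentile bootstrap (default 1,000 resamples) and a two-sided
Wilcoxon rank-sum p-value is reported alongside. A spot-level variant
(cumulative spot signal over cumulative DAPI, bootstrapped over spots) is
provided with the same contract. Recovery experiments plant the silencing
with transfection fraction 1.0: with partial transfection the
population-level "planted level" is ill-defined, since the median estimator
deliberately reads the transfected mode.

## Screen scoring

Spot aggregation sums nuclear integrated intensities over included cells;
spots with fewer than 10 cells are flagged unscoreable rather than silently
dropped. Pin normalization divides each channel by (pin-control median /
array-control median) — controls only, so true biological hits concentrated
on a pin are not normalized away. The spot index is the log2 Ki-67/cPARP
ratio (DAPI normalization cancels in the ratio but zero-DAPI spots are
flagged); the log scale symmetrizes inhibition and promotion before
z-scoring. The pseudo-count default is 1% of the array-median cumulative
cPARP. z-scores use the global array mean and population s.d. over defined
samples; replicates are combined by the mean z (the alternative —
combine raw indices, then standardize once — is available via the scoring
functions but per-array z then mean is the default). Hits are |z| ≥ 2:
inhibitory below, promoting above.

**Rank product.** Within each condition samples get average ranks
(ascending for the "down"/inhibitory run, descending for "up"; the two
directions are separate runs). A sample missing from a condition receives
that condition's worst rank + 1 and is flagged. P(RP_null ≤ RP) is computed
by exhaustive enumeration of independent rank tuples when nᵏ ≤ 10⁶ and
otherwise by seeded permutation of ranks within conditions (pooled null,
add-one correction); BH FDR is reported over samples.

**PAM.** Deterministic k-medoids: BUILD chooses greedy cost-minimizing
medoids (ties to the lowest index), SWAP applies the best cost-decreasing
exchange until convergence; SWAP never increases the total cost, and on
problems small enough to enumerate it reaches the exhaustive-search optimum.
Display ordering follows an average-linkage hierarchy over medoid profiles,
then distance to the own medoid.

## Effect planting and calibration

Planting an effect "of −3 s.d." is done in post-standardization units: the
raw log2 index shift Δ is solved from
z = −Δ(1−f)/√(1 + fΔ²(1−f)) (f the hit fraction), because the hits
themselves contaminate the array mean and inflate the s.d. The Ki-67 scale
realizing Δ additionally compensates the apoptotic Ki-67 floor, which does
not scale with proliferation effects. The null index s.d. entering the
calibration is measured on pilot null arrays; since a single array's
realized s.d. fluctuates by ~7% with the pin-bias draw, the default
calibration averages 20 pilot arrays. Planted between-replicate
concordance uses a shared per-sample latent log2 effect with s.d.
σ_m·√(r/(1−r)) given measurement noise σ_m.

## Validation experiments and problem sizes

`csma.experiments` packages the canonical experiments; the acceptance
script and test suite run them at these sizes, chosen to make each check
conclusive at interactive runtimes: knockdown recovery at 25 spots × ~51
cells × 10 runs per level; cell-cycle recovery at 2,000 cells; null
calibration on the full 984-sample array (exact binomial 99% band around
2Φ(−2) = 4.55%); rank-product uniformity on 500 null samples × 3 conditions
with 10⁴ permutations; planted-hit power as the mean recall over 20
independent 2-replicate screens (recall is a probability; a single screen
of 20 hits measures it with ±7 points of binomial noise); segmentation
round trip over 50 rendered spots.

## Known limitations

- The M gate is a condensation proxy; populations whose mitotic nuclei do
  not condense (or 4N-arrested, condensation-positive states) will be
  misread.
- Pin normalization assumes controls behave like nulls on every pin; a pin
  whose controls are systematically damaged biases its whole block.
- With ~3 control spots per pin, the normalization factor is a median of
  few values; its noise is shared within a pin and is the dominant residual
  spatial structure after normalization.
- Rank-product p-values assume exchangeable rankings under the null;
  condition-specific variance differences are absorbed by ranking but
  strong inter-condition correlation is not modeled.
- The efficacy estimator reads the transfected mode; below ~50% transfection
  the cell-median estimate no longer tracks per-cell silencing.
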