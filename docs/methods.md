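# Methods

This note records the models, numerical conventions, and design choices
behind `ephah`, in the order the workflow runs them.

## Synthetic spectra

No public spectral library exists for the courier-package microplastic
setting the package targets, so every stage is exercised on a seeded
generator that emulates its essential structure.

Each class profile is a sum of Gaussian bands at the shared methylene
combination/overtone positions (4250, 4323, 5245, 5338, 5390, 5440, 5700,
5773, 5940, 7010, 7230, 7340, 7378 cm⁻¹) plus one ester band at 5300 cm⁻¹
in the 5160–5500 cm⁻¹ second-overtone region. Widths (σ 15–40 cm⁻¹) and
base amplitudes (0.2–1.0 AU) are drawn once per seed and shared by all
classes, so adjacent peaks overlap the way un-preprocessed NIR spectra do.
A Gaussian line shape is a modelling convenience; nothing downstream
depends on the profile family.

A spectrum of sample *s* in class *c* is

    x_s(ν) = Σ_b a_b (1 + δ_cb + ε_sb) g_b(ν) · (1 + γ_s) + o_s + β_s(ν) + e_s(ν)

| term | meaning | default |
|---|---|---|
| δ_cb | class offset per band, N(0, `class_separation`²) | 0.015 |
| ε_sb | within-class composition jitter per band, N(0, `intra_jitter`²) | 0.01 |
| γ_s  | multiplicative scatter gain, N(0, `scatter_gain_sd`²) | 0.05 |
| o_s  | additive offset, N(0, `scatter_offset_sd`²) | 0.01 AU |
| β_s  | random polynomial baseline, degree ≤ `baseline_poly_degree` | degree 2, coef sd 0.05 AU |
| e_s  | i.i.d. instrument noise, N(0, `noise_sd`²) | 5·10⁻⁴ AU |

The defaults were fixed once, on these grounds:

* `noise_sd` 5·10⁻⁴ AU is the absorbance noise level of a multi-scan
  FT-NIR average; it keeps >99.9 % of per-class variance in a handful of
  principal components, as real packaging spectra show.
* Class overlap comes from the ratio `class_separation`/`intra_jitter`,
  not from instrument noise: individual fragments of one brand genuinely
  differ in additive content, which band-amplitude jitter models. The
  i.i.d.-per-band form makes the 10 class means sit in general position
  in the 14-band space, so every half-against-half bipartition is
  linearly separable in principle — the regime the method addresses. (A
  low-rank "composition factor" variant was tried and rejected: with class
  means confined to ~3 latent dimensions most balanced bipartitions are
  *geometrically* non-separable, which penalizes EPHAH and OAA for
  reasons unrelated to spectroscopy.)
* `class_separation` 0.015 with jitter 0.01 puts 10-class test accuracy
  in the high-80s/low-90s per cent — overlapping but learnable, the
  regime where decomposition strategies actually differ. Setting
  separation to 0 gives chance-level accuracy; raising it to ≳0.1 gives
  a fully separable problem.
* Default class sizes (75, 75, 84, 85, 85, 74, 74, 69, 65, 60) mirror a
  realistic 750-sample, 10-class collection; the default grid is the
  instrument convention (4000 cm⁻¹ start, 3.857 cm⁻¹ spacing, 2074
  points — the top end falls at 11 999.4 cm⁻¹, slightly short of the
  nominal 12 000).

One root seed fans out (via CRC-tagged `SeedSequence` substreams) to
profiles, spectra, and outlier injection, so stages regenerate
independently and every output is bit-reproducible.

Injected outliers: `alien-band` adds a weak (0.2 AU) Gaussian band where
no profile absorbs (targets the orthogonal distance), `extreme-leverage`
moves a spectrum 8 score-sd along the first principal direction (targets
the score distance), `shifted-baseline` adds a 0.5 AU offset.

What the generator does **not** emulate: non-Gaussian line shapes,
wavelength-dependent scatter (true multiplicative scatter is modelled as a
single gain), instrument drift between sessions, water-vapour interference
bands, and label noise. Tests passing on this generator therefore show
algorithmic correctness and the expected qualitative behaviour, not field
performance on real packaging waste.

## Outlier screening

Per class, a PCA model is fitted about the column-wise **median** (a
cheap robustness choice; full ROBPCA with projection pursuit/MCD is out
of scope, and classical mean centering is available as an option). The
component count p is the smallest reaching a cumulative explained
variance of 99.9 % by default.

Each sample is then cycled into a prediction set: its score distance
SD = √(Σ_k t_k²/λ_k) and orthogonal distance OD = ‖x − x̂‖ are computed
from a leave-one-out refit on the other n−1 class members (p held fixed).
This is both the procedure the screening literature describes for
prediction objects and the reason a single gross outlier cannot pull the
subspace toward itself and mask its own residual — verified directly: with
the outlier left in the fit, an alien band is absorbed into the loadings
and its OD collapses. `prediction_set=False` scores against the single
full fit when speed matters.

Cutoffs at confidence α (default 0.95):

    SD² limit:  p(n−1)/(n−p) · F(α; p, n−p)          (Hotelling T²)
    OD  limit:  (n+1)/n × the SD² limit               (D-statistic)

The OD/SD limit ratio is exactly (n+1)/n. SD² is compared with its limit
directly. Raw OD is in absorbance units and cannot meaningfully be
compared with an F-scale limit, so the screen standardizes it to
`p·OD²/median(OD²)` over the class — a typical sample then scores ≈ p,
the same scale on which SD² lives — and compares that with the OD limit.
Both raw and standardized values are reported.

Categories follow the two flags: regular, good-leverage (high SD only),
orthogonal-outlier (high OD only), bad-leverage (both). The default
removal policy removes any sample beyond **either** cutoff; a
`high-od` policy that keeps good-leverage samples is available. Expected
false-removal rate on clean data is the nominal tail mass (≈5 % at
α = 0.95, driven by SD; the standardized OD of clean samples concentrates
tightly below its limit).

## Sample-set partitioning

* **Kennard–Stone**: classic max–min Euclidean selection; ties broken by
  lowest sample index.
* **SPXY**: Kennard–Stone on d_x/max d_x + d_y/max d_y; class labels are
  one-hot encoded for d_y. Stratified by default for labelled data with
  round-half-even per-class train counts (no single rounding rule is
  consistent with common printed 70/30 tables, so the package documents
  one and applies it uniformly).
* **DUPLEX 6:2:2**: per class, train gets ⌊0.6 n⌋; the remainder splits
  evenly between validation and test, an odd remainder favouring
  validation — the only rule consistent with the reference per-class
  counts (45, 45, 50, 51, 51, 44, 44, 41, 39, 36 / totals 446/150/150 for
  class sizes 75…60). Sets are seeded with farthest pairs and then take
  turns picking their max–min-distance sample.
* **random**: seeded, stratified, largest-remainder rounding.

## Preprocessing

Savitzky–Golay filtering uses `scipy.signal.savgol_filter` with
`mode="interp"` (polynomial edge interpolation keeps n_points constant).
Derivatives are scaled by the grid step into physical units (per cm⁻¹,
per cm⁻²). Pipeline names follow the chemometric shorthand grammar
`TOKEN(+TOKEN)*` with TOKEN ∈ {SG, SG-w, 1D, 2D, 1D-w, 2D-w, SNV, MSC};
`SG-w` directly followed by `1D`/`2D` fuses into a single smoothed
derivative with window w. Windows are point counts and must be odd;
polynomial order defaults to 2. SNV uses the n−1 standard deviation.
The MSC reference is the training-set mean and is frozen for
prediction-time data (no leakage). The 15-variant comparison catalog
(`STANDARD_PIPELINES`) rounds conventional even windows to odd neighbours
(20→19/21, 8→9) keeping all variants distinct.

## PLS, PLS-DA, and model complexity

The PLS1 core is NIPALS with mean centering (no variance scaling — the
chemometric norm, and it keeps derivative-preprocessed magnitudes
meaningful). For a univariate response each weight vector is the
normalized covariance direction X'y, so the fit is iteration-free and
exactly deterministic; X is deflated per component. Coefficients of every
nested model (1…A components) accumulate in one pass, which is what makes
cross-validation over all LV counts cost one fit per fold.

Binary PLS-DA codes the response +1/−1 and assigns the positive group
when the predicted response ≥ c, with threshold c = 0 by default.

Latent-variable counts are chosen by Monte Carlo cross-validation:
n random stratified holdouts, ERMCCV = Σ M_i / N (M_i misjudged in split
i, N total tested), argmin over LV counts with smaller counts breaking
ties. Library defaults are 100 splits × 20 % holdout; the bundled tests
and pipeline use 8–30 splits to keep run times in seconds, which leaves
the selection slightly noisier but unbiased. Accuracy is reported as
n_correct/n_total.

## Decompositions and voting

OAO trains each pair (i, j) on those two classes only; OAA and EPHAH
train every task on all samples. EPHAH task enumeration: for even k, all
(k/2)-subsets containing the first class (complement-deduplicated,
C(k,k/2)/2 tasks); for odd k, all ⌈k/2⌉-subsets (C(k,⌈k/2⌉) tasks, the
positive group the larger side); lexicographic order throughout. OAO and
EPHAH predict by maximum-win voting; OAA by the maximum of the k
continuous responses (thresholded voting would discard its calibration
information).

Vote ties are resolved by recursively building the same decomposition
restricted to the tied classes (trained lazily on the stored training
samples, cached per subset, MCCV rerun on the restricted problem), to a
default depth of 2; a persistent tie falls back to the largest mean
signed response margin over the tasks involving each class, then to class
order. Every path is deterministic.

Per-task LV selection is independent, which is why reported mean LV
counts are fractional. Serialized models (JSON) store per-task
coefficients and centers — enough to predict; a reloaded model resolves
ties with the margin rule since training spectra are not stored.

## Synergy-interval PLS

The axis is divided into k equal-width intervals in cm⁻¹ (the axis extent
counts one step-width cell per point, so 25 intervals over the default
grid are 319.98 ≈ 320 cm⁻¹ wide); points join intervals half-open, the
last closed. All C(k, j) combinations are evaluated exhaustively — a
budget guard (10⁶ fits) rejects infeasible (k, j) — scoring each by
5-fold seeded RMSECV at its best LV count ≤ lv_max, argmin with
lexicographic tie-break. Within a decomposition, each binary task runs
its own search and contributes j selections to the interval
selection-frequency table.

## Problem sizes used in the bundled checks

The test suite runs on compact grids (120–500 points spanning the same
4000–12,000 cm⁻¹ axis) and 10–50 samples per class; the stochastic
acceptance checks use 10–50 seeds. These sizes were chosen so the whole
suite completes in about a minute while leaving the statistical margins
(e.g. ≥90 % planted-interval recovery, ≥80 % rank recovery) wide.

## Known limitations

* The OD cutoff uses the F-form D-statistic for fidelity to the screening
  convention implemented here; standard ROBPCA practice uses a
  Wilson–Hilferty chi-square approximation instead, and the two differ in
  small samples.
* Median-centred PCA is only mildly robust; many simultaneous outliers in
  one class can still distort the loadings (the leave-one-out cycle
  protects against single gross outliers, not clusters of them).
* The EPHAH task count grows as C(k, k/2)/2 — 126 at k = 10 is fine, but
  k ≳ 16 becomes expensive; no screening of uninformative bipartitions is
  attempted.
* OAA's per-task ERMCCV is computed on strongly imbalanced holdouts; its
  error rate is not directly comparable to OAO's pairwise rates.
* Synthetic-data caveats listed above: results on the generator bound
  algorithmic behaviour, not instrument reality.
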