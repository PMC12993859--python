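# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `nutrimon`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic depletion experiment

The generator (`nutrimon.synthetic`) emulates a pilot-scale deep-water
hydroponic grow-out under depletion fertilization: nutrient solution is
supplied once at a treatment-specific strength and drawn down, with
water-only replenishment. The default design is three treatments —
T1 (100%), T2 (50%), T3 (25%) of full solution strength — in triplicate
tanks, nightly overhead imaging from 4 to 26 days after transplanting
(DAT), and destructive sampling of 5 heads per tank on DAT 11, 14, 18,
21, 23, 25 and 26 (315 ground-truth rows).

**Plants per tank.** The schedule removes 35 heads per tank, so the
default tank holds 40 plants — the smallest round count that keeps the
design feasible and leaves survivors for full-length trajectories. The
usable per-tank plant count in a real camera frame is rig-dependent and
configurable.

**Growth model.** Fresh weight follows a logistic curve
FW(t) = A·f^s·u_tank·u_plant / (1 + e^{−r(t−t₀)}) with defaults
A = 250 g, r = 0.35 d⁻¹, t₀ = 16 DAT — a realistic butterhead ("Rex")
trajectory over a 30-day grow-out. The treatment's fertilizer fraction f
scales the asymptote through the depletion exponent s = 0.342, chosen so
the half-strength treatment finishes at ≈78.9% of control fresh weight —
the calibration anchor from the physical experiment, not a fitted value.
Tank-within-treatment and plant-within-tank effects u are lognormal
(default SDs 0.03 and 0.08): treatment dominates the variance, as the
experiment's mixed-effects validation requires, while plants vary more
than tanks. Dry mass is a fixed 5% of fresh weight. Tissue
concentrations start at typical lettuce baselines (N 5.3, P 0.6, K 7.0,
Ca 1.2, Mg 0.35, S 0.25% of DM), are scaled by f^{s_n} with small
per-nutrient exponents (N 0.10 … Mg 0.05, putting T2 tissue N near 4.9%,
inside the healthy 4.0–5.6% band), and dilute linearly by 10% over the
grow-out.

**Imaging model.** Each plant renders as a quasi-circular rosette whose
area grows with fresh weight, on a configurable canvas (the real imager
delivers 1280×800×10; tests use 64×96 to 200×320). Channel reflectance
is affine in a nutrient index (tissue N relative to baseline) and a
biomass index (FW relative to the control asymptote): nitrogen status
raises NIR and green reflectance and deepens red/deep-red chlorophyll
absorption, so normalized-difference indices separate treatments by
construction. Gaussian pixel noise (default SD 0.01 reflectance units)
is added per pixel. Deliberately *not* modeled: leaf texture, occlusion
and overlap between plants, specular highlights, diurnal illumination,
and segmentation error (masks are exact). Passing tests therefore show
that the pipeline recovers the statistical structure it assumes; they do
not show robustness to real-greenhouse segmentation or illumination
artifacts.

**Seeding.** One master seed; growth, sampling, rendering and downstream
stages draw from generators derived by fixed offsets, so re-rendering
images never perturbs the growth draws. Identical seeds give
byte-identical tables.

## Vegetation-index features

Ten channels (blue 475, cyan 497, green 526, amber 603, red 640,
deep-red 665, far-red 740, NIR-850, NIR-940 nm, plus broad-spectrum
white). The default registry is every normalized difference over the
nine narrowband channels — 36 indices, 108 features after the ×3
statistics — approximating the ~106-feature set of the original
analysis, whose full composition is not public; the five indices the
analysis singles out (NDVI, GNDVI, NDRE, NDWI with NIR-940 standing in
for shortwave infrared, GRVI) keep their canonical names and
orientations. The registry is a YAML file, not code.

Per plant and night, each index is summarized over the masked foliar
surface as mean, median and **population** SD (ddof = 0; the convention
is arbitrary but fixed and documented). Two data sets are built: the
designated single nightly capture (index 1 of 8 hourly captures
beginning at 10 pm — the 11 pm frame — else index 0), and the average of
the per-capture summaries over the night. Division by a near-zero
denominator (|den| < 1e−9) yields 0 for that pixel, so summaries never
see NaN or inf.

## Anomaly autoencoder

Architecture is fixed at 64–32–64 regardless of window length L: each
window is one vector of length L, hidden layers use ReLU, the output is
linear (the activation and input representation are unstated in the
original description; this is the simplest reading). Inputs are min–max
normalized per time point with statistics from the training windows.
Training: Adam, learning rate 0.001, 100 epochs, full batch (the pool is
at most 40 windows). The threshold is τ = 1.5 × mean per-window MSE of
the training set at the final epoch — the per-window mean, not a pooled
per-element mean — and a window is anomalous only when its error
**strictly** exceeds τ (deterministic tie rule). Training uses the first
40 control windows in ascending plant-id order (a deterministic stand-in
for the unspecified acquisition order), or as many as destructive
sampling leaves.

A calibration property worth knowing: if window errors were iid noise,
the per-window MSE at L = 6 is ≈ χ²₆-distributed and ~17% of healthy
windows would exceed 1.5× the mean. The 1.5× rule therefore only yields
near-zero false rates when reconstruction errors are dominated by a
common floor (strong shared structure), which is also why the
perfect-detection acceptance property is evaluated under full separation
with zero within-treatment variation.

Window sweeps run L = 6…22 starting at 4 DAT (covering DAT 4–9 through
4–25); the range is configurable since descriptions of the original
sweep differ between 6–22 and 8–22.

## Random-forest state estimation

Eight response variables are estimated independently with scikit-learn
forests. Final per-RV hyperparameters follow the original tuning (900 or
1300 trees, depth 12–14, `max_features='sqrt'`, `bootstrap=False`,
squared-error criterion, seed 50); the documented search grid is
implemented but off by default for desk-scale runtime, and tests shrink
the forests (40–100 trees) — forest size affects runtime, not the
structural properties under test.

The 27-fold scheme enumerates all per-treatment choices of 2-of-3 test
tanks; each tank tests in 18 folds and each per-treatment pair occurs in
9. The unusual 6-test/3-train split is implemented exactly as specified.
Within the training tanks, records split 80/20 into train/validation
(seeded per fold); the per-fold model is refit on train+validation after
any tuning, and evaluation uses only genuinely labeled test records
(destructively sampled plants, labeled with their tank-day means).
Pseudolabels for unsampled records use the tank's 5-sample mean on the
nearest sampling day, with the earlier day winning distance ties — the
original rule only defines the sampling-day case; the nearest-day
extension is this package's choice.

Feature selection runs three stages per fold — recursive elimination of
the lowest-importance 10% down to a floor of 30 features, removal below
the 0.10 importance quantile, and correlation pruning at |r| > 0.95
keeping the higher-ranked member — with survivors aggregated across
folds by (frequency, median importance) and pruned once more before the
top 20 are fixed. The floor, quantile and cutoff come from an
unpublished supplement, so the defaults here are package choices,
exposed in `FeatureSelectionConfig`. Importances are impurity-based.

Trajectory estimation (the RF-AE input) uses a final model per RV refit
on all labeled+pseudolabeled single-image records, predicting on the
daily-average feature set — a data set the forest never trained on.
Whether the original used per-fold models or a final refit is unstated;
the refit is the default here.

## Patch-transformer tier

The full-scale configuration matches the described architecture: 10
input channels, patch embedding 256, 16 heads, 6 pre-norm encoder layers,
MLP width 1024, token-mean pooling, and a 256→128→8 ReLU head; batch 32,
initial learning rate 1e−4 realized as reduce-on-plateau (factor 0.5,
patience 10 — the original names only the initial value), MSE over
per-RV standardized targets (multitask scales differ). Patch size is
unstated; 16 at full scale, 4–8 at desk scale. `ViTConfig.desk()`
shrinks every dimension (32-dim embedding, 2 layers, 32×32 images) so
the architecture, the shared fold memberships, and the learnability
properties are exercised on CPU in seconds; full-scale training is
supported but not run in tests. Both neural tiers run on the package's
vectorized reverse-mode autodiff engine (`nutrimon._autodiff`), whose
gradients are verified against central finite differences in the suite.

## Energy accounting

Products of independent (P, t) propagate with the exact
variance-of-product formula σ_E² = (μ_t σ_P)² + (μ_P σ_t)² + (σ_P σ_t)²
— not the first-order approximation, whose missing cross term the
Monte-Carlo check would expose at the 1% level. Power logs summarize
with an SD floor of 5 W, matching the accuracy of 1-s-averaged NVML
readings. Facility scaling multiplies per-sample energy by heads × days
and preserves relative uncertainty. The embodied-N scenario defaults:
10,000 heads, 28 days, 0.383 ± 0.052 g tissue N per head, NUE 46%,
fixation intensity 9.7–13.9 (average 11.11) kWh/kg N; applied
N = tissue N / NUE, wasted N = applied × (1 − NUE), with the tissue-N
relative uncertainty carried through. Two published inconsistencies are
resolved explicitly: of the two printed anomaly-tier inference energies
(1.78e−6 vs 1.45e−6 Wh/sample) the package uses 1.78e−6, the only value
consistent with the printed 0.5 Wh monthly total; and the embodied/GPU
ratio computed from the printed point values is ≈45–64×, so the package
reports its computed range rather than the looser printed lower bound.
Raw values are kept at full precision; display rounds to 3 significant
figures (Wh) or 2 (kg, kWh).

## Tiered pipeline

The orchestration runs simulate → extract → early warning → (triggered)
estimation + RF-AE → energy report. The trigger metric is the **net**
excess flag fraction — treated flags minus the held-out healthy false
rate, the same correction the net detection rate applies — with a
default trigger of 10%. Every run writes a manifest with the
configuration hash, seeds and stage outputs; identical configurations
reproduce byte-identical tables.

## Problem sizes

Tests and the acceptance script run desk-scale versions of the study
conditions: 10–20 plants per tank, 64×96-pixel canvases, 1–2 captures
per night, the five named indices, and 40–100-tree forests. These sizes
were chosen so the full suite and the acceptance run each complete in
minutes on one CPU while preserving the experiment's structure (3×3
tanks, the sampling schedule, the 40-window training cap, all 27 folds).
Detection properties are evaluated over 5–10 independent seeds.

## Known limitations

- The reflectance link is affine and noise is iid Gaussian; real spectra
  saturate (e.g. NDVI in dense canopy) and real noise is structured.
- Masks are exact; segmentation error, frame cut-offs and plant overlap
  are out of scope.
- The 106-feature registry is an approximation; only the five named
  indices are guaranteed to match the original feature set.
- Real-greenhouse detection rates and estimation accuracies are
  data-dependent and are not reproduced by the synthetic properties.
- SHAP interpretation and mixed-effects variance decomposition are
  consumed downstream of this package (the fitted models and tidy tables
  are exported); they are not reimplemented here.
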