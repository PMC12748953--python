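# Methods

## Data model

The package works with five labeled matrix types. Expression `X` (proteins
× cells) holds nonnegative mean ion counts per cell; the dictionary `U`
(proteins × modules) holds unit-L2, nonnegative protein-expression modules;
module activity `W` (modules × cells) is sparse and nonnegative; the
barcoding matrix `A` (channels × proteins) is binary; composite data `Y`
(channels × cells) is nonnegative. Matrices are stored internally in
exactly these orientations — the same ones the formulas `X ≈ UW` and
`Y = AX` use — and serialized as CSV with a label column, a header row and
a `# role=` comment, so nothing is ever silently transposed.

Nonnegativity is enforced on `X`, `Y`, `W` and (by default) `U`: ion counts
are nonnegative, the factorization is seeded by NMF, and the pipeline never
produces negative expression. Both `U` and `W` carry an `allow_negative`
escape hatch for sign-unconstrained variants.

Barcode uniqueness (no two proteins share a column of `A`) is enforced as
an added constraint beyond the labeling rules: duplicate barcodes make two
proteins mathematically indistinguishable at the channel level. It can be
toggled off per matrix (`require_unique_barcodes=False`).

## Error-constrained sparse coding

Both the factorization steps and decompression need the sparsest
coefficients within a relative error budget,

    min ‖W‖₁  s.t.  ‖T − B W‖²_F ≤ λ ‖T‖²_F .

This constrained form has no direct solver, so it is reduced to the
penalized nonnegative Lasso. The penalty weight is found by geometric
bisection on `[α_max·10⁻⁶, α_max]`, where `α_max` is the smallest penalty
with an all-zero solution; the bracket shrinks until its ratio is ≤ 1.02
(≈ 10 solves; a hard cap of 40 steps applies), and the sparsest iterate
satisfying the constraint — with slack factor `1 + 10⁻³` for numerical
tolerance — is returned. If even a vanishing penalty cannot meet the
constraint (the target is not in the basis range within tolerance), the
sign-constrained least-squares solution is returned and an
`InfeasibleDecodeWarning` is raised; callers that score many candidate
designs suppress the warning and simply let infeasible candidates score
poorly.

Cells can be partitioned into `num_blocks` equal-count groups by column L2
norm ("vector size"), each group receiving its own bisected penalty and
satisfying the constraint per group. Because the penalty is shared within a
block, decoding the same cells in different batch compositions can differ
at the penalty-resolution level (measured ≈ 0.1% of the value scale);
results are exactly invariant to cell *permutation* but only approximately
invariant to *batching*. Exact batch invariance would require per-cell
constraints, a stricter problem than the global form solved here.

OMP is provided as the complementary parameterization (explicit per-cell
sparsity `k` instead of an error budget), via scikit-learn's
`orthogonal_mp` with columns normalized for atom selection, lowest-index
tie-breaking, and optional nonnegative clipping of the final coefficients.
Greedy selection has no per-column optimality guarantee on coherent
dictionaries (all-positive module bases routinely have mutual coherence
> 0.9); its near-oracle behavior should be expected — and is tested — at
the whole-instance level on incoherent bases.

## SMAF

The dictionary is learned by alternating minimization, starting from a
seeded random-init NMF with `d0` components (both factors rescaled so
modules are unit-norm and the product is unchanged):

1. **W-step** — fix `U`, solve the error-constrained Lasso at tolerance
   `ldaW` (or OMP at sparsity `k`), optionally blocked by vector size
   (`num_blocks_W`).
2. **U-step** — fix `W`, solve the transposed error-constrained Lasso at
   tolerance `ldaU` (the same bisection machinery on `Xᵀ ≈ Wᵀ Uᵀ`).
3. **Normalization** — rescale every nonzero module column of `U` to unit
   L2 norm, with the inverse scale folded into `W` so `UW` is preserved.

A fixed number of iterations is run (default 100, no early stop; an
optional relative-change stop exists but is off). Modules that end with an
all-zero dictionary column or activity row are pruned once, after the last
iteration, so the reported `d` is the effective module count — looser
`ldaU` prunes more aggressively. Infeasible intermediate steps (one factor
cannot yet express `X` within tolerance) are routine early in the
alternation; they fall back to least squares and are counted in the fit
report rather than warned.

Defaults ship as the finalized parameter set for immune/stromal IMC panels:
`algorithm_for_W = lasso`, `ldaU = ldaW = 0.02`, `num_blocks_W = 1`,
`d0 = 80`, 100 iterations. Whether to apply the titration blend (below)
before training is left explicit to the caller rather than implicit in
`fit_smaf`.

## Titration normalization

Antibody concentration differences scale protein rows of `X`. The blend

    X̃_wt = wt · X̃₁ + (1 − wt) · X ,    wt ∈ [0, 1]

interpolates between raw data (`wt = 0`) and protein-wise L2-normalized
data `X̃₁` (`wt = 1`, every nonzero protein row at unit norm), emulating
partial titration. Zero-norm protein rows (a marker absent from a small
region of interest) normalize to zero with a warning rather than an error.
`wt = 0` short-circuits to an exact copy so the identity holds bitwise.

## Barcoding-matrix design

Random designs are sampled under the labeling constraints: each protein
draws 1 or 2 channels (at most `max_single_channel_proteins = 4` proteins
may keep a single channel — denser designs decode better; excess
single-channel draws are promoted to two channels), channels are chosen
uniformly, and whole draws are rejected on duplicate barcodes or empty
channels. Feasibility (`p ≤ m + C(m,2)` distinct barcodes, enough
multi-channel codes for the non-single proteins) is checked up front.

The search is a two-round tournament. Round 1 runs `n_rounds` independent
passes (default 4); each scores `n_candidates_per_round` (default 2000)
fresh designs on a fresh 25% cell subsample by simulating `Y = AX`,
decompressing, and computing per-protein Pearson correlations, then keeps
the `top_per_round` (default 50) designs by **minimum** protein correlation
— a design cannot win by sacrificing its worst marker. Round 2 rescores the
pooled `n_rounds × top_per_round` finalists (200 at defaults) on
`n_rounds` fresh subsamples; the winner maximizes the across-pass mean of
the minimum protein correlation, with ties broken by mean protein
correlation and then candidate index, so the search is fully deterministic
given its seed. Evaluation subsamples are redrawn for every pass, in both
rounds. The decode tolerance used when scoring defaults to 0.02 (matching
`ldaW`) and is exposed.

Entries of `A` are strictly binary — an antibody either carries an isotope
or not; no row or column weighting is applied.

## Decompression

`estimate_activity` solves the error-constrained Lasso with basis `A·U`
(each module's composite signature) at tolerance `lda` (default 0.02,
matching the training `ldaW`), and `reconstruct` forms `X̂ = UW`. Cells
decode independently up to the shared block penalty discussed above. The
decode is positively homogeneous: scaling `Y` by `c > 0` scales `X̂` by
`c`. No channel rescaling or calibration is applied before decoding;
measured channels with unequal sensitivities should be calibrated upstream
(the hook is simply to rescale rows of `Y` before calling the decoder).

## Evaluation conventions

Accuracy is summarized by Pearson correlations computed per protein
(across cells; mean and minimum reported) and per cell (across proteins;
mean reported), on intensities exactly as given — no arcsinh or other
variance-stabilizing transform is applied anywhere in the pipeline.
Zero-variance series (a protein absent from `U`, a constant channel) are
assigned r = 0 *and* flagged, keeping the summaries defined while
preserving auditability; flagged entries are included in the mean/min as
zeros, a deliberately conservative choice. Inputs are aligned by protein
and cell identifier before comparison.

Two harnesses support dictionary selection: a hyperparameter sweep (fit on
75% of cells, score `n_random_A = 200` random designs on the held-out 25%,
per condition) and leave-one-tissue-out (fit on all but one tissue, score
on the held-out tissue, average across tissues). Cell-type classification
of the decompressed data is out of scope; `export_aligned_tables` writes
id-aligned truth/decompressed CSVs for external classifiers.

## Image processing

Hot pixels — isolated spuriously bright pixels from the ablation process —
are detected per channel as pixels exceeding the maximum of their in-image
8-neighborhood by more than a threshold (default 50, exposed on the CLI;
border neighborhoods are truncated, not padded). Two replacement rules are
provided: **clip** writes the neighborhood maximum into the hot pixel;
**min-propagate** writes the neighborhood *minimum* into the hot pixel and
all eight neighbors, suppressing halos. The latter runs in a single pass
with detection on the input image only; overlapping writes from adjacent
hot pixels, and writes onto already-darker neighbors, resolve to the
minimum, so neither filter ever increases a pixel and the output is
independent of scan order. Single-cell tables are mean pixel intensity per
channel within each mask label (ascending label order); `sum_channels`
pools marker channels, e.g. to build a cytoplasmic segmentation input.
Segmentation itself and spillover compensation are not implemented.

## Synthetic data generator

The generator emulates the statistical structure the method relies on, not
mass-cytometry physics. A ground-truth dictionary draws `d_true` modules
with 1–4 active proteins each (distinct supports, loadings uniform on
[0.5, 1.5], unit-normalized), constructed so that **every protein belongs
to at least one module** — a panel only carries markers expressed in some
cell type, and a protein outside all modules would have identically zero
expression and be unrecoverable by construction. Cells draw
1–`modules_per_cell_max` modules (default 2) with tissue-specific usage
probabilities from a symmetric Dirichlet (α = 1), and gamma(2, 1)
activities. Observed intensities are `U·W` times per-protein titration
scales (uniform on [0.5, 2]), times mean-one lognormal noise with
coefficient of variation `noise_cv` (default 0.1), plus an optional
constant background (default 0).

Titration scales and the dictionary describe the *antibody panel*, so
`generate_study` draws them once and reuses them across independent cell
draws — the setting of training on one experiment and decompressing
another. Drawing fresh scales per draw would model swapping the antibody
mix between experiments, which the workflow never does.

Not emulated: Poisson ion-count statistics, channel spillover, segmentation
errors, spatial autocorrelation, or cell-size effects. Passing tests on
this generator therefore demonstrate correctness of the encoding/decoding
machinery under modular signal structure with realistic intensity jitter —
not robustness to every artifact of real IMC data.

A small renderer draws each cell as a uniform disk on a grid with a
matching label mask (optionally with injected hot pixels at recorded
coordinates), giving exact image → table round trips for testing the image
path.

## Problem sizes in the test suite

The fixed-seed suite runs the full pipeline at reduced scale, chosen for
fast deterministic tests while leaving every checked property
scale-invariant: end-to-end recovery uses p = 16, d_true = 10, 2000 cells
per draw, noise CV 0.1, dictionaries fitted with d0 = 20 and 15 iterations,
and a reduced search (2 passes × 100 candidates, top 10) — mean protein
correlation ≥ 0.9 over 5 seeds. Channel-count monotonicity (m = 7, 8, 9)
uses 1000 cells and a 2 × 20 search. The acceptance script uses 1500 cells
per draw with the same dictionary settings. Full-scale defaults (d0 = 80,
100 iterations, 4 × 2000 search) remain the package defaults.

## Known limitations

* Batch-partition invariance of decoding is approximate (see above).
* The "sparsest within tolerance" solution is approximated by penalty
  bisection; it is not a certified minimizer of the L1-constrained program.
* OMP inherits greedy suboptimality on coherent dictionaries.
* Correlations on raw intensities weight bright cells more than a
  transformed analysis would; the choice is deliberate and documented.
* The generator's noise and abundance families (lognormal, gamma,
  Dirichlet) are simple nonnegative choices, exposed as parameters, not
  fits to measured data.
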