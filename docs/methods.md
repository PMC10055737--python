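# Methods

`cortodeconv` estimates position-dependent densities of
transcriptomically defined cell types in cortex by fitting cell-type
transcriptomes to in-situ hybridization (ISH) image intensity. This
note describes the model, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## The model

The cortical cross-section is discretized into a grid of 100
normalized-depth bins (0% = top of layer 1, 100% = bottom of layer 6)
by 40 soma-area bins of 20 px each (1 px = 1 µm²). For every gene *i*
the ISH **intensity density** `E[i, j, k]` is the total
baseline-subtracted soma intensity in depth bin *j* and area bin *k*,
divided by the annotated slice area at depth *j* (mm²). Binning by
soma area is the soma-size compensation: without it, a bulk linear fit
would credit large-bodied cell types with more cells than they have,
because a larger soma integrates more label per cell.

Within each bin the intensity vector over genes is modelled as linear
in the cell-type composition,

```
E[·, j, k] = T · C[·, j, k],        C ≥ 0
```

where `T` is the gene × type matrix of median scRNA-seq expression and
`C[t, j, k]` the density of type *t* in that bin. Each of the 4,000
bins is solved independently by non-negative least squares
(`scipy.optimize.nnls`). Because the design matrix is shared by all
bins, it is QR-compressed once and each bin reduces to an
`n_types × n_types` problem with the same minimizer; the full-size
solver is used directly whenever the design is not full column rank.

### Fit error

Prediction quality is summarized per gene on expression **summed over
all bins**: the squared error is `Σ_i (Σ_jk E_pred − Σ_jk E_obs)²`.
Summing before squaring matches how predicted-vs-actual expression is
usually displayed (one point per gene) and makes the error insensitive
to within-gene spatial rearrangement; the per-bin residual norms are
reported separately in the `FitReport`.

## Normalizations

Two corrections precede the solve, in this order (configurable):

1. **Per-bin median scaling** — every (depth, area) bin is divided by
   the median of its non-zero gene values, so the non-zero median of
   each touched bin becomes exactly 1. This removes bin-level
   labelling-scale differences; it also deliberately discards per-bin
   magnitude, which the next step restores along depth. All-zero bins
   are left unchanged and logged. The operation is idempotent.
2. **Nissl depth rescaling** — each depth bin is multiplied by
   `s(j) = c · n(j)/m(j)`, where `n(j)` is the cell-density profile
   from Nissl-stained slices, `m(j)` the mean expression profile, and
   `c` keeps the global mean unchanged. Depth bins with `m(j) = 0`
   are zeroed and logged. "Matching the shape" is implemented as exact
   proportionality; afterwards the mean profile is proportional to the
   Nissl profile to machine precision.

Both operations preserve non-negativity, keep zeros at zero, and do
not change the rank order of genes within a bin.

## Canonical-distribution standardization

Median scRNA-seq transcriptomes differ in **completeness** (fraction
of genes with non-zero values) and in the **shape** of their sorted
value curves. A linear fit would systematically under-weight types
with incomplete or compressed transcriptomes, so all types are mapped
onto one **canonical distribution**: a shared sorted value template,
seeded from the most complete type (fewest zeros; ties to the larger
total).

Genes observed non-zero in a type keep their own rank order. A gene
missing from a type borrows a rank key from the cell-class hierarchy
(fine interneuron/excitatory classes → excitatory/inhibitory → broad
cell classes → all cells): the key is the class mean over members with
non-zero values, taken from the **finest** level with a non-zero mean,
and is merged into the type's own value ordering. We read "rank order
of the average non-zero entries" as borrowing a per-gene class-mean
key; this reading is order-consistent and total, and provenance
records the level used for every filled entry. Genes zero in every
class at every level sink to the lowest ranks. All ties are broken
deterministically: an exact tie between a borrowed key and an observed
value goes to the observed gene, and remaining ties follow gene order.
The corrected matrix is `T_corr[i, t] = canon[rank[i, t]]`, so every
type's sorted transcriptome equals the canonical distribution exactly.

## Stochastic refinement

The canonical distribution is refined by accept-if-improved search:
add `scale · N(0, 1)` noise per entry, clip at zero, re-sort, rebuild
`T_corr`, re-solve all bins, and keep the candidate iff the squared
prediction error strictly decreases. Convergence is declared after
`patience` consecutive non-improvements (default 100) with a hard cap
of 10,000 iterations.

Numerical choices:

- **Perturbation scale** defaults to 1% of the canonical maximum; the
  method prescribes a single scaling constant without a value.
- **Gauge fixing.** The fit error is exactly invariant to a global
  rescaling of the canonical (NNLS absorbs any positive factor into
  the compositions), so that direction is an unconstrained random walk
  that would make independent runs drift apart in overall scale.
  Every candidate is therefore rescaled to the starting canonical's
  mean — indistinguishable to the error, and the final anchoring makes
  the canonical's absolute scale irrelevant anyway.
- **Bin subsampling.** Re-solving all 4,000 bins per iteration is the
  dominant cost, so candidates can be evaluated on a deterministic,
  evenly spaced subsample of the occupied bins (config), with a final
  full-grid solve afterwards.
- Negative entries after perturbation are clipped to zero (expression
  is non-negative).

Reproducibility of the refinement is assessed on noise-free synthetic
data, where the error minimum is well-defined; two runs from different
seeds converge to final errors within a few percent and canonical
distributions within a few percent of the peak value. A residual soft
mode remains: the largest canonical entries can trade off against
per-type composition scales with little error change, so the top-rank
entries converge most slowly.

The optional non-neuronal adjustment re-orders the borrowed ranks of
selected classes (astrocytes, oligodendrocytes, microglia — the least
complete transcriptomes) above a per-class rank floor, by
pairwise-swap hill climbing on the RMSE of the predicted expression of
those genes. Rank floors have no published values and are plain
configuration; no literature composition percentages enter the
objective.

## Densities, anchoring, marginals

NNLS compositions are relative (the normalized intensity scale is
arbitrary), so absolute densities come from anchoring: one global
scalar brings the mean neuron density over depth bins with midpoint in
(8%, 100%] — layer 2 top to layer 6b bottom, with layer boundaries at
8/20/35/45/70/95/100% of cortical thickness — to 120,000 cells/mm³.
The same scalar multiplies non-neuronal types, preserving all relative
compositions. Areal densities (per mm²) are converted to volumetric
(per mm³) by dividing by a nominal slice thickness (default 25 µm, a
typical ISH section); the anchoring scalar absorbs this constant, so
the choice does not affect anchored results.

Depth profiles sum the composition over area bins; soma-size kernels
sum over depth bins and normalize to 1 (zero-density types keep an
all-zero kernel and a log entry). Broad-class profiles sum member
types.

## Imaging front end

The baseline of an annotated region is its modal intensity (exact
value counts for integer images, fixed-width histogram for floats,
ties to the lowest value). Somas are pixels above
`baseline + k · MAD` (default k = 3; the median absolute deviation
resists bright outliers), labelled with 8-connectivity, and filtered
by minimum area (4 px) and circularity `4π·area/perimeter² ≥ 0.6`,
which removes elongated dendrite-like artifacts. A spot's depth is the
mean normalized depth of its pixels; boundary conventions are
half-open with the top edge clamped into the last bin (depth exactly
1.0 → bin 99; area ≥ 800 px → bin 39; an area exactly on a bin
boundary goes to the higher bin). Merged (touching) somas are not
split by watershed, and no correction is attempted for layer-1 folds.

One unit inconsistency is inherited from the imaging convention: a
20-px area bin is treated as 20 µm² (1 px = 1 µm²) even though the
nominal microscope surface area of 20 px is sometimes quoted as
22.9 µm²; we use 20 µm² throughout.

## Synthetic data: what it emulates, what it does not

The generator plants a complete ground truth so every stage is
testable without any image download:

- **Transcriptomes** — per-type lognormal value vectors with a
  type-specific sigma (`shape_spread` varies the sorted-curve shape),
  a distinct boosted marker block per type (keeps the column-normalized
  matrix well-conditioned), and dropout that zeroes a per-type fraction
  of entries drawn from `1 − completeness`. Zeros are placed in the
  lowest-value entries: weakly expressed genes are the plausible
  dropouts, and this preserves sortability.
- **Densities** — each type occupies one layer (cycled over layers
  2–6b so the anchoring window is populated), with a Gaussian depth
  bump truncated to its layer and floored at 0.1% of peak. The
  truncation matters: real layer-confined types vanish outside their
  layer, whereas infinite Gaussian tails would leave faint mass in
  every bin that the per-bin median normalization then inflates into
  spurious signal. Each type has a unimodal soma-size kernel, and the
  planted density is profile × kernel — separable by construction,
  which the marginal-consistency tests exploit.
- **Expression** — the exact linear forward model, an optional
  per-area-bin intensity scaling (soma intensity integrates over soma
  area), and mean-1 lognormal noise with a chosen coefficient of
  variation, drawn per (gene, depth bin) to mimic per-slice labelling
  variability. The default `noise_cv` is 0.1; no published measurement
  of ISH slice-to-slice variability exists, and 10% is a realistic
  scale for labelling variation. The noise model is multiplicative
  because slice labelling differences are scale effects.
- **Images** — filled disks on a constant baseline with exact planted
  areas and intensities; overlapping disks are flagged as merged.

Passing tests on these data show that the pipeline inverts its own
forward model, reproduces its exact algebraic identities, and is
reproducible. They do not show robustness to the things real ISH
images add: anti-aliased and textured somas, dendritic processes,
folds, tears, uneven illumination, depth-annotation error, or
transcriptome taxonomies whose classes are imperfect. Layer-overlap
between types is also mild in the synthetic truth; heavily
co-localized types with correlated transcriptomes will degrade
gracefully (the noisy-recovery tests quantify this at 10% noise) but
are not the regime the generator emulates.

## Problem sizes

The bundled checks use 200–2,000 genes and 4–8 types on the full
100 × 40 grid; refinement runs use 300 genes with 60-bin subsampling
and a 2,000-iteration patience. These sizes keep every property at
full numerical resolution — the identities checked are exact or
tolerance-bounded regardless of scale — while the complete suite runs
in minutes.

## Known limitations

- The per-bin median normalization erases per-bin magnitude by
  design; depth structure is restored from the Nissl profile, but
  within-depth area structure is carried only by gene composition.
  Soma-size kernels therefore reflect support and composition, not raw
  intensity magnitude.
- No stereological correction for cells cut at slice boundaries; no
  nonlinear intensity–expression model.
- The refinement is a random search; its runtime is dominated by the
  per-iteration NNLS re-solve and grows linearly with the number of
  evaluated bins.
- `assign_zero_ranks` borrows class means as rank keys; other readings
  of rank borrowing exist, and the chosen one is documented above
  precisely because it is a choice.
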