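# Methods

This note records the models, parameter choices and numerical conventions
behind `macscreen`, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Population model

A responding B-cell culture is modelled as independent founder lineages:

- **Time to first division** T₁ ~ Lognormal(meanlog, sdlog). Broad variance
  in T₁ is what produces the asynchronous division peaks seen in
  dye-dilution profiles; defaults meanlog = ln 40 h, sdlog = 0.2.
- **Subsequent divisions** occur at a fixed interval Δ (default 10 h) —
  first division is slow, later ones fast and comparatively regular.
- **Death** is a memoryless per-hour hazard λ (default 0.01/h) applied to
  every live cell.
- **Differentiation** to the CD138⁺ ASC state happens at division: a
  daughter entering generation i acquires the absorbing label with
  probability clamp(p₀ + s·i, 0, 1) (defaults p₀ = 0, s = 0.05), i.e. the
  per-division frequency increases with generation, and undivided cells
  never differentiate.
- **Compound effects** are time-constant multipliers (s_surv, s_div,
  s_diff) on hazard, division rate and differentiation probability —
  matching a single-dose, fixed-concentration screen design.

Two modeling choices deserve emphasis:

1. **The ASC label does not alter kinetics.** CD138⁺ cells keep dividing
   and dying like their CD138⁻ siblings over the simulated 3-day window
   (plasmablasts are proliferative on this timescale). This makes the three
   perturbation axes orthogonal by construction: a uniform hazard multiplies
   every generation's census by the same e^(−λt), so MDN and CD138% are
   exactly invariant to s_surv, and s_diff moves only the label. Under the
   alternative (ASC frozen out of cycle), a differentiation-only compound
   would mechanically depress MDN (~−11% at s_diff = 2) and total cell
   number (~−17%), i.e. a single-axis perturbation could never be recovered
   as single-axis. We prefer the interpretable factorization; the residual
   genuine coupling is discussed below.
2. **Division-linked differentiation couples CD138% to proliferation.**
   Because the label is acquired at division, fewer divisions mean fewer
   ASC: s_div = 0.85 lowers 72 h CD138% by ~35% (relative) alongside its
   −30% MDN effect. This is biology, not an artifact — cultures blocked in
   proliferation genuinely produce fewer ASC — and it motivates the per-axis
   effect bands of the classifier.

The **expectation oracle** integrates the same process deterministically:
the flux into generation 1 is B₁(s) = 2·n₀·f(s)·e^(−λs) with f the (rate-
scaled) T₁ density; B_i(s) = B₁(s−(i−1)Δ)·2^(i−1)·e^(−λ(i−1)Δ); censuses
follow by integrating against the survival kernel on a 4001-point trapezoid
grid (relative quadrature error ≲ 10⁻⁴ at 72 h); the ASC split is
q_i = 1 − Π_{j≤i}(1 − p_j); deaths close the bookkeeping identity
dead = n₀ + #divisions − live. The test suite holds the agent simulator to
this oracle per compartment within 3 Monte-Carlo SE.

## Flow cytometry emulation and statistics

Events are sampled per well with an acquisition fraction (default 0.3)
applied identically to cells and to the 10⁴ spiked calibration beads, which
is what makes the live/bead ratio an unbiased absolute-count estimator.
CTV-like intensity is i₀/2^gen with multiplicative lognormal noise
(mean 1, CV default 0.10); dead cells appear as non-viable events.

Division assignment uses round(log₂(i₀/intensity)) clamped to [0, max_gen] —
geometric bin edges at half-integer log₂ distances. At CV 0.10 this assigns
≥ 99% of events correctly; peaks blur together above CV ≈ 0.2.

Classification calls each axis by a Welch contrast vs control wells,
Bonferroni-corrected across compounds and gated by a one-way ANOVA across
all groups (α = 0.05), **and** by a minimum relative effect size:
0.15 (survival, 24 h counts), 0.10 (proliferation, 72 h MDN), 0.40
(differentiation, 72 h CD138%). The bands encode "biologically meaningful at
this assay's precision": with hundreds to thousands of events per well the
contrasts resolve 2–3% shifts that no screen would act on, and the
differentiation band is wider because CD138% inherits proliferation changes
at roughly their own relative magnitude (see above). MDN uses all live cells
by default; `exclude_undivided=True` restricts to divided cells.

## Synthetic transcriptomes and reads

Per-well pseudo-bulk counts are negative binomial (dispersion 0.1) around
baseline means drawn lognormally (a heavy-tailed abundance distribution),
with ASC-set genes scaled by 1 + k·f_ASC and pro-apoptotic genes by
1 + k·f_dead (k = 10), then normalized to a fixed expected depth. This
carries the signature structure the scoring stage assumes; it does not
emulate gene–gene correlation, batch/position effects, ambient
contamination or zero inflation, so passing tests demonstrate estimator
correctness, not robustness to those artifacts.

The FASTQ generator writes R1 = barcode(10) + UMI(10) and R2 = 15-nt primer
pad + 35-nt transcript substring, with per-(well, gene) distinct UMIs and a
configurable PCR duplication factor; substitution errors (if any) go into
the transcript-derived bases. Gene assignment is by unique exact substring
against the toy transcriptome — the desk-scale stand-in for unique-best-hit
genome alignment; reads matching zero or ≥2 genes are discarded. Quality
gating (min Q20) spans R1 positions 1–20, the span that determines molecule
identity. With error rate 0 the whole path is exact: the count matrix
equals the generating molecule table for any duplication factor.

## Scoring, embedding, selection

The signature score is the area under the set-gene recovery curve over the
top ⌈5%·G⌉ ranks, normalized by the maximal area; ties in expression are
broken by gene id for determinism, and the rank basis makes the score
invariant to monotone transforms (so raw vs CPM vs log makes no
difference). Compound embedding standardizes genes, takes the top 10 PCs,
builds a Jaccard-weighted shared-nearest-neighbour graph (k = 10) and
partitions it with seeded RB-configuration community detection at
resolution 2; the 2-D coordinates are the first two PCs and are for
plotting only — only the partition is contractual. Multi-parameter
selection z-scores compound means against the control-well distribution
with thresholds z ≥ 2 (differentiation up) and z ≤ −2 (cell-number down).

## Integration, CRISPR screen, ELISpot

Methylation-change bins follow the fixed intervals (−∞,−2), [−2,−1),
[−1,0), (0,1], (1,2], (2,∞); logFC exactly 0 belongs to no bin and is
excluded (measure-zero in real data). Each bin's RNA logFC is compared to
the pooled Low-down + Low-up genes (the minimal-change reference) by
two-sided Wilcoxon rank-sum; an all-pairs mode with Bonferroni is
available. DEG filtering retains |logFC| ≥ 1 and adjusted p ≤ 0.05, both
boundaries inclusive.

Screen deltas average replicates per guide, then guides per gene; the
dependence z standardizes treated-minus-untreated deltas over the plate's
genes with mean/SD (median/1.4826·MAD behind `robust=True`), excluding
uninfected controls; hits at z ≤ −1; ranking is descending so
dependence-abolishing genes occupy the bottom. On null plates the hit
fraction sits at Φ(−1) ≈ 0.159 up to the O(1/n) bias of plug-in
standardization.

ELISpot images are registered by the integer circular shift maximizing
FFT cross-correlation with the stack mean (one pass; circular shifts are
harmless on a constant background). The background is the pixel-wise
median; for even stacks the **lower median** is used so the background is
always an observed intensity. A stack represents a plate's worth of wells:
the median is only spot-free where fewer than half the wells are spotted at
a pixel, so the generator defaults to 12 wells per stack. Detection
thresholds the deviation (background − image for dark spots) at
k·(1.4826·MAD) with k = 5, labels 8-connected components and keeps areas in
[4, 2000] px. Generator truth area is the hard-disk pixel area before
smoothing (radius 5 px, depth 25, noise SD 2, smoothing σ 0.8); at these
settings the detected contour sits ~0.3 px outside the disk edge, keeping
area errors well inside 15%.

## Determinism and problem sizes

Every generator takes a seed or Generator; the pipeline derives per-well
substreams from one config seed via `SeedSequence.spawn`, and FASTQ gzip
headers are written with a pinned mtime, so a rerun of the same config is
byte-identical. Default problem sizes (2000 founders per well, 100-plate
recovery batches, 200-plate null calibration, 20 image stacks) were chosen
so that recovery rates have ≤ ~2% binomial SE while the whole verification
suite completes in a few minutes on one core.

## Limitations

- No division destiny (cessation) mechanism beyond the max_gen cap; no
  time-varying compound effects; no ASC death/efflux.
- Flow emulation has no spectral spillover, doublets or debris; event
  tables replace FCS files.
- Read processing does no genome alignment, splicing, or UMI error
  collapsing (UMI edit distance 0 by design).
- Upstream differential statistics (moderated fits, TMM normalization) are
  consumed, not computed.
- ELISpot handling assumes pre-cropped single-well grayscale images; no
  well-boundary detection or color deconvolution.
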