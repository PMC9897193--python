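# Methods

## The problem

Recent, short-lived balancing selection leaves faint genomic traces that are
easily confounded with neutral variation, and single-time-point statistics
have little power against it. Serial samples — present-day haplotypes plus
small batches of ancient haplotypes at known ages — observe the allele's
trajectory directly, so a classifier that reads both should recover signal a
present-day-only method cannot. `tempobal` implements the full
simulation-based pipeline: a forward Wright–Fisher simulator generates
labelled serial haplotype samples under neutrality or overdominance, an
encoder turns them into fixed-shape tensors, and a two-branch residual
convolutional network performs the ternary classification (neutral N, weak
D0.25, moderate D0.5 overdominance).

## Simulation model

A diploid population of size N(t) (piecewise epochs with optional exponential
growth; years are converted with a configurable generation time, default 25
yr) evolves an L-bp locus (default 50 kbp) with infinite-sites mutation
(per-bp rate μ) and Poisson crossover recombination (per-bp rate ρ), both
defaulting to 1.25×10⁻⁸ per bp per generation. Balancing selection is
symmetric overdominance at one focal site: genotype fitnesses 1 : 1+s : 1,
giving the deterministic recursion

    p' = (p² + p(1−p)(1+s)) / (1 + 2p(1−p)s)

with fixed points at 0, ½ and 1. The focal variant arises de novo on one
random haplotype at the configured onset time (default 10 kyr BP, i.e. 400
generations) at the locus centre.

Each generation: diploid parents are drawn proportionally to fitness
(viability selection at the focal genotype only), each offspring haplotype is
a gamete of one parent with Poisson(ρL) crossovers at uniform positions, and
Poisson(2N′μL) new mutations fall on random haplotypes at uniform (continuous)
positions. Lost variants are pruned every generation; fixed non-focal
variants are pruned only until the first sample has been drawn, after which
they are retained so that younger sample blocks can report derived-fixed
sites consistently with older blocks.

**Sampling.** Haplotypes are copied (without replacement, without removing
individuals) at each configured age; the default design is 10 haplotypes at
8k/4k/2k/1k years BP plus 40 at present. A `TemporalSample` aligns all blocks
on the union of sites segregating in the pooled sample (plus the focal site,
always reported), columns ordered by position.

**Conditioning.** Selected replicates are retained only if the focal allele
segregates — frequency strictly inside (0,1) — in the present-day sample.
Because the pre-onset population is independent of the focal allele's fate,
failed attempts restart from a cached copy of the onset-generation state (a
fresh random stream per attempt, capped at `max_condition_attempts`, attempt
count recorded in provenance). Setting s = 0 with conditioning gives the
matched "conditioned-neutral de novo allele" control used in the tests.

**Equilibration.** Two modes. `forward` (default): the population starts
monomorphic and evolves 10·N neutral generations at the ancestral size —
E[S] then sits within ~1% of mutation–drift equilibrium. `coalescent`: the
starting haplotypes are drawn from a constant-size coalescent simulation
(msprime) at the ancestral size, which targets the same equilibrium at a
fraction of the cost; sampling the whole population (n = 2N) stretches the
coalescent's n ≪ N assumption, a standard and benign approximation of
recapitation-style initialisation. The calibration tests exercise the
forward path; the bundled desk-scale configuration uses the coalescent path.

**Rescaling.** A factor λ ≥ 1 divides sizes and times by λ and multiplies s,
μ and ρ by λ, preserving Ns, NμL, NρL and times in units of N generations.
Validity requires λs < 1 and every epoch size ≥ 2 (both enforced). The test
suite verifies distributional invariance of (S, π, present-day focal
frequency) between λ = 1 and λ = 5 by rank tests.

**Demography default.** The bundled "European-like" history — ancestral
10 000; bottleneck to 2 000 at 2 000 generations BP; recovery to 5 000; ~1.15%
per-generation growth over the last 200 generations to ~50 000 — is a
stand-in with round numbers, not a reproduction of any fitted published
model, and is fully config-driven.

## Encoding

Within every block, identical haplotypes are grouped and groups sorted by
descending multiplicity (ties: descending lexicographic order of the bits),
a canonical form invariant to row order. The W SNP columns nearest the focal
position (locus centre for neutral loci; W default 128) are kept, identically
across blocks; if fewer exist, zero columns pad both sides symmetrically.
SNP columns are *not* re-sorted by frequency, preserving positional/linkage
structure. The present-day block becomes a 40×W matrix (one input channel);
the ancient blocks are stacked oldest→youngest as a T×10×W tensor whose T
time points enter the network as channels. Alleles are 0 = ancestral,
1 = derived (the simulator knows polarity); for unpolarised user data the
reader can fall back to minor = 1.

## Network

Each branch: a 3×3 convolution stem (64 filters, 1×1 'same' padding by
default) with rectified-linear activation, then `n_residual_blocks` (default
2) stages of 2×2 max-pooling followed by a residual block
(x + relu(conv(x))), then global average pooling to a fixed-length embedding.
Branch embeddings are concatenated, passed through dropout (0.25) and a
single dense layer to 3 logits/softmax. Haplotype-permutation invariance is
supplied by the canonical sorting upstream; an optional exchangeable present
branch (row-shared 1×3 kernels, so rows are never mixed before the mean
reduction) provides architecture-level invariance behind
`exchangeable_present=True`. Ablations (`present_only`, `ancient_only`)
construct only that branch feeding the same head and are trained from
scratch — they are separate classifiers, not zero-masked variants; a
structural test separately checks that zeroing the ancient embedding equals
applying the head to (present embedding, 0).

The layers (convolution via one im2col GEMM per direction, pooling, dense,
Adam) are implemented directly on NumPy in float32, with explicit
forward/backward passes verified against finite differences; everything is
seeded, so two builds with the same spec have identical parameters and a
(config, seed) pair reproduces training bit-identically.

## Training and evaluation protocol

One stratified train/validation/test split (fractions default 0.8/0.1/0.1)
is fixed; `n_repeats` (default 10) independent trainings vary only
initialisation, batch order and dropout (seeds base, base+1, …), isolating
training variance in the accuracy interval. Optimiser: Adam, learning rate
10⁻³, batch 32, up to 50 epochs, early stopping on validation accuracy
(patience 10), best-validation weights restored. Per repeat a 3×3 confusion
matrix (rows = true, columns = predicted; a transposed rendering is a display
option) and its accuracy are reported, aggregated as mean ± t-based 95%
interval (n = 10 is too small for a percentile bootstrap) and an element-wise
mean of row-normalised matrices. Weak-vs-moderate discrimination is the
accuracy over the two selected-class rows. A single repeat yields a point
estimate with the interval flagged undefined.

## Desk-scale study conditions

The full design (2 000 replicates/class, N ≈ 10⁴, 400 selected generations)
is beyond a desktop run, so the bundled `desk_scale.yaml` shrinks it ~20×
while keeping its shape: ancestral N = 1 000 bottlenecking to 500 at 50
generations BP; θ_locus = 4NμL = 20 (μ = ρ = 10⁻⁷); onset 40 generations BP
with samples at 32/16/8/4/0 generations (the same 0.8/0.4/0.2/0.1/0
proportions of the onset age) and the 10/10/10/10/40 block sizes; 400
replicates per class (300 train / 50 validation / 50 test); W = 64; 16
filters; 3 repeats, ≤30 epochs. Selection is strengthened to s = 0.20 (weak,
2Ns = 200) and s = 0.40 (moderate, 2Ns = 400) so that both selected classes
approach the overdominant equilibrium (½) by the present *at different
speeds*: the present-day sweep-like cluster separates selected from neutral,
while the approach trajectory — visible only in the ancient blocks — carries
most of the weak-vs-moderate signal. At weaker scaled coefficients
(2Ns ≤ 100) the weak class is statistically indistinguishable from
neutrality at these sample sizes, which collapses ternary accuracy; that
regime is a genuine property of the inference problem, not of the
implementation.

## What the synthetic data does and does not emulate

The generator reproduces the study's sampling design, demographic rescaling
and selection model exactly as configured, but real ancient-DNA cohorts add
post-mortem damage, low and uneven coverage, pseudo-haploid calls, phasing
error and population structure across time points — none of which are
modelled (deliberately, matching the scope of the study design). Passing
tests therefore demonstrate the statistical machinery and the value of
temporal information under idealised data, not field performance on real
aDNA.

## Numerical and design notes

* All randomness descends from one base seed through documented
  `SeedSequence` spawn keys (class, replicate) for simulation and integer
  offsets for training repeats; no stage reads ambient entropy.
* Positions are continuous uniform in [0, L); the ms-style writer rounds to
  6-decimal fractions of L (0.05 bp at 50 kbp), the only lossy step in the
  round trip.
* Window tie-breaks: columns are ranked by (distance to focal, position);
  sorting tie-breaks are fully specified, so encoding is deterministic.
* Degenerate inputs: zero segregating sites encode as all-zero tensors;
  monomorphic populations stay monomorphic without mutation; an empty
  confusion-matrix row pair yields NaN pairwise accuracy rather than a
  silent 0.
* Early stopping keeps the *first* epoch attaining the best validation
  accuracy (strict improvement), which makes the restored weights
  deterministic.
* The interval uses Student's t with n−1 degrees of freedom; with all
  repeats identical its width is 0.

## Known limitations

* Forward burn-in at full human scale is impractical; the coalescent
  initialisation is the intended route for large configurations.
* The NumPy network is single-threaded and sized for desk-scale inputs;
  training the full-scale 64-filter/W=128 design on thousands of replicates
  is possible but slow.
* The classifier consumes polarised 0/1 haplotypes; genotype likelihoods and
  missing data are out of scope.
* Class labels ("D0.25", "D0.5") name the design's full-scale selection
  strengths; the desk-scale configuration reuses them for its strengthened
  coefficients so that reports are comparable across scales.
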