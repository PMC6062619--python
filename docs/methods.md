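# Methods

## Model

An individual with admixture proportions `q` on the K-simplex carries, at
each biallelic SNP `m`, counted-allele frequency `f_m = Σ_k q_k p_km`,
where `p` is a fixed panel of ancestry-specific allele frequencies.
Genotypes are independent binomial draws given `f`:

* diploid dosage `g ∈ {0,1,2}`: contribution `g·ln f + (2−g)·ln(1−f)`;
* pseudo-haploid call (one sampled allele coded 0/2): contribution
  `(g/2)·ln f + (1−g/2)·ln(1−f)`.

Missing genotypes contribute nothing.  The panel is never re-estimated
(supervised projection): only `q` is free, and the log-likelihood is
concave in `q`, so the optimum is global and a deterministic start
suffices.

### Estimation

`q` is fitted by multiplicative EM,

```
q_k' = q_k / (c·M_obs) · Σ_m [ a_m p_km / f_m  +  (c − a_m)(1 − p_km)/(1 − f_m) ]
```

with `c = 2` (diploid, `a = g`) or `c = 1` (pseudo-haploid, `a = g/2`),
from the uniform start, stopping when the relative log-likelihood change
falls below `tol`.  The likelihood is non-decreasing at every step; the
trace is retained on the estimate for auditing.  Zero components are fixed
points of the update (the boundary is absorbing), which the bootstrap
exploits.

Defaults: `tol = 1e-6`, `max_iter = 2000`, panel frequencies clamped into
`[1e-6, 1 − 1e-6]` (exact 0/1 frequencies otherwise make the log-likelihood
unbounded), `min_markers = 100` non-missing markers to attempt a fit
(below that, bootstrap standard errors are not meaningful).

### Boundary snapping (`zero_tol`, default 5e-3)

Under a relative log-likelihood stopping rule, a truly absent ancestry
decays geometrically but stalls at a small positive value (empirically
~1e-3 at M ≈ 1e4) because its remaining likelihood gradient is below the
stopping threshold.  Left as-is, such residue would later be declared
"significant" by the confidence-interval rule (a tiny mean with an even
tinier bootstrap spread), defeating sparsification.  After convergence,
components below `zero_tol` are therefore set to exactly 0 and the rest
renormalized.  The threshold sits an order of magnitude below both the
smallest admixture proportion treated as real in this analysis (0.05) and
the typical sampling noise of genuine components, and an order of magnitude
above the stall level.  Consequence: proportions below 0.5% are reported as
exactly 0.

## Bootstrap standard errors

Replicates resample M markers with replacement — implemented as multinomial
column weights, which yields the identical likelihood (and hence identical
EM iterates) to physically duplicating columns while letting all B
replicates run as one batched, weighted EM.  Each replicate starts from the
point estimate: by concavity the start does not change the optimum, and the
support of the start is preserved (boundary absorbing), so the batched fit
runs on the point estimate's support only.  `se_k` is the sample standard
deviation (denominator B−1) of replicate `q_k`.  Replicate r of individual
i draws from a stream seeded by `(seed, crc32(i), r)`, so results are
bit-reproducible and independent of execution order; all-missing resamples
are redrawn, capped at 10·B draws.  The convergence check in the batched
fit is evaluated every 4 iterations with the threshold scaled accordingly
(the log evaluation costs as much as the EM step itself).

Default B = 200.

## Sample aggregation

Per ancestry, individuals within a sample are combined by random-effects
inverse-variance weighting.  The between-individual variance τ² is the
DerSimonian–Laird moment estimator (with fixed-effect weights `w_i =
1/se_i²`, `Q = Σ w_i (x_i − x̄)²`, `τ² = max(0, (Q − (n−1)) / (Σw −
Σw²/Σw))`); combination weights are `1/(se_i² + τ²)`.  A single individual
passes through unchanged; a zero `se_i` with n > 1 is floored at 1e-6 with
a warning (an ancestry at exactly 0 in every individual is combined to 0
directly).  Sparsification: ancestry k is kept iff `mean_k − z·se_k > 0`
with `z = Φ⁻¹(0.975) ≈ 1.9600`; survivors are renormalized to sum to 1.
CIs are not truncated to [0,1] — only the lower bound against 0 matters.
No multiple-testing correction is applied, matching the plain per-ancestry
95% rule the analysis defines.  If nothing survives, the largest mean is
retained at 1.0 with a warning.

Group-level summaries are size-weighted means of sample profiles,
renormalized.  This convention is deliberate and documented: the published
group means in the source narrative are *not* the size-weighted averages of
the published per-sample table (e.g. the hunter-gatherer Northern European
mean comes out ≈ 63.8% by size weighting vs. 71.6% as printed), and the
original weighting is not recoverable.  Group summaries are therefore a
convenience, not a reproduction target; the printed ratio statistics, which
do reproduce, are taken from the printed group means themselves.

## Haplogroup composition

Lineage counts are tabulated by plain, case-sensitive string-prefix
matching — not phylogenetic containment.  This is the rule that reproduces
every published percentage, including `HV` counting under `H` and `R1`
under `R`; `K(xLT)` is an opaque label matching prefix `K` (the
parenthetical exclusion is not parsed).  Samples with no haplogroup data
are represented by absent records and contribute nothing to totals.
Sample names recur across period groups, so sample selectors are applied
within group selectors.

## Marker harmonization

Panels and VCFs are intersected on (chrom, pos).  If the VCF REF/ALT pair
equals the panel's (other, counted) pair the ALT dosage is kept; if it is
the swap, the dosage is complemented (2−g); strand-ambiguous pairs (A/T,
C/G) are dropped outright — the analysis cannot distinguish a strand flip
from an allele swap for them, and silent polarity errors are worse than
losing markers; any other allele combination is dropped as a mismatch.
All four categories are tallied and the tallies sum to the intersection
size.  Multi-allelic VCF records are skipped with a warning (the panel is
biallelic by construction).  An individual whose non-missing calls are all
haploid is auto-flagged pseudo-haploid (overridable).

## Synthetic data

The generator emulates the structure the model assumes, with the emulated
panel's dimensions as defaults (K = 21 ancestries, M = 19,075 SNPs):

* **Panel**: per marker an ancestral frequency uniform on [0.05, 0.95]
  (bounded away from fixation so every marker is informative), then one
  Balding–Nichols draw `Beta(p(1−F)/F, (1−p)(1−F)/F)` per ancestry.
  F_ST defaults to 0.1, the scale of continental human differentiation.
* **Individuals**: `q` rows Dirichlet(α) (default α = 1), or a sparse prior
  (fixed-size random support, Dirichlet on the support, redrawn until every
  supported component ≥ 0.05, so "present" ancestries are separated from
  zero).  Diploid dosages Binomial(2, qᵀp); pseudo-haploid individuals emit
  one Bernoulli(qᵀp) allele coded {0, 2}.
* **Studies**: each sample draws one true profile shared by its individuals
  (samples are modelled as ancestrally homogeneous groups), written out as
  panel TSV + VCF + sample map + truth table, bit-reproducible per seed.

What it does **not** emulate: linkage disequilibrium (markers independent,
as the likelihood assumes), post-mortem damage or reference bias (missing
data are marker-i.i.d., i.e. missing-at-random), genotype-calling error,
and drift between ancient individuals and the present-day panel
frequencies.  Passing the simulation benchmarks therefore demonstrates
correctness of the estimator under its own model, not robustness to those
real-data violations.

## Validation sizes

Chosen once, as the package's own benchmark design:

* EM vs. grid search: 20 two-ancestry instances, M = 50, grid step 0.001;
  the EM runs at `tol = 1e-12` here because tiny-M likelihoods are nearly
  flat near the optimum — the check probes the optimizer, not the
  production stopping rule (which targets M ≈ 10⁴, where the issue is
  absent).
* Parameter recovery: 50 individuals, K = 5, M = 20,000, F_ST = 0.1,
  20% missingness; RMSE threshold 0.05.
* Bootstrap coverage: 200 individuals, K = 3, M = 2,000, B = 100,
  interior truths (Dirichlet α = 5); nominal 95%, accepted band 90–99%.
* Sparse-support recovery: 20 studies, K = 21 with 4-ancestry truth
  (components ≥ 0.05), 10 individuals per sample, M = 8,000, B = 50,
  20% missingness; exact support match required in ≥ 90% of runs.  At this
  M the per-individual bootstrap SEs (~0.01–0.02) already separate the
  smallest real components from zero, and the inverse-variance combination
  tightens them further by ~√10.

## Known limitations

* Bootstrap SEs inherit the point estimate's support: an ancestry snapped
  to zero has se = 0 by construction, so its absence is asserted by the
  snap rule, not by the interval.
* The normal-approximation CI is poor for components near the boundary;
  coverage is only claimed (and tested) for interior truths.
* Group summaries use size weighting (see above) and are not comparable to
  the published group means.
* No liftover, imputation, BAM processing, haplogroup calling, or
  unsupervised mode.
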