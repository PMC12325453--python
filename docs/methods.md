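# Methods

`mtped` implements a covariance-structure model for detecting mitochondrial-DNA
(mtDNA) effects on quantitative traits in extended pedigrees, together with the
simulation machinery needed to study its statistical power and its bias under
pedigree misspecification.

## The model

For the `N` members of a pedigree the phenotype vector is modelled as zero-mean
multivariate normal with covariance

```
Cov(p) = a2·A + i2·I_AA + mt2·M + j2·J + cF2·C_F + cE2·C_E + e2·E
```

where the uppercase matrices are fixed functions of the pedigree and the
squared lowercase coefficients are standardized variance components:

| matrix | pattern | component |
|---|---|---|
| `A` | additive nuclear relatedness, 2× the kinship coefficient from the classic recursion (founders unrelated, no inbreeding, so `diag(A)=1`) | `a2` |
| `I_AA` | additive-by-additive epistasis, elementwise `A²` | `i2` |
| `M` | matriline sharing indicator: 1 iff two members descend from the same founding female through an unbroken chain of mother links (males carry, but do not transmit, their matriline) | `mt2` |
| `J` | nuclear-mitochondrial interaction, elementwise `A∘M` | `j2` |
| `C_F` | nuclear-family environment: full siblings (same recorded mother **and** father) plus the diagonal | `cF2` |
| `C_E` | extended-family environment: 1 within each connected component of the family graph (parent-child, co-parent, and recorded-mate edges) | `cE2` |
| `E` | identity | `e2` |

Distinct pedigrees are independent, so the pooled likelihood is block-diagonal.

Identification of `mt2` against `cF2`/`cE2` rests on the pedigree containing
pairs that share a matriline at different nuclear distances (e.g. maternal
cousins vs. maternal siblings) and pairs at the same nuclear distance with and
without matriline sharing (children of sisters vs. children of brothers).

Assumptions: random mating (married-in mates are unrelated founders), no
inbreeding, no twins or remarriage, error-free kinship records, mutation-free
mtDNA transmission, a continuous standardized trait with zero mean, and equal
environments across the patterns captured by `C_F`/`C_E`. The bias module
exists precisely to quantify what happens when the record-accuracy and
mutation-free assumptions fail.

### Choices for `C_F` and `C_E`

The `C_F` rule is read literally: members "share the nuclear family" when they
have the same two recorded parents, which excludes parent-offspring pairs and
half-siblings. An `include_parents` flag widens the household to the parents
(off by default). `C_E` is defined on connected components of the family
graph rather than on pedigree membership so that severing a branch's parent
links renders it unrelated *in every matrix* — the behaviour the
missing-link experiment manipulates. Mate edges keep childless couples inside
the family component; file-read pedigrees without an explicit mate record
recover couples from co-parenthood only.

## Pedigree simulation

A pedigree is parameterised by depth `G` (generations), width `k` (mean
offspring per couple), male newborn share `p`, and reproductive rate `r`
(share of each non-final generation's bloodline that mates, always with a new
married-in founder of the opposite sex). Generation 1 is a single mated
couple; generation `G` never mates. The expected generation sizes are

```
m_1 = 2,   m_g = k^(g-1) r^(g-2) (1+r)  (2 ≤ g ≤ G-1),   m_G = k^(G-1) r^(G-2)
```

and the expected pedigree size is the sum of per-generation ceilings, chosen
because it reproduces the canonical design sizes exactly
(33, 61, 344, 657 for the power designs; 161 for the bias design).

Two size modes:

* `expected` — per-generation counts equal those ceilings exactly
  (bloodline children `ceil(k^(g-1) r^(g-2))`, married-in mates the
  remainder). Used when a fixed per-pedigree `n` is required, as in the bias
  experiments (124 pedigrees × 161 = 19,964 per replicate).
* `poisson` — each couple's offspring count is Poisson(`k`); `round(r·children)`
  members of each non-final generation mate. Used for the power analyses.
  Pedigrees that fail to populate all `G` generations are resampled (at most
  100 attempts, then an error). This conditioning, plus flooring the mater
  count at one, pushes the mean simulated size a few percent above the
  closed-form total (≈34.7 vs 33 for the small design) — an intrinsic property
  of the stated mechanism, not a calibration target.

Newborn sex is Bernoulli(`p`); identifiers are deterministic given the seed
(generation order, then birth order). Samples are pooled by simulating
independent pedigrees until a target `N` is reached.

## Estimation

The engine groups pedigree blocks by size and evaluates the pooled
`-2 log L` with batched Cholesky factorisations, plus its analytic gradient

```
∂(-2logL)/∂c_k = Σ_f [ tr(Σ_f⁻¹ K_fk) − y_f' Σ_f⁻¹ K_fk Σ_f⁻¹ y_f ]
```

(the model is linear in the components, so no chain rule is needed).
Minimisation uses unbounded L-BFGS-B (relative function tolerance 1e-9) —
estimates may go negative by design, which keeps the likelihood-ratio test's
central/noncentral χ² reference valid without boundary corrections and
reproduces the slightly negative mean null-model estimates. Covariances that
leave the positive-definite cone during a line search return a large finite
penalty sloped along the most negative eigenvalue.

Starts are deterministic: (1) a Haseman–Elston-type least-squares regression
of the phenotype cross-products `y y'` on the component matrices — a
consistent moment estimator, so at experiment sample sizes the optimizer
starts near the optimum; (2) an equal split of the phenotypic variance;
(3) a blend of the two. `fit()` tries all three by default; the experiment
drivers use the HE start alone (`n_starts=1`) because the objective proved
unimodal across all conditions tested and the single start never changed the
optimum, at a third of the cost. The mean structure is fixed at zero
(simulated data are zero-mean); an optional pooled demeaning is available for
external data and cancels in the LRT.

Standard errors are deliberately not reported: inference is by the
likelihood-ratio test, matching the study design. `fit()` reports
convergence, function-evaluation counts and `-2 log L`; `summary()` prints a
small table.

## Power analysis

The mtDNA hypothesis is the joint test of `mt2` and `j2` (df = 2). The unit
statistic

```
T = ( [-2logL(H0)] − [-2logL(H1)] ) / N
```

is averaged over Monte-Carlo replicates (the orientation makes `T ≥ 0`;
the raw difference of the two fits is negative). Power at a target size `N'`
uses the noncentral χ²: `λ = (N'−1)·T`, `power = P(χ²_2(λ) > χ²_{2,1−α}(0))`,
and the required `N` inverts this by bisection on `λ` (reported as the
smallest integer whose power reaches the target). `α = 0.05` throughout.

Replicates use ~10,000 individuals each. This size matters beyond precision:
the finite-sample expectation of the LRT depends on the per-replicate sample
size (under the null it is visibly inflated below a few thousand
individuals — mean ≈4.2 at N=330 vs the asymptotic 2.0, recovered by
N=4,000), so the per-replicate size is part of the estimator's definition.
The reference size of 10,000 is therefore kept even in scaled-down runs;
only the replicate count is reduced. Calibration checks against the χ²
reference run at N ≥ 3,300 for the same reason.

## Misspecification experiments

All bias experiments use the fixed design `k=3, G=5, r=1` (161 members, 124
pedigrees per replicate, N = 19,964) and the truth
`a2=.40, i2=0, mt2=.05, j2=.01, cF2=.10, cE2=.10, e2=.34`; the null
experiment sets `mt2=j2=0` (`e2=.40`). In each pedigree one second-generation
bloodline female with children is selected uniformly (pedigrees without one —
probability 1/8 at `k=3` — are resampled), and the misspecification enters
the *data-generating* matrices while the misspecified analyst fits the
intact-pedigree matrices:

* **mutation** — the selected female carries a germline mtDNA mutation: she
  and her matrilineal descendants form a new haplotype class (M = 0 even to
  her own mother and siblings). Data are generated with the mutation-aware
  `M` and `J = A∘M`; the misspecified fit uses the intact `M`/`J`.
* **missing link** — the selected female's links to both parents are deleted
  and *all* data-generating matrices are rebuilt from the broken pedigree
  (her branch is truly a separate family); the misspecified fit assumes the
  intact pedigree.

The direction matters: fitting broken matrices to intact-pedigree data leaves
the estimates unbiased, because the broken model is block-separable and
maximum likelihood simply never sees the unmodelled cross-branch covariance.
Only when the fitted matrices claim relatedness that the data lack does the
mtDNA variance get redistributed (mt2 down roughly 40%, j2 up several-fold) —
the regime these experiments are designed to quantify. Both experiments use the same perturbed `M`; they differ in whether the
nuclear and environmental matrices are perturbed too.

The closed-form mutation module documents why the mutation scenario is
plausible: at 2.7e-7 mutations per site per generation over ≈17 kb,
one germline mutation is expected per ≈218 transmissions.

## What the simulations do and do not show

The generator emulates the study conditions: single-founder-couple pedigrees
of fixed depth, random mating with unrelated spouses, a 1:1 newborn sex
ratio, fully standardized zero-mean Gaussian traits, and complete phenotype
records. Real pedigree data differ in ways the model does not emulate —
variable-depth family structures, missingness in phenotypes and links, twins,
consanguinity, assortative mating, cohort effects, and non-Gaussian or binary
traits. Passing tests therefore certify the estimator's behaviour under the
stated design, not performance on empirical cohorts.

## Problem sizes and numerical choices

Monte-Carlo protocols are desk-scaled versions of the study protocols (which
used 100 replicates of 10,000 individuals for power and 500/200 replicates
for bias/null). The package defaults keep the study sizes; tests and the
acceptance script use: 30 replicates (k=3) and 20 replicates (k=8) of 10,000
individuals for the power conditions; 50 script replicates (25/15 in the
test suite) for the bias scenarios; 50 script / 32 test replicates for the
null experiment; 500 replicates of N=4,000 for the χ² calibration; 14
replicates at N=19,964 for parameter recovery. These sizes were chosen so the full suite completes on a
single CPU while keeping Monte-Carlo standard errors inside the published
tolerances. The deep-pedigree power condition (`k=3, G=8`) is not given a
tolerance-grade run in the suite: its 657-member blocks make an adequately
replicated check disproportionately expensive, and an underpowered check
would be noise.

A structural note on pedigree shape: in this model the per-individual
noncentrality `T` of the joint mtDNA test **increases with both depth and
width** of the pedigree (for the main-condition truth, the asymptotic
required N at 80% power is ≈5,125 for `k=3, G=4`, ≈4,780 for `k=4`, ≈4,300
for `k=8`, and ≈3,700 for `k=3, G=8`). The width direction was verified two
ways — Monte-Carlo fitting and a deterministic asymptotic computation of
the noncentrality from expected log-likelihoods — and is what the trend
test asserts. Wider pedigrees contain more informative kin pairs per member
(maternal vs. paternal avuncular and cousin contrasts), even though each
pair is individually less informative than the long-range pairs of deep
pedigrees.

Numerical details: per-generation ceilings use a 1e-9 slack against floating
point; Cholesky failures during optimisation return a 1e10-scale penalty;
LRT statistics are clipped at zero; required-N values are ceiling integers;
per-pedigree random substreams come from `numpy.random.SeedSequence.spawn`,
so results are reproducible and independent of evaluation order.

## Known limitations

* Binary/liability traits, multivariate traits, assortative mating, twins,
  consanguinity, pedigree collapse and cohort effects are out of scope.
* The fitter reports point estimates and LRTs only (no SEs/REML/Bayes).
* `C_E` for file-read pedigrees cannot recover childless couples without an
  explicit mate record.
* Poisson-mode pedigree sizes are conditioned on reaching all `G`
  generations, so their mean exceeds the closed-form expectation by a few
  percent for small designs.
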