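# Methods

`crossplan` compares *cross-selection criteria* (CSC) for inbred line
breeding: given a panel of candidate parents with genomic data, which
crosses should be made, and how many progeny should each receive, to
maximize the value of the best progeny while keeping the breeding
population diverse? This note records the models, the numerical choices,
and the limits of what the synthetic experiments can show.

## Progeny distribution model

For a biparental cross between inbred parents i and j, the breeding value
of an F5 recombinant inbred line (RIL — four generations of single-seed
descent selfing after the F1) is treated as Gaussian with mean

    PM_ij = (alpha_i + alpha_j) / 2

(the parental mean of genetic values) and variance given by a quadratic
form over the loci that segregate in the cross:

    sigma2_ij = d' K d,      d_l = (x_l^i - x_l^j) / 2  in {-1, 0, +1}
    K_kl = beta_k * beta_l * C(r_kl)

where beta are additive allele effects, r_kl is the recombination fraction
between loci k and l (Haldane mapping function, r = (1 - exp(-2d))/2 for
map distance d in morgans), and C(r) is the dose covariance between two
segregating coupling-phase loci in the final generation. The sign pattern
of d encodes linkage phase: coupling pairs contribute positively,
repulsion pairs negatively.

### The two-locus selfing recursion

C(r) is computed exactly by propagating the joint two-locus diplotype
distribution from the F1 double heterozygote through n rounds of selfing
(two independent gametes per individual per round) and taking the dose
covariance of the final generation. Anchor values:

* C(0) = 15/16 for four selfings — perfectly linked loci cosegregate, and
  the residual heterozygosity of (1/2)^4 leaves a per-locus dose variance
  of 15/16 rather than 1;
* C(r) -> (1 - 2r)/(1 + 2r) as the number of selfings grows
  (Haldane–Waddington limit), with C(0) = 1 at complete inbreeding;
* C(1/2) = 0 exactly: for unlinked loci the joint diplotype distribution
  factorizes under selfing from an F1, so loci on different chromosomes
  contribute nothing to the covariance term. The cross-chromosome
  correction is still wired through the code as a rank-one term per cross,
  but it vanishes identically for the F1-derived populations modeled here.

Closed-form renderings of the F5 variance bracket in the literature are
easy to typeset wrongly; the recursion is the package's source of truth
and is validated against Monte-Carlo meiosis (the simulator and the
recursion share no code path). C(r) is a polynomial in r of degree at most
2n, so batched kernel construction evaluates an exact polynomial fit of
the recursion rather than re-running it per locus pair.

Two diagonal conventions are provided. The default (`mode="f5"`) uses the
finite-selfing recursion everywhere, so analytic variances match simulated
F5 families including their residual heterozygosity. `mode="f_inf"` uses
the complete-inbreeding limit (diagonal 4 * sum beta^2 p(1-p) with
p in {0, 1/2}), the convention most published formulas print.

### Batched evaluation

For a panel of n parents all n(n-1)/2 crosses are scored at once via
sigma2_ij = (A_ii + A_jj - 2 A_ij)/4 with A = X K X' accumulated per
chromosome — one matrix product per chromosome instead of one quadratic
form per cross. 835 parents give 348,195 candidate crosses; the batch path
handles that size directly.

## Cross-selection criteria

All seven criteria score the N(PM, sigma^2) progeny distribution:

* **PM** — the expected progeny mean itself.
* **UC1, UC2** — usefulness criteria PM + i_q * sigma at q = 7% and
  q = 0.01%; i_q = phi(z_q)/q is the selection intensity (inverse Mills
  ratio), 1.918 at 7% and 3.958 at 0.01%. The heritability factor h in
  UC = PM + i*h*sigma defaults to 1 (genomic values are used directly) and
  is exposed as a parameter.
* **EMBV** — expected maximum among the D progeny allocated to the cross,
  PM + INT_{1/D} * sigma with Burrows' order-statistic approximation
  INT = i_{1/D} - (D-1)/(2(D+1) i_{1/D}); INT(1) = 0.
* **PROBA** — probability that one progeny exceeds a threshold lambda
  (default: the best parental genetic value). The design objective
  minimizes sum D_ij log(1 - q_ij), the log-probability that no progeny
  exceeds lambda. Tail probabilities are clamped to [1e-12, 1 - 1e-12]
  to keep the logarithm finite; thresholds far outside the progeny
  distributions make the criterion non-discriminating, so lambda should
  sit within the parental range.
* **UC3** — design-level usefulness: the expected mean of the top q
  fraction of the *whole* design's progeny under a common threshold s_q
  solved from sum D_ij q_ij(s) = q D (bisection to |error| <= 1e-6 D;
  the left side is continuous and strictly decreasing whenever any family
  has sigma > 0). Degenerate all-sigma-zero designs are handled by direct
  enumeration of family means, with a warning.
* **OHV** — optimal haploid value 2 * sum_b max(beta_b^i, beta_b^j) over
  genomic blocks, three per chromosome (two arms and a centromere).
  Synthetic maps without explicit centromere annotations label the middle
  20% of each chromosome as the centromere block.

## Mating-design optimization

A design allocates integer progeny counts D_ij to crosses under breeder
constraints: total progeny (C1, default 3,300), progeny per cross (C2,
5–60), number of crosses (C3, 200–300), progeny per parent (C4, <= 250),
number of parents (C5, 100–132), and exclusion of crosses between parents
above the 99% quantile of pairwise LD-weighted genomic covariance (C6,
removing ~1% of candidates). Candidate lists are pre-filtered to the 10%
highest-PM crosses.

Linear criteria (PM, UC1, UC2, OHV, PROBA) are solved exactly as a
mixed-integer program — variables D_ij, cross-use indicators y_ij and
parent-use indicators z_i — with the HiGHS branch-and-bound solver to a
relative gap of 1e-4. Unconstrained ("NO CONSTRAINT", C1 + C2 only)
designs use the closed-form greedy rule: the top D_total/D_max crosses by
criterion value receive D_max progeny each (3,300 at 60/cross = 55
crosses).

EMBV and UC3 change value with the allocation itself, so they are
optimized by a genetic algorithm over allocation vectors: population 100,
half seeded from linear-programming solutions of a related criterion (UC1
seeds EMBV; PROBA seeds UC3) and half from repaired random allocations;
tournament selection on sharing-adjusted fitness (fitness divided by the
count of members within Hamming radius 0, i.e. exact duplicates — two
candidate designs are "different" as soon as one D_ij differs); uniform
cross-exchange crossover; mutation that moves progeny between crosses;
and a feasibility repair after every operator that shifts progeny from
violating to slack crosses and drops the lowest-coefficient crosses when
counts must shrink. Elitism guarantees the returned design is at least as
good as the best seed; a fixed RNG seed makes runs reproducible. The
operator and repair details are this package's own design — several
reasonable variants exist; the tests pin behaviour (feasibility via an
independent validator, seed dominance, brute-force optimality on tiny
instances in >= 90% of seeds) rather than any particular operator.

## GBLUP and marker effects

Estimated-effects scenarios fit y = mu + a + e with a ~ N(0, G sigma2_a),
G = ZZ'/(2 sum p(1-p)) built from centered doses excluding QTL columns.
Restricted maximum likelihood is computed on the eigenbasis of G with mu
and sigma2_e profiled out and a bounded scalar search over log(lambda),
lambda = sigma2_a/sigma2_e — deterministic, no iterative average-
information updates; a grid check in the tests confirms the optimum.
Marker effects are backsolved as beta_hat = Z'G^{-1} u_hat / (2 sum
p(1-p)) (ridge jitter 1e-8 * mean diag before inversion), so the GEBV of
any genotype is its dose cross-product with beta_hat and Z beta_hat
reproduces u_hat in the full-rank case. With 0/2 dose coding the diagonal
of G is near 2, so the reported heritability is h2_hat = 2 sigma2_a /
var(y).

The LD-weighted relatedness matrix used by C6 is G2 = WW' with
W_l = w_l (Z_l - 2 p_l)/sqrt(p_l (1 - p_l)); per-SNP LD weights are
accepted as input (unit weights by default), not estimated. Some
published renderings print the denominator without the square root; the
square-root form is the standardization that gives unit-variance columns,
and the C6 quantile filter is invariant to the convention.

## Synthetic study conditions

The generator's defaults are the full-scale study conditions: 835 inbred
founders, ~16k SNPs on 21 chromosomes, minimum MAF 0.10, 300 QTLs drawn
uniformly among the SNPs with i.i.d. N(0,1) effects and random favorable
allele, rescaled by a single scalar so the founder TBV variance is exactly
14 (quintal/ha)^2; phenotype noise variance 21 so h2 = 14/35 = 0.4.
"Selected" populations apply three cycles of truncation selection (300
random crosses among the top-300 TBV lines, 11 F5 RILs per cross, keeping
the best 1/1/3 progeny per cross over the cycles, yielding 900 lines from
which 835 are sampled); the cycles track haplotypes because cycle parents
are residually heterozygous RILs. All counts are configuration fields so
tests and examples run at desk scale (typically 40–220 founders, 90–600
loci); the methods are scale-free, and the problem sizes used in each
test are chosen to keep the statistical check sharp at that scale.

Founder LD comes from a distance-indexed Markov copy process (refresh
probability 1 - exp(-k d) per interval, k = 8 per morgan by default —
LD extending over tens of centimorgans, as in elite inbred panels) rather
than a coalescent or forward simulator: it is cheap, seedable, and
reproduces the two features downstream code consumes, a MAF floor and LD
decaying with map distance. It does *not* reproduce population structure,
pedigree relatedness, a historical genetic trend, mutation, or selection
footprints. Consequences worth knowing:

* the candidate crosses have a higher progeny-SD-to-mean variance ratio
  (t = var(sigma)/var(PM) around 0.2) than is typical of real elite
  panels, because an exchangeable panel lacks the multi-year genetic
  trend that spreads PM;
* estimation-accuracy comparisons conditioned on the top-10%-PM crosses
  are strongly affected by range restriction at desk scale: selecting on
  estimated PM compresses its spread and deflates cor(PM_hat, PM) below
  cor(sigma_hat, sigma) even when, over the full candidate set, PM is
  estimated much more accurately than sigma (which it is, consistently).
  The diagnostics therefore report both the subset and the full-set
  correlations, and the qualitative claim "sigma is harder to estimate
  than PM" is asserted on the full set.

Meiosis is Poisson with no interference (Haldane-consistent): crossover
counts per chromosome are Poisson(map length), positions uniform. The
batched simulator uses the equivalent interval-parity form — independent
strand switches with probability r(d) per inter-locus interval — which is
exact at the typed loci; the explicit-crossover reference implementation
is kept for crossover-count statistics, and the two are cross-checked on
realized recombination fractions.

## Evaluation

Designs are scored by simulating their full F5 progeny (20 replicates at
full scale; 2–3 in tests) and computing: relative gain of each criterion
over PM, (mean top-fraction TBV_CSC - TBV_PM)/(TBV_PM - mean parent TBV);
genic variance sum 4 beta^2 p(1-p) at QTL frequencies of the selected
progeny (the linkage-equilibrium diversity metric); the t-ratio
var(sigma)/var(PM) over top-PM crosses; accuracy correlations; parental
contribution shares (each progeny counted once per parent, shares summing
to one — a 4% best-parent share corresponds to the C4 cap of 250 out of
2 x 3,300 parent-slots); and Pareto fronts over (gain, diversity) points.
Progeny selection is always on true TBV. In scenario runs the GBLUP fit
is performed once per architecture and reused across constraint modes,
and the PM-vs-PM gain cell is exactly zero by construction.

Headline percentages from real elite panels depend on the panel itself
and are not reproduced here; the desk-scale experiments assert directions
and orderings — variance-aware criteria beat PM at strong (<= 1%) selection
under TRUE effects; contribution constraints raise the genic variance of
the selected progeny at some cost in gain, most strongly for PM; sigma is
estimated less accurately than PM.

## Known limitations

* Single trait, additive effects only; no epistasis, dominance, or GxE.
* One generation of mating-design evaluation; long-term gain is out of
  scope.
* The GA's operators are deliberately simple; on large instances it finds
  good, not certified-optimal, designs (the MILP bound from the seeding
  criterion gives a reference point).
* The REML fitter is single-kernel with an intercept-only fixed effect.
* VCF input expects fully homozygous biallelic records; imputation and
  multiallelic sites are out of scope.
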