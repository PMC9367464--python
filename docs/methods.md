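# Methods

This note documents the statistical models, numerical choices and design
decisions behind the package, and what the synthetic-data tests do and do not
establish about real data.

## Exact 2×2 inference

Conditioning a 2×2 case/control table on all four margins leaves one free
cell `A` whose law is Fisher's noncentral hypergeometric distribution with
odds-ratio parameter ψ. Three quantities are computed from that conditional
law (matching the conventions of the widely used R `fisher.test` output):

* **Two-sided p** — the sum of central (ψ = 1) hypergeometric probabilities
  of all tables with the same margins whose probability is at most that of
  the observed table; ties are resolved with a relative tolerance of 1e-7.
  Any zero margin gives p = 1.
* **Conditional MLE of ψ** — the root of the score equation E_ψ[A] = a,
  solved by Brent bracketing on log ψ (xtol 1e-8). `a` at the bottom/top of
  its support gives 0 / ∞; degenerate margins give NaN. The conditional MLE
  is slightly shrunk relative to the sample OR ad/bc (e.g. 13.00 vs 13.11
  for dam 1's table), which is exactly the behaviour of the printed tables.
* **Exact central CI** — ci_low solves P(A ≥ a | ψ) = (1−level)/2 and
  ci_high solves P(A ≤ a | ψ) = (1−level)/2, again by bracketed root
  finding; boundary cells give 0 / ∞ endpoints.

All conditional probabilities are evaluated in log space (`gammaln` +
`logsumexp`), so tables as unbalanced as 17/17 vs 44/577 are exact to
machine precision. Display rounding follows the "rule of four" for ratios:
two significant digits when the leading digit is 4–9, three when it is 1–3
(hence 13.0, 2.94, 0.275 but 4.9, 0.45, 96); machine outputs always retain
full precision alongside.

Risk labels are a pure function of the pair (OR, p): *high* iff OR > 1 and
p < 0.05, with p exactly 0.05 classified low (strict inequality). The
per-parent tables exclude offspring born after the cutoff year (2019 by
default — the youngest affected animals in the source cattery were born that
year), and offspring of unknown status count as healthy controls, mirroring
how the phenotype ledger was compiled; a switch allows excluding them
instead for sensitivity analyses.

The confounding-adjusted model is an ordinary binomial GLM (logit link,
IRLS via statsmodels) with the sire factor (last sire as reference), the
binary high/low-risk dam variable and centered year of birth; nested models
are compared with the likelihood-ratio chi-square. Rank deficiency is
detected before fitting; quasi-complete separation is flagged on the fit.

## Pedigree algebra

The additive relationship matrix is built by Henderson's tabular method in
topological order; inbreeding is F_i = A_ii − 1, and the Mendelian sampling
standard deviation defaults to the decorrelated animal-model term

    s_i = sqrt(0.5 − 0.25 (F_sire + F_dam))        (two known parents)
          sqrt(0.75 − 0.25 F_parent)               (one known parent)
          1                                        (founder)

Unknown parents are treated as unrelated, non-inbred founders — the standard
BLUP convention; the output of the heritability stage is conditional on that
assumption, which matters only if the imported breeding animals' unrecorded
ancestors were in fact related. An alternative mode, `paper_literal`,
defines s_i = sqrt(A_ii) = sqrt(1 + F_i) — the square root of the
relationship-matrix diagonal. That reading keeps the *diagonal* language of
the source description but conflicts with the decorrelated parameterization
it cites (under it, z would not be standard normal a priori); the standard
term is therefore the default and the flag preserves the literal variant for
comparison. For non-inbred pedigrees with complete parentage the two differ
only in that the literal variant inflates s for inbred animals.

Topological sorting breaks ties by input order then id, so every derived
matrix is a deterministic function of the record *set*.

## The Bayesian logistic animal model

Phenotypes are Bernoulli on the logit scale with fixed effects (intercept,
centered year of birth, sex coded male = 1 / female = 0 / unknown = 0.5) plus
the breeding value a_i defined recursively as the parental average plus
σ_a·s_i·z_i with independent standard-normal gametic deviations z. This
non-centered (Mendelian-sampling) parameterization gives a the covariance
σ_a²·A while keeping the prior on z spherical. Priors: N(0, 4) on the three
regression coefficients, N(0, 1) on each z (the "residual"/gametic term),
and a configurable positive-truncated prior on σ_a with four shipped
presets — half-Cauchy(2.5), half-Cauchy(10), half-Normal(10), Uniform(0, 10)
— plus Uniform(0, 20) (two spellings of the uniform prior circulate for this
analysis; both are available, the (0, 10) version is in the default
four-prior set). Heritability is h² = σ_a²/(σ_a² + 1) with the binary-trait
residual variance fixed at 1; a `residual_variance` argument exposes the
logit-scale π²/3 convention for comparison.

Animals with genuinely unknown status are dropped from the likelihood but
kept in the recursion, so they still transmit breeding values.

### Sampler

Any kernel targeting the posterior is acceptable; the implemented reference
kernel is an adaptive random-walk Metropolis-within-Gibbs with all chains
advanced in lockstep as vectorized rows:

1. **Terminal animals' z** (no offspring): their updates are mutually
   independent given the rest, so proposal, likelihood delta and
   accept/reject are vectorized over all of them at once.
2. **Parents' z**: a change propagates to descendants with coefficients
   halved along each parent-offspring edge (precomputed sparse influence
   sets). Parents whose descendant sets are pairwise disjoint are grouped by
   greedy coloring and each group updated in one vectorized sweep — in a
   cattery the dams form one group and the sires another.
3. **Regression block** β as a joint 3-dimensional random walk.
4. **log σ_a** random walk, alternated with an **ancillarity–sufficiency
   interweaving** move: σ_a′ = σ_a·e^ε, z′ = z·e^(−ε) leaves every breeding
   value (hence the likelihood) unchanged and is accepted on the priors plus
   the e^((1−n)ε) volume factor. This move walks along the ridge of the
   (σ_a, z) funnel that otherwise throttles mixing of the additive SD; the
   pair is repeated three times per sweep because σ_a is the slowest
   coordinate.

Proposal scales adapt by Robbins–Monro toward acceptance 0.44
(coordinatewise) and 0.234 (the β block) during burn-in only, so the
post-burn-in chain is a fixed-kernel Markov chain. Initialization: β ~
N(0, 0.1), σ_a ~ U(0.1, 2), z = 0, jittered per chain from chain-indexed
seed streams; a non-finite posterior at initialization is retried up to 100
times. Identical seed and configuration give bit-identical retained draws.

The default schedule is 4 chains × 60 000 iterations, the first half
discarded and every 30th retained (1 000 draws per chain). The test suite
and recovery studies use the same schedule scaled down tenfold
(6 000/3 000/30), which keeps a full four-prior analysis under a minute on
one CPU; at that length the worst-case Gelman–Rubin statistic across the
scalar parameters is typically 1.0–1.5, and the reported summaries pool all
chains.

Convergence is summarized by the classic potential scale reduction factor
sqrt(((n−1)/n·W + B/n)/W) on the retained draws; constant chains return 1
with a warning. Posterior summaries are the mean and the central interval
from linear-interpolation empirical quantiles; an upper bound that rounds to
1.00 is displayed as "to 1", matching the usual table style for a
boundary-hugging posterior.

### Validation and what it shows

The kernel was validated against an exact two-parameter quadrature posterior
(founders-only design, z marginalized by Gauss–Hermite quadrature): MCMC and
quadrature means of h² agree to ~0.01 with matching intervals. On
cattery-shaped cohorts the posterior of h² from ~800 binary records is
intrinsically wide; across 20 replicate cohorts at true h² ∈ {0.2, 0.5,
0.9}, the replicate-averaged posterior means land within ≈0.05 of the truth
and the 95% intervals cover the truth in ≈90% of replicates, but a *single*
dataset's posterior mean can sit 0.2–0.3 from the truth at intermediate h².
High reported heritabilities from one pedigree should be read with that
sampling variability in mind — the posterior interval, not the point
estimate, is the meaningful statement.

## GWAS stage

QC runs in the fixed order sample call rate → variant call rate → Mendelian
errors → MAF, with every threshold a strict inequality exactly as stated
(below 0.95, more than one error, below 0.05 — boundary values are
retained), and per-criterion removal counts recorded so alternative orders
are auditable. Mendelian errors use trio logic when both parents are
genotyped (offspring genotype incompatible with any gamete combination) and
duo logic otherwise (opposite homozygotes only); pairs with missing calls
contribute nothing, and the per-variant count pools all duos/trios. MAF is
computed from non-missing calls of the retained samples, after sample
exclusion. Samples without a phenotype label are kept for call-rate and MAF
computation but excluded from testing.

The association test is allelic: 2N allele counts per group, cases vs
controls, tested with the same exact machinery as the parent-risk stage.
Holm's step-down adjustment multiplies the k-th smallest p by (m − k + 1)
under a running maximum, capped at 1, with stable tie handling; the
genome-wide line is α/m. Because the exact test is discrete, null p-values
are *sub-uniform* (P(p ≤ t) ≤ t): QQ plots of small panels sag below the
diagonal by construction, and the calibration guarantee is one-sided. The
test suite checks exactly that — never anti-conservative, with a bounded
conservativeness gap — rather than literal uniformity.

Only text PED/MAP is read and written (lossless round trip; the additive
code counts the second allele observed at each variant). Chromosomes sort
in the feline karyotype order A1–F2, X, with a natural-order fallback for
other names.

## Synthetic cattery

`SimulationConfig` defaults emulate the study population: 3 sires weighted
0.59/0.27/0.14, 43 dams each with a primary sire (90% litter fidelity —
dams were usually mated to one specific sire), six-year breeding careers
inside 2002–2021, Poisson litter counts and sizes tuned to ~757 kittens,
baseline prevalence 0.081 on the logit intercept, σ_a = 4.9 (h² ≈ 0.96),
small year and sex effects (β_year = −0.02, β_sex = 0.3 — the direction and
rough size suggested by the reported summaries; the original coding is
unknown, so these signs are convention-dependent), and no underreporting by
default (an `underreporting` knob flips affected records to unknown for
robustness studies). Phenotypes for founders are drawn from the same
liability model, so occasionally affected dams arise naturally. Genotypes
are gene-dropped founder alleles (per-variant MAF uniform on [0.05, 0.5]),
Mendelian-consistent by construction, with configurable missingness; a
helper injects duo incompatibilities to exercise the QC filter, and another
picks a 14-case/10-control subset with parent links, mirroring the study's
GWAS design.

What the simulator does *not* emulate: linkage/LD structure (variants are
independent), age-dependent penetrance, infection phenocopies, shared litter
environment, or non-random mate choice by phenotype. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to those real-world violations.

The deterministic **margin ledger** is a pedigree whose per-dam and per-sire
case/control margins equal the published tables exactly (61 cases / 594
controls among 655 offspring born through 2019; 102 later healthy kittens
bring the totals to 61/757, and dams 2 and 3 are recorded affected so the
parental-phenotype cells are 13/58 and 48/699). The dam→sire assignment is
not published; the ledger uses one consistent assignment (dams 1–2 under
sire 1, as reported) that satisfies both tables simultaneously. Birth years
cycle deterministically (affected kittens over 2006–2019, healthy ones over
2002–2019, post-cutoff kittens 2020–2021), and 35 of the 61 affected cats
are male. Quantities that depend only on the margins — every odds ratio, CI,
p-value, label and prevalence cell — are therefore reproduced exactly;
quantities that depend on the unpublished fine structure (e.g. heritability
from this pedigree) are illustrative only.

## CLI

The `sequestra` command exposes the stages as subcommands (simulate,
parent-risk, heritability, gwas, report) over YAML config with dotted-key
overrides. Every run writes a JSON manifest (config snapshot, seed, package
version, SHA-256 of inputs, timestamp); machine-readable TSVs never mix
with logging, and re-running a subcommand on the same inputs and seed
reproduces byte-identical TSVs. Exit codes: 0 success, 2 usage/config
error, 3 data error.

## Known limitations

* The margin ledger fixes only table margins; its within-dam year/sex
  structure is an arbitrary deterministic fill.
* The animal model assumes a single additive variance component — no
  maternal-environment or litter random effects, no dominance; a shared
  early-litter environment would inflate h² here as in any animal model.
* The GWAS stage implements the plain allelic exact test without
  kinship/stratification correction (the MDS/PCA screening of the original
  workflow is out of scope), so it is appropriate for the small single-
  cattery design it mirrors, not for structured populations.
* Exact-test p-values are conservative at small sample sizes; with 14 cases
  and 10 controls the smallest attainable p is ~2e-6, which bounds the
  achievable genome-wide evidence regardless of effect size.
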