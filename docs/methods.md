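# Methods

This note documents the models, algorithms and design choices behind
`amfniche`, in the order the pipeline runs them.

## Synthetic study generator (`amfniche.synth`)

The generator emulates a three-trial soybean inoculation experiment in a
randomized complete block design (3 trials × 4 blocks × two P-fertilizer
levels × control/inoculated, 48 plots) plus one pure-culture sequencing
run of the inoculum.

**Reference sequences.** AM-fungal OTU references are 360-nt random
sequences descended from a common random ancestor with 15% of sites
substituted per OTU, so any two AM references sit near 73% identity —
far below the 95% assignment criterion — while a read with ≤1%
substitution error stays at ~99% identity to its own source. Outgroup
references are unrelated random sequences verified < 80% identical to
every AM reference. Divergence constraints are checked at generation time
and violations redrawn (bounded attempts, then an error). Real LSU-D2
sequences share conserved blocks that random sequences lack; the
classifier margin here is therefore cleaner than on real data, and
passing accuracy tests bound the aligner's bookkeeping, not its behaviour
on genuinely ambiguous taxa.

**Community composition.** Each trial gets its own indigenous base
composition (Dirichlet(0.5) over 22 OTUs); each plot draws its community
from a Dirichlet centred on the trial base (precision 200), giving
realistic between-plot variation and clear between-trial structure. In
inoculated plots the three inoculum OTUs jointly take a share

    s = logistic(a − b·ln(MPN) + ε),  a = −2.2, b = 0.85, ε ~ N(0, 0.25),

of the community, a decreasing function of the trial's indigenous
propagule density (MPN, propagules/mL soil; defaults 0.02, 0.025, 0.2 per
trial). At these defaults inoculated plots in the sparse-propagule trials
carry ~70–75% inoculum-type reads and the dense trial ~30%. Control plots
carry a constant 5% background of inoculum-type look-alikes; the
mechanism behind such background reads (indigenous look-alike genotypes
vs contamination) is left open, so the share is a plain parameter.

**Yields.** `yield = 3100 + 400·s·1[inoculated] + N(0, 60)` kg/ha — a
~10% response when the inoculum dominates, with block-scale noise. Soil
covariates (phosphate absorption coefficient, nitrate-N, exchangeable K,
available P) have trial-level means with plot-level jitter, so they are
realistic confounders without being exact linear combinations of trial.

**Reads.** Each sample draws `reads_per_sample` 220-nt read pairs from a
multinomial over the plot's true proportions; 5% of pairs come from
outgroup references and 2% are unalignable random sequence ("junk").
Substitution errors are Phred-consistent: each base is independently
"bad" with probability `2e` (where `e` is the configured error rate),
bad bases carry Q3 (error probability 0.5) and good bases Q40, so the
marginal per-base error rate is exactly `e` and every quality score
states its base's true error probability. This makes the QV-30 3'-trim
rule exercisable while keeping the simple i.i.d.-substitution error
model. Chimeras, indels, primer-site bias and PCR template-amount bias
are deliberately not modelled.

**Dilution bioassays.** For each trial × block, pots at dilutions 2⁻¹,
2⁻³, 2⁻⁵, 2⁻⁷ (4 plants each, 20 mL assay soil) are positive with
probability `1 − exp(−λ·d·v)`; block-level λ varies lognormally (sd 0.15)
around the trial density.

Every output is a deterministic function of the config seed; independent
child generators per stage keep outputs order-independent.

## Read processing (`amfniche.readproc`)

The stated criteria are implemented natively rather than wrapping the
original external tools, so behaviour is pinned by this code base:
3' bases are removed until the terminal base has QV ≥ 30 (a plain scan,
not windowed — only the terminal rule is specified), a known 5' adapter
prefix is stripped, and mates shorter than 200 nt are rejected before
merging. Merging reverse-complements mate 2 and scans every ungapped
overlap in [10, 300] nt, choosing the fewest mismatches (ties → longest
overlap); consensus takes the higher-QV base (mate 1 on ties), and pairs
whose best overlap exceeds a 10% mismatch rate (configurable; unspecified
upstream) are rejected. Gapped merging is unnecessary for a fixed-locus
amplicon; indel handling is deferred to the alignment stage.

## Classification (`amfniche.classify`)

`align_read` is a full Smith–Waterman local alignment with affine gaps
(match +2, mismatch −3, gap open 5, gap extend 2), run on both strands;
identity is matches / alignment columns including gaps, and
E = K·m·n·exp(−λS) with K = 0.41, λ = 0.625 and n the searched group's
total reference length, evaluated in log space. "E ≤ −100" shorthand is
read as E ≤ 1e−100 (an E-value cannot be negative). Acceptance of the
best hit (highest score, ties by E-value then lexicographic id) requires
all of E ≤ 1e−100, identity ≥ 0.95, and alignment length ≥ 330 bp for AM
references or ≥ 220 bp for outgroup references; an AM best hit failing
the criteria is reported `unassigned_AM_fail`, an outgroup one `no_hit`.
Accepted outgroup reads are tallied in QC and excluded from the AM table.

For throughput, `assign_read` screens candidate references with an
edit-distance prefilter (edlib, infix mode, distance cap at 35% of the
read length, candidates kept within +8 of the minimum) before exact
scoring; `exhaustive=True` scores every reference. The exact kernel is
the component verified against a brute-force dynamic-programming oracle.

Normalization realizes "N reads per sample" as rarefaction — sampling
without replacement via multivariate hypergeometric draws — which keeps
integer counts and known sampling properties; proportional scaling is
available by using shares directly. Samples below depth are dropped with
a warning.

## Tracking (`amfniche.tracking`)

The inoculum OTU set is every OTU with share > `min_share` (default 0,
i.e. any detected read) in the pure-culture sample. Tracked abundance is
the plain sum of the set's reads in each rarefied sample; inoculum-origin
and indigenous reads of the same OTU cannot be discriminated, so the
combined signal is reported, and the same set is excluded from the
indigenous-community indices.

## Ecological statistics (`amfniche.ecostats`)

*Yield response* matches controls within trial × P level (configurable to
trial-wide); a zero control mean raises.

*Commonness* uses control plots only: trial means per OTU, shares
P_ij normalized over trials, C = 1/ΣP². OTUs under the 0.2%
mean-relative-abundance rare filter and the inoculum set are excluded;
all-zero OTUs are dropped and reported. *Robustness* is the per-trial
inoculated/control mean ratio, NaN-flagged (never silently zero) when the
control mean is zero. The rare filter is applied to both indices for a
consistent OTU universe (flag to disable).

*PERMANOVA* partitions the Gower-centred squared-distance matrix with
sequential (Type I) sums of squares, terms ordered trial, inoculation,
interaction (order configurable — it must be fixed for determinism).
Sample labels are permuted freely; within-block restriction was judged
unnecessary for the calibration tests but the permutation scheme is a
seam for extension. p = (1 + #{F* ≥ F}) / (1 + n_perm); an exhaustive
mode enumerates all n! permutations for exact small-sample p-values.

*Log transforms* use natural log with a 0.5 pseudo-count added only when
zeros are present (base and zero-handling are otherwise arbitrary).

*Stepwise OLS* searches bidirectionally from the full model, applying the
single add/drop that most lowers AIC until none does; collinear columns
are dropped greedily with a warning. Standardized partial regression
coefficients come from refitting the selected model on z-scored response
and predictors. The search never returns a model with higher AIC than
the full or null model (tested).

*Binomial GLMM*: tracked reads out of the rarefaction depth are modelled
as binomial with a logit link, fixed covariates and a Gaussian random
intercept per block. The marginal likelihood integrates the random
effect by adaptive Gauss–Hermite quadrature (21 nodes centred at each
block's conditional mode, scaled by the conditional curvature from an
inner Newton iteration) and is maximized by L-BFGS over (β, log σ).
Non-adaptive quadrature is inadequate here: with thousands of binomial
trials per plot the integrand is far narrower than the random-effect
prior. At σ fixed to 0 the fit reproduces a plain binomial GLM to 1e−6
(tested against an independent IRLS oracle), and estimates, standard
errors (inverse numerical Hessian) and the random-effect sd match lme4's
adaptive-GQ `glmer` on shared data. Modelling read counts as binomial
pseudo-replicates understates plot-level overdispersion; the random
intercept absorbs block-level spread, and odds ratios are exp(β).

## MPN estimation (`amfniche.mpn`)

Maximum likelihood under the Poisson single-propagule model rather than
classical lookup tables: the log-likelihood is unimodal in λ, maximized
by bounded search on log λ in [1e−8, 1e4] propagules/mL, with a 95%
profile-likelihood CI (drop of 1.92). All-negative series return 0 with a
one-sided upper bound; all-positive series return an infinite point
estimate flagged with a finite profile lower bound. Densities are per mL
of soil with an explicit mL-per-gram conversion helper; the assay soil
volume is a required input, never defaulted. Batch summaries report the
arithmetic mean ± SE of block-level estimates per trial.

## Pipeline and sizes (`amfniche.pipeline`)

A single seed fans out to per-stage child seeds through fixed
SeedSequence derivations, and no artifact embeds wall-clock state, so
rerunning a config is byte-identical. The demo study uses 800 read pairs
per sample and a rarefaction depth of 500 — chosen so a full end-to-end
run (49 samples through trimming, merging and exact alignment) completes
in about 1–2 minutes on one CPU while leaving >100 AM reads of headroom
above the depth; production-scale depths (10,000) are the pipeline
default. The classifier accuracy checks use 5,000-read samples over 25
OTUs.

## Known limitations

* Reference divergence is idealized; real communities contain OTU pairs
  near the 95% identity boundary where assignment is genuinely ambiguous.
* The error model is substitution-only; indel-rich platforms would need
  the merge and alignment parameters revisited.
* PERMANOVA permutes labels freely; block-restricted permutation is not
  implemented.
* The GLMM supports a single random intercept (block); crossed or nested
  random effects are out of scope.
* Yield responses in the generator are non-negative in expectation;
  yield depression by an introduced strain (as can occur in
  high-propagule sites) is not emulated.
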