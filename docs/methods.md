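# Methods

This note documents the simulation model, the estimation machinery, the
numerical choices, and what the desk-scale defaults do and do not show.

## Population simulation

**Genome.** 18 chromosomes of 100 cM, 3,100 equally spaced markers and 50
QTLs per chromosome (QTL positions uniform, distinct from markers).
Recombination is Haldane: crossover counts per chromosome are Poisson with
mean equal to the map length in Morgans, positions uniform, no
interference.  The recombination model is a modelling choice of this
package; it matches the default behaviour class of standard forward
simulators.

**Historical phase.** 200 male + 200 female founders with allele
frequencies initialised at 0.5, then 300 non-overlapping generations of
constant-size random mating (each offspring draws its father and mother
uniformly) to build linkage disequilibrium by drift.  Recurrent symmetric
mutation at 2.5e-5 per locus per meiosis is applied in this phase only, so
that the recent pedigree is exactly Mendelian.  Pure drift over t = 300
generations at Ne = 400 corresponds to diffusion time t/(2Ne) = 0.375 and
leaves roughly 80% of loci segregating, matching the intended study
conditions (~45,000 of 55,800 markers, ~730 of 900 QTLs).  Because the
single `scale` knob shrinks Ne and t together, this diffusion time — and
hence the segregating fraction — is preserved at desk scale.

**Recent pedigree.** A base population of 30 boars (random) plus all 200
sows from the last historical generation, then 8 non-overlapping
generations: 30 sires and 300 dams sampled at random from the alive
animals of the previous generation, each sire mated to 10 dams, one litter
per dam, litter sizes {10,12,14,16,18} with probabilities
{0.02,0.14,0.68,0.14,0.02} (mean 14.0), piglet sexes i.i.d. 1:1.
Generation 1 is bred from all base sows (the base has fewer females than
the 300-dam design); generations 2+ use the full design.

**Trait.** Direct and maternal QTL allele effects are drawn from a
bivariate normal with correlation r_am = 0.30.  TBVs are dosage-weighted
effect sums, centred and scaled **on the base population** so that the
realized variances equal the designed liability-scale values exactly
(population variance, ddof = 0); later generations drift freely.
Liability = own direct TBV + dam's maternal TBV + litter effect +
residual.  Three presets (direct h2 / maternal h2 / litter proportion):
T_4/4 = 0.04/0.04/0.04, T_2/4 = 0.02/0.04/0.04, T_2/2 = 0.02/0.02/0.02,
always with litter variance equal to maternal variance and r_am = 0.30.
The residual variance is fixed as sigma_e^2 = 1 - (s2_a + s2_m + s2_l);
the direct-maternal covariance is **not** added to this denominator (the
total liability variance is therefore slightly above 1; the convention is
configurable in `TraitArchitecture`).

**Survival.** Within each generation, exactly round(0.2 n) individuals
with the lowest liabilities are scored dead (ties broken by (liability,
id)).  Per-generation thresholding keeps the alive parent pool at exactly
80% of every cohort.  Base animals have no phenotype (no dam in the
pedigree); analysis uses the data of generations 5-8, with 5-7 as
reference and 8 as validation.

## Genotyping scenarios

Masks are drawn once per replicate over the analysis cohort (the
phenotyped piglets of generations 5-8): `G_all` genotypes all of them,
`G80_ran` a uniform random subset of the same size as the alive subset
(80% up to per-generation rounding), `G_alive` exactly the survivors,
`G_none` nobody.  Restricting genotyping to the phenotyped generations —
rather than all eight — keeps the genomic block tractable; earlier
generations contribute through the pedigree, and their genotypes would add
little information to a validation generation four meioses away.  All
scenarios and models within a replicate share the same pedigree,
phenotypes, TBVs and masks, so contrasts are paired.

## Relationship matrices

A is built by the tabular method (inbreeding included) and inverted
sparsely by Henderson's rules with inbreeding.  G follows VanRaden:
Z Z' / (2 sum p(1-p)), allele frequencies observed in the genotyped
subset, monomorphic markers dropped.  G* = beta G + alpha with (beta,
alpha) solving the two constraints Avg.diag(G*) = Avg.diag(A11) and
Avg.offdiag(G*) = Avg.offdiag(A11); G_w = (1-w) G* + w A11 with w = 0.2
(blending guarantees positive definiteness even when markers << animals).
H enters the mixed-model equations through its sparse inverse
H^-1 = A^-1 + [[G_w^-1 - A11^-1, 0], [0, 0]]; the dense block formula for
H is retained as a testing oracle and for the dense-REML experiment.  If
G_w is numerically singular, 1e-8 is added to its diagonal once (with
w = 0.2 this does not trigger at the scales used).

## Estimation

**Mixed-model equations.** Unknowns [mu | litter | a | m] with the 2x2
genetic covariance expanded over K^-1 (Kronecker form) and litter ridge
I/s2_l.  Systems up to 6,000 equations are solved by dense Cholesky;
larger ones by Jacobi-preconditioned conjugate gradients (relative
residual 1e-10).  The MME pedigree is pruned to the analysis cohort and
its ancestors; animals outside it carry no data and no descendants with
data, so their EBVs are recovered exactly afterwards as parent averages
(`extend_ebvs`), keeping EBVs indexed by every pedigree ID.

**Binary links.** Logit and probit models are fitted by penalised
quasi-likelihood: iterate working response z = eta + (y - mu)/mu'(eta) and
weights w = mu'(eta)^2 / (mu(1-mu)) through the weighted MME until the
relative change of the solution vector is below 1e-8 (max 50 iterations).
Complete separation is flagged and the intercept capped.  PQL is a
first-order approximation and is known to attenuate variance components
for binary data; it is used here as the standard working-variate approach
of animal-breeding software, and the model comparison (LM vs LG vs PM) is
read at the level of prediction accuracy, where the three links agree.

**AI-REML.** Variance components are estimated at observation level with
a dense phenotypic covariance V(theta) — exact gradients
-(tr(P Q_k) - y'P Q_k P y)/2 and average-information updates — which is
both simpler and faster than an MME-based implementation at n of a few
thousand.  Newton (AI) steps are damped 30% for the first 3 iterations,
then step-halved and Levenberg-Marquardt-damped towards the gradient
direction whenever a step would decrease the restricted likelihood or
leave the parameter space (variances floored at 1e-8 of var(y), |s_am|
clipped to 0.99 sqrt(s2_a s2_m)); this damped ladder plays the role of EM
fallback steps and keeps the likelihood monotone.  Convergence: change in
log-likelihood < 1e-6 and relative parameter change < 1e-6; standard
errors from the inverse AI matrix.  For LM all five components are free on
the observed scale.  For LG/PM the components are re-estimated on the link
scale from the converged PQL working variates with the residual structure
diag(1/w_i) fixed (canonical PQL, dispersion 1), alternating PQL fit and
REML update for 2 rounds; reported link-scale ratios use the conventional
residual pi^2/3 (logit) or 1 (probit).  Following the study protocol,
**EBV prediction in every scenario and model uses the pedigree-based
variance components** (REML under single-step models with selective
genotyping is biased — see below).

**Observed vs liability scale.** h2_obs = h2_liab * z^2/(p(1-p)), z the
standard normal density at the threshold; at 80% survival the factor is
0.49, so a liability h2 of 0.04 appears as ~0.020 on the observed scale.
The same factor applies to any liability variance ratio, which is how the
pedigree-REML recovery checks are scored.

## Validation

Accuracy = Pearson correlation of EBV with TBV over the validation
generation, separately for a, m and a+m.  Dispersion slope = OLS slope of
the whole-data (generations 5-8 phenotypes, `G_all` genotypes) EBV on the
reference-data EBV over validation individuals; computed within replicate
and averaged across replicates.  The whole-data fit is computed once per
(replicate, model) and reused for all scenario regressions.  Selection
differentials rank the validation generation on total EBV and report the
mean TBV of the top 1% (boar intensity) and 30% (sow intensity); ranking
within the validation generation is the default (a switch is not needed
for the desk runs).  Paired t-tests across replicates, without
multiplicity correction, generate compact letter displays at P < 0.05;
with a single replicate the letters are suppressed.

## Selective-genotyping REML experiment

As a qualitative companion result, `reml_selective_genotyping_contrast`
re-estimates variance components by AI-REML for a reduced linear model
(direct + litter effects) twice on the same data: with K = A and with
K = H built from survivor-only genotypes.  The survivor-only single-step
fit inflates the additive variance by orders of magnitude and pushes the
residual towards zero, while the pedigree fit stays on the right order —
the reason the pipeline never takes prediction variances from a
selectively genotyped genomic fit.

## Desk-scale defaults and what they show

The full design (scale 1.0: ~34,000 animals, ~27,000 genotyped, 40
replicates, three traits) reproduces the complete study but requires
many hours and ~10 GB for the dense genomic blocks; it is available by
setting `scale=1.0` explicitly.  Tests and the acceptance script run the
1/10 design: 2 chromosomes x (310 markers + 20 QTLs), Ne = 40 for 30
historical generations, 3 sires x 30 dams, ~420 piglets x 8 generations,
~1,700 phenotyped/genotypable animals, 5-10 replicates.  At this scale the
qualitative structure of the results is stable and reproducible: the
accuracy ordering G_all > G80_ran > G_alive > G_none for direct and total
EBVs, near-equality of G80_ran and G_alive for maternal EBVs, dispersion
slopes near 1, agreement of the three links, and the direction of the
REML recovery and inflation checks.  The absolute numbers are not those of
the full design: with 3 sire families and ~40 segregating QTLs,
accuracies are higher, their replicate spread is larger, and per-replicate
variance-component estimates frequently sit on a boundary (the mean across
replicates is the meaningful quantity).  The QTL count per chromosome is
deliberately floored at 20 when scaling down so the trait stays
polygenic; an oligogenic trait would change the selective-genotyping
contrast qualitatively.

Features of real pig data that the generator does not emulate: fixed
effects (herd-year-season), overlapping generations, selection on EBVs,
genotyping error and imputation, sex chromosomes, non-normal QTL effect
distributions.  Passing tests therefore demonstrate internal correctness
of the estimators and the direction/ordering of the design contrasts, not
calibration to any real population.

## Known limitations

* PQL link-scale variance components are approximations; their absolute
  values are convention-dependent (documented above), though prediction
  rankings are unaffected.
* Per-replicate AI-REML estimates at desk scale often hit the parameter
  floor (tiny true components, ~1,700 binary records); inference is meant
  to be read across replicates.
* The dense observation-level REML limits a single fit to n of a few
  thousand phenotypes; the full-scale design would need the MME-based
  trace machinery instead.
* `G80_ran` is sized to the survivor count (so the G80_ran/G_alive
  contrast is exactly size-matched), which can differ from round(0.8 n)
  by a couple of animals due to per-generation rounding of deaths.
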