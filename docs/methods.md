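# Methods

## The decay model

A founder mutation arises on one chromosome `G` generations ago. A marker at
recombination fraction `θ` from the locus still carries the founder's allele
on a descendant chromosome after `L` meioses with probability `(1−θ)^L`,
because a single crossover between marker and locus replaces the ancestral
allele with a population allele. With `p_d` the founder allele's frequency
among sampled disease chromosomes, `p_n` its control frequency and
`δ = (p_d − p_n)/(1 − p_n)` the LD-attributable excess, equating the
observed decay to its expectation gives the per-marker moment estimators

    ĝ_Risch   = ln δ  / ln(1 − θ)
    ĝ_Bergman = ln p_d / ln(1 − θ)

The Bergman-style estimator is shipped in two variants behind a stable enum:
`proportion` (`Q = p_d`, the default — no control correction, appropriate
when the founder allele is rare in controls) and `delta` (`Q = δ`, which
coincides with the Risch form). Published applications do not always state
which variant produced a given number; the enum keeps both inspectable.

Assumptions: a star genealogy (each sampled chromosome descends
independently from the founder over the full age — exact only in the limit
of very fast carrier growth), one effective breakpoint per side, marker
independence given the age, and correctly identified founder alleles. The
estimators are undefined (flagged non-informative, never silently computed)
when the founder allele is not enriched on disease chromosomes
(`p_d ≤ p_n`, i.e. `δ ≤ 0`) and when `θ = 0` (no recombination clock).

## Genetic map

Physical distances are converted at a constant regional rate (default
1.64 cM/Mb, overridable per run and per marker; a supplied genetic map takes
precedence) and map distances become recombination fractions through the
Kosambi function `θ = ½·tanh(2d)` (`d` in Morgans), which allows moderate
crossover interference. The inverse `d = ¼·ln((1+2θ)/(1−2θ))` round-trips to
~1e−12 relative error; `θ` is clamped strictly below ½ at the float
saturation point of `tanh` so downstream logarithms stay finite. The map
function is a pluggable callable wherever it is consumed; only Kosambi is
shipped.

## Conserved region and founder alleles

The conserved ancestral region is grown marker by marker from the locus
outwards on each side and stops at the first marker whose non-missing
disease calls disagree (at least two disease chromosomes required). Missing
calls never veto a marker: if all non-missing calls agree the marker extends
the region, flagged "partial support"; a marker with only missing calls
stops the scan. Outside the region the founder allele is the modal allele
among disease chromosomes; ties are broken toward the smallest label and
always warned (`FounderAlleleTieWarning`), since the printed tables this
rule mimics never report a tie. All frequencies are computed over
non-missing calls only.

The informativeness filter additionally drops, for the Risch-style
estimators, any marker whose founder-allele disease frequency equals that of
its neighbour nearer the locus on the same side (the distal marker adds no
recombination information — its δ decays only through its larger θ, so the
pair is redundant). Frequency equality is tested at 1e−12, adequate for
frequencies that are ratios of small counts. Study-specific exclusions that
no numeric rule captures are expressed as explicit per-marker overrides
(`--exclude-marker NAME:ESTIMATOR:REASON`), which are recorded in the
report with their reasons rather than applied silently.

## Growth correction

In a growing carrier population the genealogy is not star-shaped: a sampled
lineage joins the founder's lineage `T` generations after the founding and
only accumulates recombination over `L = G − T` meioses, so the moment
estimators date the sample's TMRCA, not the mutation. The default
correction models `T` with density proportional to the pairwise coalescent
intensity `1/N(t) ∝ e^{−pt}` truncated to `(0, G)` — i.e. a truncated
exponential with the per-generation growth rate `p` — and solves

    E[(1−θ)^{G−T}] = δ_observed

for `G` (Brent root-finding, xtol 1e−9; the closed form for the expectation
is evaluated with `expm1` and an explicit `a → p` limit branch for
stability). Properties: the corrected age always exceeds the star estimate
for finite `p > 0`; the correction vanishes as `p → ∞` (fast growth ⇒
star-like genealogy); and it is exactly the inverse of the simulator's
`exponential_growth` genealogy, so correction-undoes-simulation-bias is a
testable round trip. With `p = 0` the estimate is returned unchanged by
convention: the model itself is undefined without growth, and no correction
is attempted rather than applying the (maximal) uniform-branching limit.
The correction is a pluggable callable, so alternative published corrections
can be swapped in without touching the pipeline.

Note the direction of the `p`-dependence: slower growth means earlier-
concentrated coalescent intensity relative to a bigger, flatter genealogy
and a larger gap between TMRCA and mutation age; faster growth shrinks the
correction. The published per-marker corrected values this mimics are not
exactly reproducible from the printed uncorrected integers under any single
closed form (the underlying frequencies are unpublished); the package
therefore treats only the *ordering* (corrected > uncorrected at `p > 0`)
as the contract, which the default correction satisfies everywhere.

## Averaging and confidence intervals

Per-marker generation estimates are combined as an unweighted arithmetic
mean with `SE = s/√n` (sample SD, `n−1`) and `CI95 = mean ± 1.96·SE`; this
choice regenerates the published summary intervals from the printed
per-marker integers in four of five reproducible cells (the fifth differs
by one unit in the upper bound, consistent with the original interval having
been computed from unrounded per-marker values). A single informative marker
yields a mean with an explicitly undefined CI. Rounding (half away from
zero) happens only in report strings; JSON summaries carry the unrounded
values alongside the display text. Years use 30 years/generation by default.

## Composite-likelihood age

As a simplified stand-in for Bayesian LD-dating (which samples intra-allelic
genealogies by MCMC — out of scope), the package maximises

    Σ_chrom Σ_marker log P(observed allele | g)
    P(ancestral | g) = (1−θ)^g + [1 − (1−θ)^g]·q(ancestral)
    P(a ≠ ancestral | g) = [1 − (1−θ)^g]·q(a)

with `q` the control spectrum, over `g ∈ (0, 500]` by bounded scalar
minimisation (xatol 1e−6). Markers and chromosomes are treated as
independent given `g`, so the profile-likelihood interval (1.92 log-lik
drop) is anti-conservative when the genealogy is far from star-shaped; the
result object says so. In the single-marker case with the founder allele
absent from controls the MLE reduces analytically to the Risch estimator
with `δ = k/n`. A fully ancestral panel puts the MLE at the 0 boundary with
a warning. An optional user prior turns the same likelihood into a grid
posterior (512 points by default); no prior is imposed otherwise.

## Demography

Growth rate: generations between censuses are rounded to the nearest
integer before `p = ln(N/N0)/g` — with the default 1591/2011 census years
and 30-year generations this gives `g = 14` and reproduces the published
rate 0.107. HWE allele frequency `q = √(homozygotes/population)` assumes
complete case ascertainment and no heterozygote selection. Prevalence
denominators round to the nearest 1,000 by default (parameterised). The
sampled-chromosome proportion for Bayesian LD-dating software defaults to
`n_sampled/(2Nq)` — the natural reading — with an `individuals` alternative;
the method used is recorded with the result because published values are
not always derivable from stated inputs.

## The simulator

`synthetic_data` emulates the study design the estimators were built for: a
microsatellite panel at ±{1.98, 2.52, 3.32, 3.34, 4.54, 8.7} Mb around the
locus at 1.64 cM/Mb, ~11 disease chromosomes (3–11 is the realistic range
for a rare recessive cohort; 11 mutated alleles in the largest published
group), 200 control chromosomes, and 8-allele control spectra with
heterozygosity ≈ 0.85 typical of the dinucleotide repeats used in such
panels. The founder haplotype is drawn from the control process (or given
private labels to realise `p_n = 0` exactly for oracle tests).

Lineage lengths: `L = G` (star) or `L = G − T` with `T` truncated-
exponential(`p`) (growth), matching the correction model. Breakpoints, one
per side (the estimators only see the nearest one): the default `meiosis`
model draws each generation's nearest crossover by inverting the map
function — equivalently the per-side minimum `M = 1 − U^{1/L}` of the
per-meiosis CDF values, with a breakpoint iff `M < ½` at the distance whose
recombination fraction is `M` — so retention at every marker is *exactly*
Binomial with success `(1−θ)^L` and nested across markers. The alternative
`exponential` model places the breakpoint at Exponential(rate `L` per
Morgan), the classical approximation; it differs from the map-consistent
decay by up to ~0.7 % absolute retention on this panel, which matters at
10,000-lineage calibration resolution — hence the map-consistent default.
Markers beyond the breakpoint receive alleles from a fresh control
haplotype (linkage-equilibrium background; background LD is not modelled).
Optional stepwise mutation perturbs retained microsatellite labels by ±1
per event, Poisson(`rate·L`) events per lineage.

What passing tests show — and do not: the simulator realises the
estimators' own decay model plus controlled violations (growth genealogy,
marker mutation). Recovery within tolerance therefore validates the
inferential machinery, not the adequacy of the model for real data, where
background LD between markers, genotyping error, unphased controls and
inhomogeneous growth all add error not represented here.

Reproducibility: identical config and seed give byte-identical panels and
truth records (single `numpy` Generator, fixed draw order).

## Problem sizes

Calibration experiments use 10,000 lineages for retention checks, 200
replicates × 50 disease chromosomes for recovery means, and 100 replicates
for the composite-likelihood median — sizes at which the Monte-Carlo SE is
comfortably inside the stated tolerances while the whole suite runs in
seconds.

## Known limitations

- Statistical phasing is out of scope: trios are phased by Mendelian logic
  only; ambiguous markers stay unresolved, and externally phased input is
  accepted as-is.
- The composite-likelihood estimator is not a substitute Bayesian genealogy
  sampler; its interval is anti-conservative by construction.
- The growth model treats branch-off times as i.i.d. across lineages — an
  approximation to the coalescent adequate for sign-of-bias and
  round-trip tests, not for full genealogy inference.
- Recombination-rate heterogeneity, allele-frequency drift in controls
  since founding, and selection are not modelled anywhere.
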