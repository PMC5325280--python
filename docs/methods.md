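# Methods

This note documents the models behind each module, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical conventions that a reader would otherwise have to reverse-engineer
from the code.

## Study system and data model

The pipeline operates on diploid microsatellite genotype tables: one row per
individual, an unordered pair of allele sizes (base pairs) per locus, a
population label per individual. Allele sizes at a locus must be congruent
modulo the locus' repeat-unit (motif) length; when motifs are not supplied
they are inferred as the GCD of allele-size differences, which is exact
whenever at least two alleles differ by a single repeat. Missing data are a
pair of zeros; all estimators operate on non-missing gene copies only.

The analyses target a two-deme system: a small focal deme (census a few
hundred) and a neighbouring source an order of magnitude larger, genotyped
at ~14 unlinked loci. Three calibrated presets provide synthetic stand-ins:
a diverse source (H_E ≈ 0.81, ~10.5 alleles/locus in a 647-individual
sample), a depauperate isolate (H_E ≈ 0.55, ~4.4 alleles/locus, n = 139) and
an intermediate island control (H_E ≈ 0.70, n = 56).

## Synthetic populations

Per-locus allele frequencies are drawn from a symmetric Dirichlet(α) over k
allelic states. For that family E[1 − Σp²] = (k−1)α/(kα+1), which seeds a
bisection on log α against the *realized* mean expected heterozygosity of
the drawn vectors, so a preset's draw lands within ±0.02 of its target H_E.
The number of states k is the second calibration axis: it controls how many
alleles a sample of the preset's size realizes. k = 11 / 5 / 6 for the three
presets reproduces both the target heterozygosities and the observed mean
allelic richness values; a heterozygosity-only calibration with many more
states would produce an unrealistically heavy tail of ultra-rare alleles,
which matters for everything that tracks rare-allele retention. Genotypes
are drawn under Hardy–Weinberg; generated populations satisfy |F_IS| < 0.05
at n ≥ 500.

Limitations: the Dirichlet spectrum is exchangeable across states (no
directional size constraints), loci are strictly unlinked and neutral, and
there is no genotyping error or null-allele process. Passing tests on these
fixtures demonstrate estimator correctness and pipeline behaviour, not
robustness to real-data artefacts.

## Summary statistics

* H_O is the fraction of heterozygous genotyped individuals; H_E carries the
  2n/(2n−1) small-sample factor.
* Allelic richness is rarefied hypergeometrically to g gene copies;
  g defaults to the smallest per-locus genotyped gene count within the
  population (pass a common g for cross-population comparisons).
* F_ST is Weir–Cockerham's θ with variance components summed over alleles
  and loci before the ratio.
* Jost's D uses the Nei–Chesser small-sample estimators per locus
  (harmonic-mean sample size ñ): Hs_est = (2ñ/(2ñ−1))Hs, Ht_est = Ht +
  Hs_est/(2ñk), D_est = ((Ht_est − Hs_est)/(1 − Hs_est))·k/(k−1); across
  loci the harmonic mean of per-locus values is used, falling back to the
  arithmetic mean when any locus value is non-positive (the harmonic mean is
  undefined there).
* F_IS comes in the Nei variant (1 − mean H_O / mean H_E) and the
  Weir–Cockerham variant (1 − Σc/Σ(b+c) from within-population components).
* Relatedness is the symmetrized Queller–Goodnight estimator averaged over
  all unordered pairs. Reference allele frequencies are taken from the
  pooled table, not the focal population: with own-population references the
  within-deme mean is ≈ −1/(n−1) by construction, whereas pooled references
  make members of a drifted deme mutually related relative to the total —
  the convention under which the empirical values (≈ 0.44 in the isolate,
  ≈ 0 in the source) were produced. A `reference` argument restores the
  own-population reading.
* Bootstrap CIs are percentile intervals over locus resampling (1,000
  replicates by default); the CI is flagged unstable when the statistic is
  undefined on more than 10% of resamples.

All eight indices are checked against naive loop/enumeration oracles on
small tables, including exhaustive-subset rarefaction.

## Forward two-deme simulation

Each generation applies, in order: (1) migration — Poisson numbers of
migrants per sex and direction around the scheduled means, so fractional
rates like 0.1/generation are meaningful; migrants replace random same-sex
residents, keeping census sizes constant; (2) random mating with fixed equal
sex ratio, each offspring drawing a uniform mother and father (polygyny
allowed) and one gamete from each with free recombination across loci;
(3) mutation per gamete copy at rate μ = 2×10⁻⁴ under a K-allele model over
the source's allelic states by default (SMM/TPM available). Demes are seeded
from a common source-diversity pool, standing in for the ancestral
panmictic population. Generation time is 10 years for converting the
narrative time scales (400 recent years ↦ 40 generations).

Scenario families: (1) sustained high migration and (2a/2b) sustained
reduced migration over 1,200 or 400 generations; (3) a recent two-crash
bottleneck with unchanged migration; (4) a linear decline of migration over
the last 40 generations (a steady decline with no other stated functional
form); (5) the combination of 3 and 4. The crash segment runs at yearly
resolution in the individual-based engine because the two mortality events
(fractions Ma, then Mb five years later) are closer together than one
generation; recovery follows a capped exponential schedule (growth rate g
per year to carrying capacity). During that segment each recruit draws an
independent random pair of mature parents — the convention of
generation-overlap crash simulators; litter-structured breeding (below)
would roughly double the drift rate and does not describe those tools.

The default scenario grid reproduces the published family sizes (52
historical situations, 13 crash situations, 16 recent-migration situations,
13 × 16 = 208 combined, 289 total); the exact factor levels within the
stated ranges lived in unpublished supplementary material, so the defaults
are representative levels spanning those ranges.

Each replicate is sampled at the empirical sample sizes (139 focal, 647
source), the eight indices are computed, and the mean with a 95% CI of the
mean (±1.96 SE over replicates) is reported. A parameter set is supported
when ≥ 2 indices overlap the empirical data across ≥ 2 of the four
categories; overlap is CI–CI intersection where the empirical side has a
bootstrap CI (differentiation) and point-in-simulated-CI elsewhere, since
the empirical table prints the other indices without CIs.

## Effective population size

Long-term Ne inverts the mutation–drift equilibrium heterozygosity under
IAM and SMM; both are exact closed forms and the SMM value dominates the IAM
value for all H_E ∈ (0, 1).

The LD method averages Burrows' composite r² (with the S/(S−1) correction)
over all allele pairs across locus pairs after screening alleles at minor
frequency < 0.05, subtracts the no-LD sampling expectation 1/S + 3.19/S²,
and inverts E[r²′] = 1/(3Ne) + 0.69/Ne² — the random-mating, S ≥ 30
correction branch, applied uniformly. A non-positive corrected r² is
reported as an infinite estimate (no drift signal). The CI is a jackknife
over locus pairs on the 1/Ne scale.

The temporal method computes F_c = mean over alleles of
(x−y)²/((x+y)/2 − xy) and estimates Ne = t / (2[F_c − 1/(2S₀) − 1/(2S₁)])
under sampling plan II. Both contemporary estimators recover the true size
of ideal simulated populations within a factor of two (median over
replicates) for Ne ∈ {25, 50, 100}.

ΔF = 1/(2Ne) is the per-generation inbreeding increment implied by an
estimate; the individual-based engine's realized pedigree inbreeding
accumulates at a compatible rate (within a factor of two of 1/(2·breeder
count)).

## Bottleneck tests

The coalescent kernel simulates a Kingman genealogy of n gene copies,
Poisson mutations at rate θ/2 per unit branch length, and evolves repeat
states: single ±1 steps, or — with probability p_g under the two-phase model
— a multi-step of at least two repeat units, sized 1 + Geometric with mean
δ_g. The multi-step family is one-parameter; the implied variance (≈ 2.3 at
δ_g = 3.1) is smaller than the variance quoted alongside δ_g in some legacy
tools, a documented choice. The kernel is cross-checked against an
independent coalescent simulator (msprime) at matched θ.

*Heterozygosity excess.* For each polymorphic locus, the equilibrium
heterozygosity distribution conditional on the observed allele count k is
obtained by tuning θ (bisection on the pilot mean allele count, cached per
(n, k, model)) and rejection-sampling replicates with exactly k alleles.
The across-locus excess is tested with a one-tailed Wilcoxon signed rank on
the per-locus differences. Conditional on equal k, the stepwise model's
H_EQ exceeds the infinite-alleles value (homoplasy requires more mutations
to reach the same k), which is why stepwise nulls make the test
conservative. The mode-shift indicator flags a pooled allele-frequency
spectrum whose rarest class (0–0.1) is no longer the most populated. On
equilibrium data the test's rejection rate at 0.05 stays near nominal; it
detects severe recent crashes under an infinite-alleles-like null.

*M-ratio.* Observed M = k/r per locus with r counting allelic states
inclusively, (max − min)/motif + 1, so a gapless locus has M = 1;
monomorphic loci enter the observed mean as M = 1 with a warning. The
critical value Mc is the 5th percentile of mean M across loci in equilibrium
null replicates at θ = 4Neμ; each simulated locus is conditioned on being
polymorphic, because monomorphic loci never enter an empirical M
calculation. These two null conventions (polymorphism conditioning;
multi-step size ≥ 2) are pinned by reproducing the full published table of
critical values across eight (θ, δ_g, p_g) combinations to within ±0.01.
P is the fraction of null replicates at or below the observed M.

## Translocation forecasts

The individual-based engine tracks age, sex, genotypes, and (optionally) the
full kinship matrix of a closed population with yearly cycle: age-dependent
survival → aging → translocation in scheduled years → density-regulated
reproduction → bookkeeping. Life history (defaults, configurable): first
reproduction at 4, last at 20, senescence at 16 with 50% reduced output,
annual adult survival 0.9, juvenile (0–3) survival 0.7, mean litter 2.5
with a 2-year breeding interval, polygynous mating, balanced birth sex
ratio, ceiling regulation at carrying capacity (recruitment capped). These
values make an isolated population of 220 demographically stationary at its
carrying capacity. Translocated individuals are breeding-age adults drawn
from the source gene pool (modelled as infinite with fixed frequencies —
the source is 10× larger and assumed unaffected); they are guaranteed a
breeding opportunity in their arrival year (females whelp regardless of
interval; males receive at least one mating). Pedigree inbreeding uses the
kinship recursion with founders and immigrants assumed non-inbred and
unrelated; extinct replicates (loss of a sex, or < 2 animals) contribute
zero retention from extinction onward.

Rare alleles are all source alleles at frequency ≤ 0.05; retention at year
y is the fraction carried by at least one living individual, so it includes
founder-sampling loss at year 0. Under the stationary default demography the
forecasts reproduce the qualitative published pattern — large losses under
isolation, strong mitigation by frequent translocations, ordering monotone
in batch size and frequency — while the absolute endpoints sit below the
published band (≈ 67% vs 70–80% loss under isolation at start size 220, and
≈ 37–43% vs ≤ 30% with 5–10 immigrants per 5 years). The legacy forecasting
tool's unstated vital rates (most sensitively juvenile survival, which sits
on either side of the demographic-stationarity boundary near 0.66) and its
single-allele parameterization cannot be recovered from the published text;
a declining isolated population with demographically meaningful
translocations would widen the gap between the isolation and translocation
endpoints in exactly the published direction. The defaults here were fixed
by the stationarity criterion and not adjusted afterwards.

## Numerical conventions and edge cases

* Percentile CIs and the 5th-percentile Mc use linear interpolation
  (`numpy.percentile` defaults).
* F_ST/D are undefined (raised) without a shared polymorphic locus; LD-Ne
  and temporal-Ne report infinity when the drift signal is non-positive.
* θ < 10⁻⁴ is rejected in the M-ratio null (the polymorphism-conditioned
  sampler would essentially never accept), as is δ_g ≤ 2 (a multi-step must
  exceed one repeat unit).
* All generators and simulators accept integer seeds and are bit-for-bit
  reproducible; replicate streams derive from (seed, replicate index).
* Problem sizes in the test suite and the acceptance script are scaled
  (tens to hundreds of replicates, 10,000 for the M-ratio null) so the
  whole analysis reruns in minutes on one CPU; the statistics reported are
  means over replicates with their Monte-Carlo uncertainty.
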