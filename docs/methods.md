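# Methods

## Incompatibility model

An `IncompatibilityModel` is a set of lethal loci, each tagged with the
parent whose allele contributes to the lethal combination, a penetrance,
and the set of conditions in which the lethality acts.  A spore carries the
lethal genotype iff it inherits the lethal parent's allele at **every**
listed locus; in a listed condition it then dies with probability equal to
the penetrance (default 1).  Model kinds: `none`, `two_locus_unlinked`,
`two_locus_linked` (recombination fraction `r`), and `k_locus`
(k ≥ 1 unlinked loci).  The worked case is the two-locus configuration
with the driver allele (premature stop in a respiratory gene) from parent
P2 on chrV and the rescuing suppressor absent from parent P1 on chrX; the
lethal combination is therefore a *recombinant* (repulsion) genotype.

## Meiosis simulator

Each chromosome is a bivalent of four chromatids (two sisters per parent).
Crossovers fall as a Poisson process along the genetic map (default
0.35 cM/kb, the yeast genome average) with no chiasma or chromatid
interference: each event picks one chromatid of each homolog uniformly and
exchanges their distal segments.  This is the Haldane model; for two
markers at recombination fraction r it reproduces the classical
no-interference tetrad-type frequencies

    d   = -ln(1 - 2r)/2
    TT  = 2/3 (1 - e^{-3d})
    NPD = 1/2 (1 - e^{-2d}) - 1/3 (1 - e^{-3d})

Chromatids are packaged into the four spores by an independent uniform
permutation per chromosome.  Consequences: (i) exactly 2:2 segregation at
every locus, always; (ii) markers on different chromosomes receive
independent, uniformly distributed 2:2 spore partitions (the six
partitions equiprobable), which yields PD:NPD:TT = 1:1:4 for unlinked
pairs.  Centromere linkage and first/second-division segregation are
deliberately not modelled: the analytic theory used throughout assumes
independent uniform partitions, and the screen being emulated never types
centromere-proximal markers.  The uniform-partition choice is an
interpretation — the underlying assumption is only that the interacting
loci assort independently — and is stated as such.

## Analytic tetrad distributions

For k unlinked loci the dead-spore set is the intersection of k uniform
2-subsets of the four spores; `expected_tetrad_distribution` enumerates all
6^k joint partitions exactly.  For k = 2 this gives {4: 1/6, 3: 2/3,
2: 1/6} (the 1:4:1 ratio) and mean spore loss 1/4; in general the loss is
penetrance × 2^-k.  A closed-form cross-check used in the tests:
P(2 dead) = 6^{1-k} and E[dead] = 4·2^{-k}, which determines the whole
three-class distribution.  Linked pairs map (PD, NPD, TT) to viable classes
(4, 2, 3) when the lethal alleles are in repulsion and (2, 4, 3) in
coupling.  Penetrance < 1 is handled by binomial thinning of the
dead-candidate count.

## Segregation classifier

`classify_segregation` scores an observed viable-count histogram against
candidate models by multinomial log-likelihood and selects by BIC
(parameter counts: fixed-expectation models 0, linked 1 — its r profiled
over a 0…0.5 grid in steps of 0.025 — and `complex`, the free multinomial,
4).  Ties break toward fewer parameters, then lexicographic kind name, so
the call is invariant to candidate order.  The goodness-of-fit p-value of
the winner is an exact multinomial test by full enumeration for ≤ 30
tetrads, a chi-square test above 200, and a Monte-Carlo multinomial test
(fixed internal seed 0, 10^5 draws) in between.  The `complex` category is
an explicit stand-in for "does not fit any Mendelian candidate": the
original screen labelled most cases complex without stating a decision
rule, so the BIC rule here is this package's own, documented criterion.

## Screen scoring

Offspring viability = condition-viable spores / permissive-medium-viable
spores (never total dissected spores).  Instances with a non-viable parent
are excluded before any classification.  Severity uses viability loss
1 − v: `severe` at loss ≥ 0.20 (closed boundary, implementing "at least
20%"), `potential_epistasis` at loss ≥ 0.01, else `none`.  The 1% bound is
configurable because it is ambiguous whether it is a detection threshold
or merely the smallest observable loss with 80 spores.  By default no
significance test is applied; an optional exact binomial filter tests the
null that true viability ≥ 1 − epistasis_threshold at α = 0.05 (testing
against viability = 1 exactly would flag any single dead spore, making the
option vacuous).

## Bulk-segregant mapping

Reference-parent allele frequency is scored per marker; markers with depth
< 10 (at 50× nominal coverage) are excluded from region detection as
unstable.  The driver-side rule: a maximal run of ≥ 5 consecutive
sub-threshold (AF < 0.1) markers, bounds at the first/last sub-threshold
marker.  Isolated sub-threshold markers are sequencing noise and are
dropped; `max_violations` optionally allows a bounded number of
above-threshold markers inside a run.  The run length 5 and the depth cut
are explicit stand-ins — the original rule was stated only qualitatively
("most of the mapped SNPs", "inconsecutive SNPs … considered noise").

The rescuer-side rule detects marker deserts: inter-marker or
chromosome-end gaps longer than 10× the chromosome's median spacing.  For
this rule to fire, the marker set must reflect reference-based SNP calling:
`ascertain_markers` keeps a position only when the alternate-parent allele
has ≥ 2 reads **and** ≥ 10% of the depth, since a pooled caller cannot
distinguish lower fractions from noise.  At 50× and 1 marker/kb this
produces a desert of roughly 10–40 kb around a locus where the pool is
fixed for the reference parent.  All coordinates are 1-based inclusive
internally and in TSV output; BED output converts to 0-based half-open.

Pooled sequencing itself is modelled as Poisson(coverage) depth per marker
with each read drawn from a uniformly random pool member and flipped with
the per-read error probability (implemented through the equivalent
binomial marginal).  Pools take at most one spore per tetrad, matching the
independent-tetrads design of the emulated experiment.

## Annotation

ORF coordinates are 1-based from the A of the start codon, so the first
base of codon c is 3(c−1)+1.  A nonsense call requires: reference codon
not a stop, variant codon ∈ {TAA, TAG, TGA}, codon index before the
terminal codon.  Variants are applied one at a time by default (each SNP
judged against the reference ORF); a phased mode applies them jointly for
compound codons.  Stop-to-stop changes and terminal-stop disruptions are
never counted.  Anticodons are handled as DNA 5'→3'; the codon a tRNA
reads is the reverse complement of its anticodon, so a suppressor call
requires revcomp(after) ∈ stop set and revcomp(before) ∉ stop set.  Genes
annotated on the minus strand are mapped through coordinate reflection and
allele complementation and give identical calls to their plus-strand
representation.

## Growth quantification

The maximum specific growth rate is the largest least-squares slope of
log(OD) over a sliding window of consecutive points.  Defaults: window 15
points and a 0.05 OD quantification cutoff (only windows entirely above it
are used; all windows if the curve never reaches it).  At 10-minute
sampling a 15-point window spans 2.3 h — long enough to average read noise
of ~0.005 OD, short enough to stay inside the exponential phase; shorter
windows measurably inflate the maximum slope by chasing noise at low OD.
OD is floored at 1e-4 before the log because blank-subtracted readings can
be ≤ 0; flat or declining curves return rate 0 with a warning.

Percent growth variation is 100·(mean_SUP − mean_Ctrl)/mean_Ctrl with a
two-sided two-sample t-test.  Colony sizes are normalised per replicate by
the same replicate's size on the reference medium, arms are compared on
mean per-replicate ratios (not ratios of means), and |variation| ≥ 10% is
flagged — a magnitude display rule, separate from the statistical tests.
Variance comparisons report a two-sided F-test and the Brown–Forsythe
(median-centred Levene) test; both-arms-constant input returns p = 1 by
convention.  P-values are reported raw; Benjamini–Hochberg is available
but off by default.

## Synthetic data: what it does and does not emulate

The generator reproduces the study's design parameters: 27 crosses × 20
conditions × 20 tetrads; 80-spore inviable pools from independent tetrads;
~50× coverage with 0.2% per-read error; 1 marker/kb (~12,000 markers over
16 chromosomes of realistic lengths); six-replicate 48 h microcultures
read every 10 min with 0.005 OD noise; 12-replicate colony grids with 5%
multiplicative noise.  A default 10% of screen instances get a non-viable
parent to exercise the exclusion filter.  Not emulated: read-level errors
structured by sequence context, mapping bias, aneuploidy, gene conversion,
crossover interference, centromere effects, plate spatial effects, and
condition-specific growth physiology.  Passing tests therefore demonstrate
correctness of the analysis logic under the stated stochastic model, not
robustness to every artefact of real screens.

## Problem sizes and numerical checks

Test and reproduction runs use: 10^5 partition-level tetrads (and 10^4
full-meiosis tetrads) for distribution agreement at chi-square p > 0.001;
50 seeded pool simulations for driver-locus localisation; 2,000 null
simulations at n = 288/arm for F-test type-I calibration (accepted range
3.5–6.5% at α = 0.05); 200 six-replicate pairs for percent-variation
recovery (median within ±2 points of the planted −22.8%).  Boundary
comparisons (the 20% severity cut, the 10% flag) use an epsilon of 1e-9 so
closed boundaries survive float roundoff.

## Known limitations

- The classifier's `complex` call depends on the BIC penalty and so on the
  tetrad count; with < 20 tetrads, moderate departures from 1:4:1 are
  rarely distinguishable from the unlinked model.
- The marker-desert rule needs ~10 markers/chromosome and a marker density
  comparable to the desert width; at 10 kb spacing the rescuer-side signal
  of the worked case is invisible.
- The max-log-slope estimator is slightly biased toward the logistic's
  early-phase slope r(1 − N₀/K); at the defaults this is < 5% and is
  absorbed in the SUP/Ctrl contrast, but very slow arms (≥ 2-fold
  reductions) are compressed by a few points.
- Linked-model expectations assume the no-interference map; real yeast
  shows positive interference, so r̂ from the profile is approximate.
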