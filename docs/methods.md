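# Methods

## The problem

When three ingroup genomes P1, P2, P3 and an outgroup O are compared at
biallelic sites polarized by the outgroup, incomplete lineage sorting (ILS)
produces the two discordant site patterns ABBA (derived allele shared by P2
and P3) and BABA (shared by P1 and P3) at equal expected rates.
Hybridization between the non-sister taxa P2 and P3 breaks that symmetry
and, unlike ILS, also leaves tracts of recent common ancestry in which the
P2–P3 sequence divergence drops well below its chromosomal background.
`introscan` implements the resulting three-stage windowed test: an excess
of ABBA over BABA (Patterson's D) that is statistically significant, an
admixture-fraction statistic f_d in the top decile genome-wide, and a
donor–recipient d_xy significantly below the scaffold background.

## Statistics

At site *i* with derived-allele frequencies (p̂ᵢ₁, p̂ᵢ₂, p̂ᵢ₃, p̂ᵢ₄),

    C_ABBA(i) = (1 − p̂ᵢ₁) p̂ᵢ₂ p̂ᵢ₃ (1 − p̂ᵢ₄)
    C_BABA(i) = p̂ᵢ₁ (1 − p̂ᵢ₂) p̂ᵢ₃ (1 − p̂ᵢ₄)

    D = (Σ C_ABBA − Σ C_BABA) / (Σ C_ABBA + Σ C_BABA)

For single-genome (haploid) inputs every frequency is 0 or 1 and the
weighted sums reduce to integer pattern counts, so the |ABBA − BABA| filter
below operates on plain counts.

f_d divides the D numerator S(P1, P2, P3, O) = Σ(C_ABBA − C_BABA) by its
value under complete introgression, S(P1, P_D, P_D, O), where P_D at each
site is whichever of P2, P3 has the higher derived-allele frequency.  f_d
is reported as undefined when the numerator is non-positive (the statistic
is meaningful only for ABBA-excess windows) or the denominator is zero;
undefined windows can never pass the f_d stage.

d_xy between taxa x and y over a region is (1/n) Σ [p̂ᵢx(1 − p̂ᵢy) +
p̂ᵢy(1 − p̂ᵢx)].  The divisor n counts all retained aligned positions in
the window when alignment input is available; with VCF or SNP-table input
invariant positions are not observable, so n falls back to the window
length in bp, with monomorphic positions contributing zero to the
numerator.  Both modes are flagged in the output and the same mode is used
for windows and their scaffold background.  The pair defaults to (P2, P3),
the donor/recipient pair whose divergence introgression reduces; it is
configurable.

## Significance of D per window

The null hypothesis makes the sign of the per-block numerator exchangeable.
Sites in a window (in position order) are cut into `n_blocks` contiguous
blocks of near-equal site count (default 20), with per-block numerator
s_j = ABBA_j − BABA_j.  Under sign exchange the numerator S = Σ s_j has
exact variance Σ s_j², so the test uses

    se(D) = sqrt(Σ s_j²) / (ABBA + BABA),    z = D / se,

with a two-sided standard-normal p.  We use this null-variance form rather
than a delete-one jackknife of the D ratio because the jackknife SE is
itself a noisy estimate when informative sites are sparse and arrive in
linkage clumps; studentizing by a noisy SE produces far too many extreme
p-values exactly in the tail the scan thresholds on (measured on simulated
null genomes, the jackknife form exceeded its nominal 10⁻³ rate more than
ten-fold, while the null-variance form is calibrated — see the acceptance
suite).  Windows with fewer than two blocks containing informative sites
get an undefined test and can never be called significant.  The same
estimator applied genome-wide (where both forms agree closely) provides the
genome-level D and its SE.

The d_xy comparison is a one-sample z-test of the window against the
population of full-size windows on its scaffold: the background `se` is the
sample standard deviation of per-window d_xy, and p is the lower one-sided
normal tail, since introgression requires *reduced* divergence.  (Taking
"standard error" as the SE of the scaffold mean instead would declare
almost any window below the mean significant, which cannot be what a
per-window filter intends.)  Partial terminal windows are excluded from the
background to avoid length-driven variance; candidate windows are included,
reading the background as the whole scaffold.  A background needs at least
two windows and positive spread, otherwise its candidates are dropped with
an explicit flag, never silently.

## The cascade and its thresholds

Stage 1 retains windows with p < 10⁻³, |D| > 0.59 and |ABBA − BABA| > 10
(all three configurable; the gap criterion is interpreted on the
frequency-weighted sums, which equal counts for haploid input).  Stage 2
computes the 90th percentile (linear interpolation) of f_d over all windows
with defined f_d genome-wide and keeps candidates at or above it — ties
are kept.  Stage 3 keeps candidates with d_xy z-test p < 0.01.  The stages
are strictly nested by construction; no multiple-testing correction is
applied across windows (raw per-window thresholds are the operating
characteristic being emulated; a correction could be layered on the output
TSV).  Windows default to tumbling (step = size, adjacent windows, sizes
5/50/100/500 kb preset); a smaller step gives a sliding scan.  The 500-kb
clade summary deliberately reports only stage-1 incidence — a coarse
per-quartet overview, not locus calls.

## Input handling

Polarization uses the outgroup sample's allele as ancestral, never the VCF
REF; the derived frequency is the non-outgroup allele's frequency, so
p̂ᵢ₄ = 0 at every retained site.  Sites that are monomorphic across the
quartet, carry more than two alleles, have missing calls, or an
outgroup-polymorphic genotype are dropped and counted per reason (a
permissive mode keeps outgroup-polymorphic sites, polarizing on the
outgroup's majority allele with fractional p̂ᵢ₄).  Alignment input is
anchored to the ungapped outgroup coordinate so windows live in one
reference frame; columns where any taxon has a gap or ambiguity code are
skipped.  The SNP-table dialect carries one allele column per taxon, so
writing is restricted to haploid tables, where the round trip is exact.

## The simulator

The generator produces the statistical structure the scan assumes and
nothing more: a JC69 quartet with ultrametric split depths d12 = 0.02,
d123 = 0.05, dO = 0.10 substitutions/site (interspecies fungal scale —
the P2–P3 background divergence is ≈ 2·d123 = 0.10), ILS emulated by
independent 100-bp blocks drawing a discordant ingroup genealogy with
probability 0.2 (the two discordant topologies equiprobable, which is
exactly the symmetric null of the D test), and introgression as tract
replacement: the recipient's sequence re-derived from the donor's with a
residual divergence of 0.01 = 0.1 × background.  The reference dataset is
one 1 Mb scaffold with ten evenly spaced 5-kb P3→P2 tracts.  Block-wise
topology resampling is not a coalescent: there is no depth heterogeneity
between discordant loci, no recombination within blocks, no rate
variation, no indels and no assembly error, so passing tests demonstrate
the statistics and cascade operate correctly on data with the assumed
structure — not performance on any real genome alignment.  All randomness
flows from the mandatory config seed; outputs are byte-identical across
runs.

`expected_pattern_rates` computes, by exact enumeration over internal-node
states with JC69 transition matrices, the per-site probability of the
(haploid, biallelic) ABBA and BABA patterns under each regime — concordant,
either discordant topology, and the tract mixture.  Because the simulator
composes the same transition kernels, observed pattern counts must match
these values up to Monte-Carlo noise; the acceptance suite checks agreement
within 3·√(expected count) per regime over 20 seeds.

## Numerical and degenerate-input choices

Undefined statistics are represented as None and propagate as "never
passes"; a window with ABBA + BABA = 0 has undefined D, and an empty VCF
yields an empty table list with a warning rather than an error.  The f_d
percentile uses NumPy's linear-interpolation convention.  BED output is
0-based half-open; VCF and table positions are 1-based; GFF3 is converted
to 0-based half-open on load.  Gene–region overlap requires ≥ 1 bp
(half-open intersection); a containment mode is available.  Problem sizes
throughout the test and acceptance runs — 1 Mb genomes, 20 replicate
seeds, 5-kb primary windows — were chosen so the full suite exercises
every stage at the default study conditions in well under a coffee break
on one core.

## Known limitations

* The ILS emulation is block-exchangeable, not coalescent-exact; branch
  depths do not vary between loci, so d_xy at discordant loci is less
  dispersed than real ILS would make it.
* With VCF-only input the d_xy divisor is window length in bp, which
  understates divergence where alignability is poor; supply alignments
  when absolute d_xy levels matter.
* The |ABBA − BABA| > 10 floor is scale-dependent: at low SNP densities it
  dominates the cascade and at very high densities it is vacuous.
* f_d is undefined for BABA-excess (D < 0) windows by construction;
  scanning for introgression into P1 requires swapping the quartet roles.
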