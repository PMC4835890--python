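# Methods

This note documents the models and procedures implemented in
`couplebiome`, the parameter choices that matter, what the synthetic
cohort generator does and does not emulate, and the numerical decisions
taken where the design was genuinely open.

## Read quality control

Four exclusion rules, evaluated per read in a fixed order so every
rejected read is attributed to exactly one rule: (1) length < 200 bases;
(2) one or more ambiguous bases, where "ambiguous" means the character
`N` only — other IUPAC ambiguity codes are rejected at parse time;
(3) mean Phred quality strictly below 25; (4) a homopolymer run strictly
longer than six nucleotides. Boundary semantics are literal: a 200-base
read, a mean of exactly 25.0, and a run of exactly six all pass. Reads
without a quality track (FASTA input) skip rule 3 rather than failing
it, on the grounds that the rule is inapplicable and FASTA deliverables
have typically been quality-filtered upstream. All thresholds are fields
of `QcParams`.

## Two-tier taxonomy

**Tier 1 (species).** Percent identity is computed on an optimal
semi-global alignment (free end gaps on both sequences; match +5,
mismatch −4, gap open −10, extend −0.5) as matches divided by aligned
columns, with terminal-gap columns excluded. This makes a read that is
an error-free prefix of its reference score exactly 100 %. Because free
end gaps let two short unrelated sequences "match" on a one-column
overlap, a hit must additionally cover at least 80 % of the query
(configurable). The best hit is accepted at ≥ 97 % identity; ties break
by greater aligned length, then lexicographically smallest reference id.
An edit-distance prescreen (edlib, infix mode) orders candidates and
discards references more than max(3, 1 % of read length) edits worse
than the best; it is a pure optimisation and the test suite verifies it
never changes an assignment on seeded cohorts.

**Tier 2 (genus).** A word-based naive-Bayes classifier with word size
k = 8. For word *w* and genus *g* with M_g training sequences, m(w,g) of
which contain *w*, and N total sequences, n(w) containing *w*:

    P_w    = (n(w) + 0.5) / (N + 1)
    P(w|g) = (m(w,g) + P_w) / (M_g + 1)

A read is scored by the sum of log P(w|g) over its distinct words.
Bootstrap confidence: 100 draws of ⌊V/8⌋ of the read's V distinct words
with replacement; the reported genus is the modal winner and the
confidence its winning fraction. Reads below 0.80 confidence are
excluded from all downstream analyses and counted per specimen.

**Tree mapping.** OTU-table rows carry `s__`/`g__` prefixes so the two
namespaces cannot collide. For phylogenetic metrics, species rows map to
their own tip; genus rows map to that genus's most abundant species tip
in the cohort (ties by label), or can be dropped entirely.

## Diversity

**Rarefaction** draws a multivariate hypergeometric subsample (without
replacement) to a common depth. The depth default is 90 % of the
smallest specimen depth; specimens below the chosen depth are dropped
with a logged warning. Alpha metrics are means over ten independent
rarefactions.

**Chao1** uses the bias-corrected estimator S + F1(F1−1)/(2(F2+1)),
defined even with no doubletons; the classic form is available by flag.
**Faith's PD** uses whole-tree semantics: the branch path from the
present tips to the root is included, so a single tip on a star tree has
PD equal to its own branch length. **Unweighted UniFrac** is the branch
length unique to one community divided by the branch length leading to
either community; branches subtending neither are ignored. All three
are computed from a branch × tip incidence matrix of the rooted tree, so
the all-pairs distance matrix reduces to dense matrix products.

**PCoA** eigendecomposes the double-centred −D²/2. Negative eigenvalues
are reported but carry no coordinates; no Lingoes/Cailliez correction is
applied. **ANOSIM** uses R = (mean between-group rank − mean
within-group rank) / (n(n−1)/4) with average ranks for ties and a
permutation p-value that counts the observed statistic, so p ≥
1/(permutations+1). 999 permutations by default.

**Group comparison** of alpha values defaults to a permutation test (999
label permutations, Welch statistic, observed counted — minimum p
0.001), with the parametric Welch test available. The permutation
default reflects the granularity such tests produce in practice.

## The partner / non-partner test

For each man in a stratum: the partner distance is the UniFrac distance
to his partner's vaginal specimen; the non-partner distance is the
arithmetic mean of distances to every other woman's vaginal specimen.
Non-partner women are restricted to the same clinical group by default
(a flag lifts the restriction): the scientific question is whether a
BV-man is closer to *his* BV-partner than to other BV-women, not
whether BV and normal communities differ. Men missing their own or
their partner's specimen are skipped with a logged note. The test is a
two-sided paired *t* across men; strata are group × male site ×
circumcision (8 in total), and empty or single-man strata are reported
as absent. If all paired differences are exactly zero the result is
t = 0, p = 1; constant non-zero differences are a degenerate-variance
error rather than a silent p ≈ 0.

### Calibration of the paired design

A structural property of this test matters for interpretation: write
the man–woman distance as x_ij ≈ a_i + b_j + c_ij (man effect, woman
effect, pair interaction). The partner assignment is a bijection, so the
woman effects b_j cancel exactly from the *mean* paired difference but
still inflate its sample standard deviation. The t statistic is
therefore deflated by roughly √(σ_c²/(σ_b²+σ_c²)): when women differ a
lot in how far they sit from *everyone* (large σ_b), the test is
conservative, not anticonservative. The synthetic generator (below) is
designed so that, within a group, women's communities have nearly
constant phylogenetic eccentricity (σ_b small relative to σ_c), which
keeps the null rejection rate of the test near its nominal 5 % — the
regime in which the original design is informative. With heterogeneous
real cohorts the test errs on the side of missing effects. This is a
property of the published procedure itself, not of this implementation.

## Synthetic couple cohorts

The generator emulates the *statistical structure* the analysis relies
on, not vaginal microbiology in detail.

**Reference and phylogeny.** Sequences evolve by uniform random
substitution along a random binary genus tree (branch lengths
0.04–0.08 substitutions/site per level) with species as short terminal
branches (0.02–0.045, at least two substitutions so sibling species
never coincide). This yields within-genus identity ≈ 91–96 % and
between-genus ≈ 70–85 % — congeneric 16S species realistically differ by
4–9 % — so the 97 % species tier and the genus-level Bayes tier have
honestly separated jobs. Homopolymer runs are capped at four bases in
references so that QC truth stays exact. Genus names follow the
organisms typical of this literature (one *Lactobacillus* analogue, four
skin genera, the rest BV-associated anaerobes); the names are labels
only. A `simulate_novel_genus` helper produces a lineage diverged near
the root (~35 %), roughly equidistant from every reference genus — the
situation in which a genus classifier should refuse to assign.

**Communities.** Compositions are sparse: taxa a subject does not carry
are exactly zero, which is what presence-based UniFrac needs to carry
signal at realistic read depths. Normal vaginal communities have one
dominant *Lactobacillus* species (Dirichlet weight 50; a second dominant
with probability 0.3) plus 2–6 minor taxa. BV communities carry a
per-woman species subset spanning *every* BV genus (each species with
probability 0.55, at least one per genus; Dirichlet weight 0.8 each)
plus one residual *Lactobacillus*. The per-genus stratification mirrors
the near-universal prevalence of BV-associated genera among BV-positive
women and, as discussed above, keeps the paired test calibrated under
the null. Penile skin baselines are skin-genus communities plus a
random 40 % of BV taxa at low weight (BV-associated organisms are common
on penile skin); urethral baselines are sparse low-concentration draws
over skin and BV taxa, giving the high between-specimen variance that
makes urethral diversity similar in both groups.

**Couple structure.** The male composition at each site is
(1−κ)·(draw around his baseline) + κ·(partner's vaginal composition).
κ defaults to 0.5 for BV couples and 0 for normal couples — no
quantitative effect size is known for couple-level community similarity,
so κ is a calibration knob chosen to reproduce the qualitative
stratified pattern, not an estimate of anything measured. The urethra receives κ scaled by 0.6 (uncircumcised)
or 0.15 (circumcised), so a clear urethral effect appears mainly in
uncircumcised men. Because unweighted UniFrac is presence-based, the
partner effect saturates above κ ≈ 0.25: partner taxa cross the
presence threshold at low κ already. Circumcision is drawn at 54 %
(BV group) and 74 % (normal group) and is unlinked to composition apart
from the urethral κ scaling, so ANOSIM on circumcised vs uncircumcised
penile specimens is expected non-significant.

**Reads.** Depths are Poisson around per-site means 6053 (vagina), 5074
(penile skin), 5350 (urethra). Reads are reference prefixes of length
~N(455, 40) clipped to [250, 500], with i.i.d. substitution errors
(default 0.5 %) and Phred qualities uniform on 28–40. The four QC defect
classes are injected mutually exclusively per read (1 % each by
default): truncation below 200 b, 1–3 `N`s, qualities re-drawn from
10–22, or an inserted 7–9-base homopolymer. Clean reads are verified to
pass all filters at construction, so per-rule rejection counts have an
exact ground truth.

**What the generator does not emulate:** chimeras, platform-specific
homopolymer miscalls, within-couple dynamics over time, abundance
gradients between anatomical sub-sites, strain-level variation, and any
real taxon's actual abundance distribution. Passing tests therefore
demonstrate that the *pipeline* behaves correctly under the assumed
statistical structure, not that real cohorts would show these effect
sizes.

## Problem sizes and seeds

Statistical experiments (type-I error, stratified power, effect
monotonicity) run on count-level cohorts — compositions feed multinomial
counts directly — at the full 96-couple design: 400 replicate cohorts
for null calibration, 100 for the stratified pattern, 20 per κ level
for effect curves. Read-level stages (QC accounting, classifier
recovery) run on small cohorts (hundreds of reads), where per-read
alignment is comfortable. Every source of randomness flows through
`numpy` generators seeded from a single master seed via stable per-stage
hashes, so runs are bit-reproducible and inserting a stage does not
reshuffle the others.

## Known limitations

- Percent identity on very short or unrelated sequence pairs is
  degenerate under free end gaps (a one-column overlap scores 100 %);
  the ≥ 80 % coverage requirement is what makes tier-1 search sound.
- The stratified "expected pattern" frequency (~0.90–0.95 of cohorts) is
  bounded by the joint behaviour of four approximately calibrated normal
  strata (each clean with probability ~0.97–0.98); it cannot approach
  1.0 without making those tests artificially conservative.
- ANOSIM and permutation group tests use label permutations that assume
  exchangeability within the tested factor; nothing corrects for couple
  non-independence in cross-site pooled analyses, so such pooling should
  be avoided (the implemented analyses stay within site × group).
- The Bayes tier classifies at genus rank only, and its behaviour on
  lineages closely related to a reference genus is to assign them there
  with high confidence — exclusion is only expected for genuinely
  isolated lineages.
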