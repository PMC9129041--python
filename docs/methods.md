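# Methods

## The question and the estimators

Mutation in most genomes is GC→AT biased, yet mammalian-style genomes keep
GC-rich stop codons (TGA) at high frequency in GC-rich isochores. Two
forces can hold an allele above its mutational equilibrium: purifying
selection and GC-biased gene conversion (gBGC), a repair bias that behaves
like directional drive on AT↔GC heterozygous sites wherever recombination
initiates. `stopflux` implements the statistics that distinguish them:
substitution flux at the focal stop codon, the same trinucleotides outside
the stop context, mutational-equilibrium baselines built purely from de
novo mutations, and second-order deviations that isolate a GC-coupled
fixation advantage.

## Ancestral states on a trio

A three-taxon tree has one internal node; the marginal posterior of its
state at a column is pi(x) times the product of tip transition
probabilities, one branch per tip. We fit JC69 or HKY85 by coordinate
ascent: base frequencies are empirical, and each branch length (and kappa)
is maximised in turn with bounded 1-D optimisation over the fully
ungapped columns, so the log-likelihood never decreases. Transition
probabilities use the closed-form HKY solution with the rate matrix
scaled to one expected substitution per time unit, so branch lengths are
in substitutions/site. Tips showing a gap or N drop out of the column's
product; MAP ties break on the fixed order A < C < G < T. The ancestral
stop codon is the MAP state at the three stop columns, accepted only when
it spells TAA/TGA/TAG and no stop column is gapped in two or more
sequences.

Assumptions worth keeping in mind: a single reversible matrix is shared by
all sites and branches, although the underlying mutational process is not
reversible; parallel substitutions in the two ingroups are not corrected.
Both choices mirror how such reconstructions are run in practice, and both
compress flux contrasts at deep divergence — ambiguous columns resolve
toward the equilibrium frequencies, converting some true GC→AT events into
apparent AT→GC ones. The acceptance pipeline reports the reconstruction
accuracy alongside the flux estimates so this compression is visible
rather than silent.

## Flux, pTGA and partitions

Each ingroup lineage contributes one incidence of the resolved ancestral
stop and one transition when its tip codon differs; the outgroup only
informs the reconstruction. Transitions to non-stop codons are tabulated
but excluded from stop-to-stop rates, matching the equilibrium model's
assumption that stop→sense changes are rare and deleterious. pTGA =
1/(1+s) with s the ratio of the two dominant fluxes; it equals the
stationary TGA share of the implied two-state chain (a property the tests
verify against long-run iteration). Partitions are compared by (O−E)/E;
uncertainty comes from resampling genes with replacement within each
partition (10,000 replicates by default; resamples with an undefined pTGA
are skipped and logged, and a partition whose resamples are more than half
invalid raises instead of returning a number).

The half-split by intronic GC balances flux events, not genes, so the two
halves have equal information content; with a discrete isochore structure
the cut can place a few GC-rich genes in the GC-poor half, which is the
price of the balancing and is shared by any event-balanced design.

## The Monte-Carlo null

Under the null, every gene experiences the pooled genomic per-incidence
rates. Per replicate, each TAA incidence fires a TAA→TGA event with the
genomic rate (and symmetrically for TGA), giving a null pTGA; 1,000
replicates per group and 10,000 random cross-group pairs give p = n/m,
one-sided by default because the hypothesis is directional. Replicates
with zero TAA→TGA events and pairs with a zero reference draw are redrawn
and logged so counts stay exact. Simulation at the study conditions used
in the acceptance suite (two groups of 2,000 genes at rates 0.02/0.02)
puts the empirical type-I error at 0.049, i.e. the procedure is
calibrated; the acceptance test runs 1,500 replicate experiments rather
than a few hundred so the estimated level is measured with a Monte-Carlo
SE of about 0.006.

## Mutational equilibria

Rates are counts per incidence of the source state in the exposure
region, with exact (Garwood/chi-square) Poisson 95% intervals — the same
interval R's `poisson.test` reports. Stationary distributions are solved
directly: replace one balance equation by the sum-to-one constraint and
solve the linear system; long-run iteration of the per-generation
transition matrix is kept as an independent oracle in the tests, and
reducible chains raise with their strongly connected classes named. The
three-stop system substitutes one frequency by one-minus-the-others and
solves the remaining 2×2 system; the answer is invariant to which stop is
eliminated and satisfies every balance equation to 1e-12.

Dinucleotide matrices trace each point mutation to the reference and count
both overlapping dinucleotide changes (a single-side mode exists for
sensitivity analysis). For local-GC-binned equilibria the exposure is the
bin's opportunity set: every reference position whose centred 10 kb window
GC falls inside the bin's local-GC range. An earlier variant that used the
union of the mutations' own windows biases exposure composition at
isochore boundaries (positions in the union whose window GC lies outside
the bin's range could never have contributed a mutation to that bin), and
the opportunity-set definition removes that artefact; under a homogeneous
mutation process the per-bin GC*/TGA* profiles are flat to within
bootstrap error, as they must be.

## Markov null sequences

Null sequences start from the equilibrium dinucleotide distribution and
extend with P(next|prev) = F(prev,next)/F(prev,·). Each simulant consumes
its own deterministically spawned random stream, so enlarging the set
never reshuffles earlier sequences. The default set is 10,000 sequences
of the analysed gene set's mean CDS length. The closed form
p(abc) = F(ab)·P(c|b) is exposed alongside the simulator; it is exact
whenever F's left and right marginals agree, which holds for genuine
equilibrium compositions, and the simulator exists because the procedure
(and its sampling error) is part of what is being reproduced.

## Boost

D = (O−E)/E per trinucleotide, observed in the top or bottom 20% of
sequences by GC and expected from the GC-matched mutation bin's
dinucleotide equilibrium through the Markov closed form. The boost is the
literal (D1−D2)/D2; because that formula flips orientation when D2 < 0,
D1−D2 and the |D2|-denominator variant are always co-reported and never
silently substituted. GC classes contain 8/24/24/8 trinucleotides;
rankings use mid-ranked ties; the sense/antisense permutation test
re-pairs trinucleotides strictly within GC class (reverse complementation
preserves GC content, so this is the exchangeable null).

## The synthetic generator

The generator emulates the full input suite with mammalian-flavoured
defaults chosen once: an AT-biased, transition-rich mutation matrix whose
two-class equilibrium GC* is about 0.32; isochore blocks at GC 0.35/0.55;
genome-wide stop usage near TAA 28% / TGA 52% / TAG 20%; log-normal
protein abundances; a log-normal recombination map whose correlation with
window GC is a single coupling knob. Branch lengths are in expected
proposals per site; with the default acceptance baseline of 0.5 the
realised substitution rate is half that, which the parameter-recovery
tests account for.

The gBGC knob B acts at fixation, not mutation: substitutions are
proposed from the mutation matrix and accepted with probability
min(1, 0.5·B) for AT→GC, min(1, 0.5/B) for GC→AT and 0.5 otherwise. The
baseline 0.5 keeps both directions informative up to B = 2. Trio
alignments are generated ungapped, isolating flux inference from aligner
error, and each branch applies at most one substitution per site per
round (multi-hit behaviour is approximated by running multiple rounds).

The boost sign-recovery experiment starts all blocks at GC 0.45 — above
the mutational equilibrium, as mammalian genomes are — and confines B to
a designated half of the blocks, which therefore become the GC-rich
class. Designation rather than realised-GC ranking keeps the B = 1
control exchangeable: ranking by realised GC would select on composition
noise and manufacture a spurious class/boost correlation even without any
fixation bias. Partial relaxation (about 0.3 substitutions/site) keeps D2
bounded away from zero for the 0% and 100% GC classes, so the literal
boost formula is stable exactly where the ordering check reads it; the
33%/66% classes pass near D2 = 0 and their literal boosts are
correspondingly volatile, which is a property of the formula, not of the
implementation.

What the generator does not emulate: demography and polymorphism (changes
fix instantly with a biased acceptance, there is no segregating variation),
indels and alignment error (unless gaps are injected deliberately),
recombination hotspot fine structure, selection on codon usage, and
context effects beyond the dinucleotide level. Passing the recovery tests
therefore demonstrates that the estimators recover the forces they are
built for under those idealisations — not that real genomes contain no
additional forces.

## Problem sizes and determinism

The acceptance pipeline runs a 6,000-gene genome with branch lengths
0.25/0.25/0.4 proposals per site and a 50,000-mutation de novo table —
sizes at which flux events number in the hundreds and every equilibrium
estimate has a relative error of a few percent. All randomness flows from
a single seed through spawned `SeedSequence` streams; two runs with the
same seed are bit-identical. Tolerances: linear-algebra identities are
checked at 1e-10 to 1e-12; statistical recoveries at 3 standard errors of
the quantity being checked, with Monte-Carlo SEs computed across
simulants (overlapping trinucleotide windows are correlated, so
naive multinomial SEs would under-cover).

## Known limitations

ML ancestral reconstruction with a reversible model underestimates flux
asymmetry at deep divergence (see above); the importer for external
`.state` tables exists so reconstructions from richer models can be
substituted. The enrichment statistic treats downstream positions
conditionally (positions with no stop trinucleotide in a gene are
skipped), one of two defensible readings of a formula whose published
rendering is incomplete. Two-fold synonymous flux uses the 12 standard
NNR/NNY pairs and third positions only. PGLS and GLM model fitting are
out of scope: the package assembles model-ready tables and leaves the
fitting to standard statistical software.
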