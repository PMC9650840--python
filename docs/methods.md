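# Methods

This note records the models behind `coreflow`, the parameters that
matter, the design choices made where the design was genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## Data model

All statistics operate on a *core-genome concatenate*: one equal-length
nucleotide alignment per species (alphabet A/C/G/T/-/N; other IUPAC
codes are collapsed to N rather than inventing allele semantics) plus a
gene map of 0-based half-open, in-frame intervals. Coordinates are
0-based internally and 1-based only in human-readable reports. Missing
data is handled pairwise throughout: a column counts for a genome pair
only when both genomes carry a plain nucleotide there (π, ANI,
distances, window identities, haplotype frequencies).

## Species delimitation

ANI of core genes is the percent identity over comparable columns;
species are connected components of the ≥94% graph (single linkage, the
delimitation cutoff used throughout; 95% is the common taxonomic
convention but 94% is this framework's operating point). Cluster labels
are `SP_<smallest member id>`, making the partition order-invariant.

Corrected distances are closed-form: p-distance, Jukes–Cantor, or K2P
(default). Guide trees are neighbor joining on K2P distances with
negative branch-length estimates clamped to zero. Maximum-likelihood
distance/tree estimation was deliberately not used: the homoplasy
engine consumes only relative distances and topology, for which the
closed-form pipeline is adequate, self-contained and fast. Distances
needing log of a non-positive argument raise with advice to fall back
to p-distance.

## The homoplasy engine

For each polymorphic column, each non-modal allele (modal ties broken
alphabetically) becomes a presence/absence character; gap/N leaves are
free. Its origin count is the exact unit-cost parsimony score computed
by a vectorised Fitch pass over a binarised postorder representation of
the guide tree (refining multifurcations with zero-length nodes leaves
the score unchanged). `homoplasic ⇔ score ≥ 2`; note this counts any
second state change, so a gained-then-lost allele is also flagged — the
operational meaning is "distribution incompatible with one origin and
vertical inheritance". Alleles carried by one genome are trivially
single-origin and count toward m by default (`include_singletons`);
they can be excluded for symmetry with the LD singleton filter, but the
convergent-mutation null relies on the default, since a diverged
genome's private alleles are the dilution that h/m_0 must reproduce.

Resampling excludes exactly one genome at a time: the leaf is pruned
from the fixed guide tree (no re-estimation) and the tally recomputed;
the 100 replicate ratios are drawn by cycling random permutations of
the genome list, and their sample SD is the h/m uncertainty. Outlier
(non-recombining) genomes are excluded greedily: the genome whose
removal most increases the median resampled h/m is dropped when the
one-sided rank-sum P < 10⁻⁴ *and* the median relative increase is ≥10%
("substantial" is not otherwise defined; 0.10 is the configurable
default), iterating until no genome qualifies or only 4 would remain.
Rank-sum (Mann–Whitney) is used because the two resample distributions
are unpaired.

Synonymous/non-synonymous classification considers only codons with
exactly one polymorphic, biallelic site (standard genetic code, phase
from the gene map); species qualify for reporting with ≥100 homoplasic
and ≥100 non-homoplasic classified alleles.

## Clonal simulation and the 3-SD test

The simulator draws a root sequence i.i.d. from the species GC (K2P's
stationary distribution is uniform, but branches are short enough that
composition drift is negligible) and evolves it along the guide tree as
a per-site Poisson substitution process: site rate ∝ the codon-position
rate for its position, normalised to mean 1 so branch lengths are
substitutions/site; substitution type is a transition with probability
κ/(κ+2), each transversion 1/(κ+2). Repeated hits at one site compose
sequentially, so back-mutations occur naturally.

κ is defined on the K2P *rate* scale (α/β) and estimated as
2 × (transition-type / transversion-type biallelic sites), because
under K2P a fraction κ/(κ+2) of substitutions are transitions. This
keeps estimation and simulation mutually consistent: simulating at the
estimated κ reproduces the observed substitution spectrum. (Estimating
κ as the raw site-count ratio and simulating with κ/(κ+2) would halve
the transition bias and bias the clonal null low — empirically enough
to misclassify genuinely clonal populations as recombining.) κ is
capped at 100 when no transversions are observed. Codon-position rates
are proportional to polymorphic-site counts at positions 1/2/3 (floored
at 1 so no position is unmutable).

Because recombination inflates estimated branch lengths, the simulation
runs once per factor on a geometric grid of 99 rescaling factors
(0.05–5.0; the bracket covers both deflation and strong inflation), and
the replicate whose π is closest to the real π becomes the null; a best
factor on the grid edge triggers a warning. Replicate r uses seed + r.
The null replicate gets its own re-estimated NJ tree before its h/m is
computed, mirroring the treatment of the real data. The species is
clonal iff `real h/m ≤ null h/m + 3·SD(real resamples)`; the SD
multiplier k = 3 is the conservative default (2–4 give very similar
answers at scale).

## Linkage disequilibrium

Loci: biallelic, minor allele in ≥2 genomes (singletons depress the
recombination signal), <25% of genomes missing. r² is computed from
allele and haplotype frequencies over genomes non-missing at both loci,
for all pairs within a distance cap, then averaged in consecutive
1,000-bp distance bins; the verdict is Spearman's ρ on (bin midpoint,
mean r²), clonal unless ρ < 0 with P < 10⁻⁴ (the operative threshold;
0.0226 is the multiple-testing-adjusted level it reflects and is
recorded in output metadata). A perfectly flat profile is clonal with a
"degenerate profile" flag.

The profile itself defaults to the full concatenate range, but the
clonality *driver* caps pair distance at L/2: beyond that distance a
bin can only be filled by loci near the alignment ends, so genomic
position and distance become confounded and position-specific locus
effects drift the binned means, firing the rank test spuriously in
either direction. With the cap, every locus contributes to every bin.
This is a desk-scale necessity (100-kb concatenates); on multi-Mb real
concatenates the confound is far weaker. Raw pairs are retained on the
profile only below 2×10⁶ pairs; binned sums are always exact.

## Between-species tests

The shared core of a reference species and a candidate gene set is
built by global pairwise protein alignment (BLOSUM62, terminal gaps
free) of candidate genes against reference gene consensus translations:
best bidirectional hits at ≥70% identity (computed over aligned columns
excluding terminal gaps) and ≥80% length conservation
(shorter/longer ratio), single-copy in the candidate; retained genes
are threaded codon-by-codon through the protein alignment onto the
reference coordinates, gaps elsewhere. Exhaustive pairwise alignment
replaces a heuristic search engine — acceptable at the hundreds-of-genes
scale this package targets.

h/m_ref, h/m_cand and h/m_0 are tallied with their own NJ trees and
leave-one-out resampling (the excluded genome is drawn uniformly from
all rows, candidate/null included). The null sequence evolves from the
reference consensus by uniform JC point mutations (with replacement;
first crossing of the target mismatch count stops the process) to the
candidate's mean p-distance from the reference (mean is the default
aggregator; max is available). Verdicts: *distinct_species* when
h/m_cand sits significantly (one-sided rank-sum P < 10⁻⁴) and
substantially (median drop ≥ 10%) below h/m_ref; otherwise
*same_species* when h/m_cand is significantly above h/m_0; otherwise
*ambiguous* — and forced ambiguous when |h/m_ref − h/m_0| is within one
resampling SD, where h/m_norm is unstable. h/m_norm is reported
unclipped (values slightly outside [0, 1] are legitimate noise).

## Introgression scan

Windows are laid on the concatenate (spanning gene junctions), trailing
remainder dropped; a window needs ≥50 comparable columns in every
required pair or it is skipped and logged. "More similar" is strict;
ties are conservative (not introgressed). The identity threshold
applies to the best candidate-to-reference identity, the same quantity
the call compares against the minimum within-reference identity. The
scan is refused entirely when any reference genome is more related
(K2P distance) to the candidate than to a fellow reference genome,
since the method assumes the candidate is an outgroup. S_i is
non-increasing in the threshold by construction.

## MEPS model

Sequence pairs are simulated at 50% GC with uniform JC substitutions
and no indels, stopping at the first crossing of the target observed
identity, so the mismatch count is exact. Identical segments are
counted with a 1-bp-sliding window (the count of *available* segments;
a non-overlapping mode exists for sensitivity analysis) via a cumulative
mismatch sum. The analytic baseline (length − L + 1)(1 − d)^L assumes
independent uniform mismatch placement; the simulation's fixed mismatch
count makes it very slightly hypergeometric, a <0.1% effect at the
sizes used here and well inside Monte-Carlo error.

## Synthetic data: what it emulates and what it does not

The generator produces Yule or perfectly balanced ultrametric
genealogies (balanced requires a power-of-two leaf count) scaled either
to a root-to-tip depth or so the mean tip-to-tip path equals a target
π. Populations evolve forward in time under the clonal model plus
gene conversion: events arrive at `rate × length × branch-length`
(events per site per substitution — the event-count analogue of r/m),
each copying a geometric-length tract (no wraparound) from a donor
branch alive at the event time, chosen uniformly; the donor's sequence
is approximated by its parent node's resolved sequence. With rate 0 the
code path is the clonal simulator, bitwise. Every event is logged, and
the log plus the seed replays to the identical alignment. Candidate
genomes evolve from the population root (or the consensus) by JC to an
exact target divergence, optionally interleaving conversion events from
extant reference genomes; introgression injection overwrites chosen
100-bp windows of one reference genome with the candidate haplotype and
returns the truth mask.

Not emulated: indels (real concatenates contain alignment gaps; the
package handles them, the generator does not produce them), selection,
demographic structure, divergence-dependent recombination acceptance
(the pipeline, not the generator, must discover divergence effects),
and intra-gene rate variation beyond codon position. Passing the
recovery experiments therefore shows the inference machinery is
correct and calibrated under the stated model, not that real data meet
that model.

## Study conditions of the end-to-end experiments

Chosen once, on biological plausibility, and fixed:

* Generator defaults: GC 0.5, κ = 3, codon-position rates 1 : 0.5 : 3,
  900-bp genes, π ≈ 0.02 (a typical well-sampled species core genome).
* Clonality calibration: 20 clonal + 20 recombining populations, 15
  genomes × 100 kb (the 15-genome floor mirrors the framework's
  inclusion rule). The recombining arm is a *heavy* recombiner: 0.02
  conversion events/site/substitution with 15-kb mean tracts, i.e.
  long imports as seen in strongly recombining species. Long tracts
  matter for the LD arm specifically: decay length tracks tract
  length, and 1-kb tracts decay within ~3 of the 1-kb bins — invisible
  to a rank correlation across 50 bins at P < 10⁻⁴. The h/m arm
  detects 1-kb-tract recombination without difficulty; this is a
  documented limitation of the LD test at desk scale, not of the
  recombination model.
* Gene-flow verdict recovery: 31-genome references (50 kb, balanced
  genealogy so every held-out genome is exchangeable; conversion rate
  0.05, 2-kb tracts). Positives are held-out conspecifics; negatives
  are clonally diverged candidates at 10%. Small references (~10
  genomes) systematically inflate h/m_cand relative to h/m_ref because
  h/m grows with sample size and the candidate-inclusive tallies use
  n + 1 genomes — another reason for the ≥15-genome rule.
* Introgression recovery: 10-genome, 50-kb references at π ≈ 0.015,
  candidates at 10% divergence, 5% of windows injected; scanning at
  the 100% threshold. Injection itself lowers the recipient's
  within-reference identity, so even reference-monomorphic windows are
  recoverable.
* MEPS agreement: 100-kb pairs, 50 replicates per divergence,
  d ∈ {0.01, 0.02, 0.05, 0.10, 0.20}, L ∈ {20, 40, 100}; the
  Monte-Carlo band uses max(sample SEM, Poisson SEM) so near-zero
  expected counts keep a meaningful tolerance.

These sizes keep the entire experiment battery to a few minutes on one
CPU while leaving each test's discriminating margin large against its
own noise.

## Numerical and degenerate-input policy

All randomness flows through seeded NumPy generators (`seed + r` for
replicate r); runs are bit-reproducible and the CLI embeds the resolved
config and its hash in every stage's metadata, with no timestamps in
artifacts. Ratios with m = 0 are NaN and flagged; a zero resampling SD
with real > null is non-clonal with a flag; r² is clipped to [0, 1]
against floating error; consensus of an all-gap column is N; JC/K2P
corrections refuse saturated inputs rather than returning complex
values; the convergent null refuses divergence ≥ 0.75 and targets
beyond the mutable (non-N) positions.

## Known limitations

Homoplasy counting conflates reversal with parallel gain; the guide
tree is NJ, so origin counts inherit its topological errors (both
choices also apply to the simulated null, which is what the tests
compare against). The LD test is underpowered for short conversion
tracts at 100-kb scale (above). Concatenate distance stands in for
chromosomal distance, as in any concatenate-based LD analysis. The
ortholog matcher is exhaustive O(ref × cand) pairwise alignment and is
not meant for genome-scale all-vs-all searches. h/m depends on sample
size, so comparisons should hold genome counts fixed (the assessment
keeps h/m_cand and h/m_0 at equal n for exactly this reason).
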