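# Methods

`circasym` reimplements, as a tested library, the comparative-genomics
analyses used to characterize circular, asymmetrically organized viral
chromosomes of the *Marseilleviridae* type: an in-silico counterpart of the
PFGE circularity test, anchor-gene linearization, nucleotide-skew
replication-origin analysis, orthogroup-based pangenome classification with
Heap's-law openness, sliding-window gene-category density, and
infection-time-course expression timing. A seeded synthetic generator
provides planted ground truth for every stage.

## Coordinate model

Genomes are explicit `circular`/`linear` sequences over {A,C,G,T,N}. Internal
gene coordinates are 0-based half-open; GFF3's 1-based inclusive convention
is converted exactly once at the I/O boundary. A gene spanning the sequence
origin of a circular chromosome is a single record with `wraps_origin=True`
(internal start > end) rather than two split features, so it remains one unit
for density and synteny computations. `rotate_to_anchor` rotates (and, if the
anchor is on the reverse strand, reverse-complements) a circular genome so a
single-copy anchor gene — located by id or by a product-name regex defaulting
to "major capsid" — starts at position 0 on the forward strand. The applied
offset/flip is returned and exactly invertible; rotation preserves pairwise
circular distances between gene midpoints. We place the anchor on the forward
strand; nothing downstream depends on that choice beyond a global flip.

## Restriction digestion and topology testing

Recognition sites are matched on both strands with positional IUPAC
expansion; an `N` in the genome never matches. On circular genomes the scan
crosses the origin (doubled-string scan keeping matches that start before L)
and cut coordinates are reported mod L. A circular chromosome with k ≥ 1 cuts
yields exactly k fragments, a linear one k + 1; fragment lengths always sum
to L. `topology_report` digests under both topology hypotheses and compares
predicted fragment sets with observed gel band sizes at a relative tolerance
defaulting to 5% (roughly pulsed-field gel resolution); kb inputs are scaled
by 1000. Enzyme definitions (ApaI `GGGCC^C`, SwaI `ATTT^AAAT`, standard
REBASE conventions) ship as editable config so chemistry stays out of code.

## Cumulated skew and breakpoint detection

GC-skew is (G − C)/(G + C) per window, AT-skew the A/T analog; the cumulated
curve is the running sum of per-window values. Windows partition the anchored
linear frame into W near-equal pieces (default W = 100, resolving ~1%-scale
features while averaging hundreds of bases per window); windows with no
informative base get skew 0. With `normalized=True` the cumulated values are
divided by W and coordinates by genome length so genomes of different sizes
share one scale. We compute skew per window rather than per nucleotide, and
normalize the cumulated curve by W; both are conventions of this package.

Replication-origin candidates are slope changes of the cumulated curve.
They are found by exact dynamic-programming least-squares segmentation:
`cost[i, j]` is the residual sum of squares of an ordinary least-squares line
through windows i..j (minimum segment length 3), the DP minimizes total RSS
for each candidate breakpoint count 0..max_breaks, and BIC
(n·ln(RSS/n) + p·ln n with 3 parameters per additional segment) selects the
model. Segments are fitted independently rather than as a continuous
piecewise-linear function — the independence is what makes the DP exact — and
on noise-free or strong-signal profiles the selected segments are continuous
to within noise anyway. The detector is deterministic; a flat or single-slope
profile yields zero breakpoints.

The classic confounder-removal device — the "rearranged chromosome" that
concatenates all genes oriented to one strand, discarding intergenic
sequence — is provided (`build_rearranged_chromosome`, forward and reverse
variants) for transcription-bias-free skew analysis on real data.

## Pangenome classification and openness

Orthogroup tables follow the OrthoFinder `Orthogroups.tsv` dialect; annotated
genes absent from every row are wrapped as singleton orthogroups. A gene is
*core* when its orthogroup has a member in every genome, a *paralog* when the
orthogroup has ≥ 2 members in the gene's own genome (so per genome,
single-copy + paralog = total), and *strain-specific* when its orthogroup is
confined to one genome and survives a cross-genome similarity back-check
(callers may pass a precomputed hit list; ORFans are the strain-specific
genes without external homolog annotations). Core percentages are percentages
of total annotated genes, rounded half-up for the printed-table analog.

A minimal protein clusterer (shared 5-mer fraction of the shorter sequence,
single-linkage components at a similarity threshold, default 0.5) stands in
for alignment-based orthology on synthetic data. It is a coarse proxy that is
only sensitive at shallow divergence (k-mer identity decays as roughly
(1 − d)^k); deeply diverged orthologs require alignment-based search, which
is out of scope, and real-data runs should supply OrthoFinder tables.

Rarefaction enumerates all genome orderings when N ≤ 8 and uses seeded random
permutations (default 1000) otherwise; pan(k)/core(k) are orthogroup counts
present in any/all of the first k genomes. Heap's law is fitted on the mean
new-orthogroup increments Δ(k) = pan(k) − pan(k−1) by least squares of
log Δ on log k (k ≥ 2, Δ > 0), giving κ·k^(−α); α < 1 is reported as an open
pangenome, and a saturated curve (no growth past the second genome) as closed
with α = ∞. Different pangenome tools differ in fit details, so α on real
data may differ slightly between implementations.

Gene-order comparison is restricted to orthologs single-copy in both anchored
genomes, mapped as a signed circular permutation (sign = relative strand). A
circular adjacency of genome A not preserved with consistent orientation in B
is a breakpoint (position reported as the A-side junction gene's normalized
midpoint); an ortholog with flipped relative orientation is an inversion.

Annotation QC compares each genome's inferred protein lengths (CDS nt/3 − 1)
against the pooled other genomes by Mann–Whitney and flags genomes that are
both strongly significant (default p < 1e-10) and short on average (default
mean < 120 aa) — the signature of an over-called, possibly mis-assembled
genome that should be excluded from comparisons.

## Regional densities and comparisons

Each gene's position is its wrap-aware midpoint divided by genome length.
Category density is computed in windows sliding circularly on [0, 1) (default
width 0.05, step 0.01 — about 20 genes per window at these gene densities) as
the *fraction* of the window's genes belonging to the category, which makes
rows comparable across genomes with different gene counts. Each genome row is
converted to z-scores by median centering and standard-deviation scaling
(MAD scaling available), so a constant row maps to zeros and z values need
not sum to zero. Rows are ordered by clade so related genomes sit together,
as in the usual heatmap presentation.

A fixed boundary (default 2/3 of the anchored genome) partitions genes into
the `core_region` (rightmost third) and `other_region`. Region-wise numeric
comparisons (e.g. per-gene dN/dS ω from an input table) report means/sds and
a two-sided Mann–Whitney p; regional GC content excludes Ns and reports to
0.1%; category overlaps (e.g. core genes among virion-associated proteins)
are 2×2 tables with two-sided Fisher exact tests, with virion labels
transferable to unproteomed genomes through orthogroups.

## Expression timing

Counts per gene and timepoint are normalized to TPM
(10⁶·(c_g/l_g)/Σ_h(c_h/l_h) per sample; all-zero samples stay zero), log
transformed with a +1 pseudocount — the pseudocount is ours, since zeros
exist in real count tables — and row-scaled (gene mean subtracted, divided by
gene sd). Timing classes come from k-means (k = 3, 50 restarts, k-means++
seeding at a fixed seed) under Spearman distance, realized exactly as
Euclidean k-means on z-scored rank vectors: 1 − ρ is proportional to the
squared Euclidean distance between standardized ranks, so the centroid
update is exact for that metric. Clusters are labelled by their mean
profile: peak ≤ 2 h post-infection → early; peak ≥ 4 h with expression
sustained through the end of the cycle → late; otherwise intermediate (ties
broken by peak order so the three labels stay distinct). Genes with constant
(all-zero) profiles are excluded from clustering and reported as
`unclassified`. Region×class tables are tested by Pearson chi-square without
continuity correction (Fisher on request for 2×2); per-gene total and maximal
log(TPM+1) are compared between regions by pooled-variance t-tests.

## Statistical kernels

All tests are two-sided. Mann–Whitney uses the normal approximation with tie
and continuity correction; chi-square uses no continuity correction (the
convention under which the published 2×3 timing table reproduces its printed
p-value); Fisher is the exact hypergeometric tail sum; the t-test is
pooled-variance with natural zero-variance limits (equal means → p = 1,
unequal → p = 0). Implementations wrap scipy.stats; the test suite checks
them against independent oracles (full permutation enumeration of U for
n,m ≤ 8, Σ(O−E)²/E, closed-form hypergeometric sums). No multiple-testing
correction is applied anywhere.

## Synthetic data generator

The generator emulates the genome organization the pipeline detects, with
every label recorded as ground truth. Study conditions (defaults): 12 genomes
in 5 clades (3,3,2,2,2); ~360 kb genomes with 500 genes; 54% core genes; 3%
strain-specific genes per genome; 20% paralog copies; replication origin at
0.8 of the anchored frame; AT-skew amplitude θ = 0.10 and GC-skew 0.05 around
GC content 43.7%; three rearrangements (inversions/translocations of 5–20
gene blocks) per clade, confined to the leftmost two thirds; nine timepoints
at 0,1,2,4,5,6,8,10,12 h post-infection with late-class probability 0.70
inside the core region versus 0.44 outside (full class mixtures taken from
the published per-region counts); negative-binomial counts with dispersion
0.1; ω per gene lognormal with region means 0.097/0.156 (σ = 0.4); 100
virion-associated genes of which 83.5% are core.

Construction: the conserved tail (rightmost third) carries the core families
in fixed order at ~445 nt pitch (genes 300–390 nt); the accessory section
carries paralog pairs and clade-partial single-copy families (450–750 nt,
~1 kb pitch) plus per-strain fresh random genes (ORFans by construction); the
single-copy anchor gene sits at position 0. Accessory families occupy 2–4 of
the 5 clades, which makes expected per-genome totals match the configured
fractions and keeps the pangenome open. Sequence evolution is
substitution-only (clade edges 0.12, strain edges 0.04 substitutions/site,
duplicates diverged 0.02 at birth), so orthology and tail coordinates are
exact by construction; substitutions resample from the position's composition
model, preserving the planted skew. The composition switch sits at a fixed
distance from the genome end inside the conserved tail, so every strain's
realized origin fraction (recorded per genome in the ground truth) stays near
0.8 despite gene-content differences. Genomes are emitted in a random
rotation and random orientation, as an assembler would produce them, with the
applied transform recorded.

Chosen-once parameters the study system does not pin down: divergence levels
(tuned to the intra-/inter-clade identity contrast typical of the family),
gene-length ranges, block sizes of rearrangements, NB dispersion, and the
class archetype profiles — an early bump at 1 h (σ 0.8 h), an intermediate
bump at 3.5 h (σ 1.3 h), and a late sigmoid rising at 6 h (scale 1.5 h),
consistent with the timing windows the classes describe (early peak 1–2 h,
intermediate activity 1–4 h, late from ~4 h sustained). On the 9-point
sampling grid, bumps much earlier than these are indistinguishable in rank
space, so the profiles were chosen to make the planted three-class structure
actually present in the emitted data.

What the generator does **not** emulate: indels and real rearrangement
breakpoint reuse, codon structure and transcription-coupled skew, HGT,
sequencing noise in the genome sequences, and library-size variation beyond
NB dispersion. Passing recovery tests therefore demonstrate correctness of
the analysis logic under the planted model, not robustness to every artifact
of real assemblies; real-data runs consume externally produced annotations,
orthogroups, counts and ω tables through the same interfaces.

## Numerical and degenerate-input choices

Window boundaries use rounded `linspace`, so windows differ by at most one
base; the wrap window of the anchored frame is assigned to the end. Zero
denominators (empty skew windows, empty density windows, constant z-score
rows, constant expression profiles) map to 0 rather than NaN, with flags
where the distinction matters. Percentages in printed-table analogs round
half-up. Segmentation BIC ties prefer fewer segments. All randomness flows
through `numpy.random.default_rng` seeds recorded in outputs; pipeline runs
write a manifest with seed and config hash, and reruns are checksum-identical.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the generator at its default
12-genome/360 kb conditions for the headline recoveries (origin position over
10 seeds, openness over 10 seeds, classification fractions, density contrast,
synteny confinement, timing enrichment), and at a 6-genome/72 kb scaled
configuration for unit-level checks; the digest oracle comparison uses 1000
random circular instances up to 5 kb plus a synthetic full-length (376,207
nt) two-site chromosome. These sizes are the package's choices for fast,
deterministic verification.
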