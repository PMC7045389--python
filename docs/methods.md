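# Methods

`viromeshare` re-implements, as a tested and reusable library, the contig-level
comparative analysis used for pooled gut-virome studies: quality filtering of
reads, greedy overlap-consensus assembly, nucleotide homology search between
per-sample contig databases, a resampling test of within- vs between-group
virome overlap, Jaccard/PCoA/PERMANOVA beta diversity, a Shannon-type alpha
diversity over homologous-contig clusters, and functional/family profiling of
phage communities (integrase vs lysin content, caudovirus vs *Microviridae*
composition, G+C). A synthetic study generator with complete ground truth
stands in for deposited sequencing data so that every statistic can be checked
for recovery.

## The synthetic study generator

**Design.** One pooled sample per group × timepoint. The default layout is a
murine diet-switch study: four groups (CTL, STAT, CTL-COHO, STAT-COHO) sampled
at weeks 4, 5, 15 (normal chow) and 16, 28 (high-fat diet, HFD). Pooling is
modeled at the group×week level (matching pooled designs in which several
animals contribute to one sequenced sample); within-pool animal-level
heterogeneity is deliberately not modeled, as it is unrecoverable from pooled
data.

**Virus templates.** Each template is a random genome (1.5–2.6 kb here — a
deliberately small stand-in for phage genomes that keeps homology search
desk-fast; lengths are configurable) with an exact G+C count at its target,
non-overlapping gene intervals (250–500 nt) labeled with structural
(capsid/head, portal, tail, baseplate, sheath, collar), replication,
transposition or restriction/modification categories, and a lifestyle marker:
temperate templates carry an integrase, lytic phage templates a lysin,
non-phage (eukaryotic-virus) templates neither. A fixed sub-genomic *window*
(default 800 nt) per template is what samples realize as a contig, so two
samples drawing the same template emit homologous contigs covering the same
gene complement.

**Sharing model.** Within a diet regime the template supply is layered: a
regime-wide common pool, one pool per group, and sample-private templates.
Each sample includes each pool template independently with inclusion
probability ρ (`pool_inclusion`, default 0.80) and is topped up with private
templates to exactly `n_viruses_per_sample` (default 250). Pool sizes are set
to `s·n/ρ²` so that expected pairwise shared-template fractions equal
`sharing_within` for same-group same-diet pairs and `sharing_between` for
different-group same-diet pairs; pairs across the diet switch share nothing
(strong turnover, the regime the diet-signal analyses probe). Realized sharing
fluctuates binomially around the targets — this fluctuation is load-bearing
for the permutation test's calibration (below). An optional per-sample
propensity spread (`propensity_sd`, default 0) widens pair-to-pair dispersion
toward the ±10–17-point spreads reported for real pooled viromes.

**Abundance and reads.** Per-contig read counts are a multinomial draw of
`reads_per_sample` over log-series weights (long-tailed, emulating a few
highly abundant members such as *Microviridae* under MDA amplification; the
shape is a knob, and MDA bias itself is not otherwise modeled). Contig
sequences are template windows with i.i.d. substitutions at rate 0.005 —
well below the 0.02 divergence at which the 98%-identity assembly/homology
rules would stop recognizing "the same virus" in two samples. Optional read
emission tiles each contig with its read count of reads (clipped-normal
lengths, mean 216 nt) for end-to-end QC+assembly tests.

**Diet effect.** The HFD regime pool differs in family mix (caudovirus
families down, *Microviridae* and eukaryotic viruses up), temperate fraction
(0.8 → 0.2, driving the integrase decline), and G+C target (0.41 → 0.445).

**Annotation fixtures.** `emit_annotation_fixture` writes ranked
protein-style hits (13-column tabular rows) for every gene interval a contig
covers: true hits carry the gene-category keyword and the bracketed family
label at E-values past both cutoffs; with probability `noise` a hit is
corrupted to a "hypothetical protein" decoy, and every contig receives an
additional low-ranked decoy. This stands in for a translated search against
an external protein database so the annotation module is testable offline.

**What passing tests do not show.** The generator produces clean
substitution-only divergence, perfectly indexed families, no chimeras, no
amplification bias, and gene-interval annotations that the fixture mirrors
exactly at noise 0. Recovery on these studies demonstrates correctness of the
computations, not robustness to real-world annotation sparsity or assembly
artifacts.

## Read QC

Quality trimming is the running-sum (Mott) rule: each base contributes
`limit − p_error` and the read is clipped to the maximal-scoring contiguous
segment (ties resolved leftmost). The default `limit = 0.5` reads the
"modified Phred score of 0.5" convention of workbench-style trimmers as an
error-probability threshold; because that phrasing is ambiguous across
vendors the limit is a parameter. Reads then pass pure per-read predicates —
length within [150, 300] nt, no homopolymer of ≥8 identical bases, no
non-ACGT character (N counts as ambiguous wherever it appears) — applied
after trimming, since trimming is listed first in the protocols this
implements. Host screening removes reads with any hit at E < 1e-5 against a
host index (built by the homology module) or an imported hit table; the host
reference itself is never bundled.

## Assembly

Greedy overlap-layout-consensus, not de Bruijn: the parameters of the target
protocol (98% identity over ≥50% read overlap, 25-nt absolute minimum) are
OLC-style, and best-overlap-first merging makes the algorithm deterministic.
Candidate offsets come from shared 15-mers; overlaps are ungapped offsets
scored by column identity. The fractional overlap requirement applies to the
shorter of the two sequences being merged but is capped at the longest input
read length: the 50% rule is a *read*-overlap rule, and without the cap a
growing consensus would demand ever longer overlaps and low-coverage tilings
could never close. Consensus is per-column majority with ties broken in the
fixed order A < C < G < T; reverse-complement overlaps are allowed and the
final contig is reported in canonical (lexicographically smaller)
orientation. Contigs under 200 nt or containing ambiguity are dropped with
their reads counted unplaced; singletons ≥200 nt are kept by default (flag to
drop). A post-hoc validator re-aligns every member read against the consensus
at the identity threshold.

## Homology search

A seed-and-extend nucleotide aligner in the BLASTN mould: exact k-mer seeds
(default k=11, both subject strands indexed), optimal ungapped extension
along each seed diagonal (the maximal-scoring segment through the seed,
computed exactly from cumulative sums), and greedy chaining of collinear
segments across diagonal shifts ≤20 with affine gap costs — the gapped step.
Scoring is +1/−2 with gap open −5 / extend −2, and significance is
Karlin–Altschul: `bits = (λS − ln K)/ln 2`, `E = m·n·2^(−bits)` with λ=1.33,
K=0.621 (the classic ungapped DNA calibration; the protocol this serves fixes
only thresholds — 1e-10 cross-virome, 1e-5 host/functional — not the
scoring). The effective search space uses raw lengths with no edge
correction, a deliberate simplification. Directed sharing A→B (fraction of
A's contigs with ≥1 admissible hit in B) is asymmetric; both directions are
always computed. `cross_compare` searches every contig once against one
combined index and derives all ordered-pair shared sets, which is equivalent
to per-pair databases but linear in total contigs. Externally computed
12-column tabular hits can replace the built-in engine at every consumer.
Contigs (not reads) are the query unit for cross-virome comparisons, matching
databases built after assembly.

On independent random 300-nt pairs the engine reports zero hits at E < 1e-10
(null-simulation test), and on the generator's 0.005-substitution copies it
recovers shared templates essentially perfectly — measured shared fractions
track the ground truth to within a contig or two.

## Overlap permutation test

For a factor grouping the samples (diet, timepoint, cohousing, antibiotic
exposure), each iteration subsamples `n_contigs` (default 1,000; 10,000
iterations) from the query virome of each ordered pair and compares the
within-group and between-group shared-homologue fractions;
`P = (1 + #{between ≥ within}) / (n_iter + 1)`. Ties count toward P
(conservative; strict mode available) and the add-one smoothing keeps P
positive, invisible at two printed decimals. Incidence (which contigs of A
have a homologue in B) is precomputed once, so iterations are pure
resampling.

Two per-iteration statistics are offered. The default (`pair_mode="average"`)
averages over every pair, drawing a fresh subsample per pair evaluation; the
alternative (`pair_mode="resample"`) draws one random within pair and one
random between pair per iteration, which reproduces the large ±SD spreads
printed for real pooled viromes (those spreads are pair-to-pair dispersion,
far larger than resampling noise at depth 1,000) but is extremely
conservative as a test — with pair redrawing, P approximates the probability
that a random between pair out-shares a random within pair, which rarely
falls below 0.05 under the null.

**Calibration.** The averaged mode is a parametric-bootstrap-style test:
contig resampling re-enacts the binomial sampling of templates into pooled
samples, so the test is calibrated exactly when resampling noise matches
construction noise. Two knobs set that balance and were fixed by a null
calibration study during design: a fresh subsample per pair evaluation
(sharing one subsample per sample across pairs cancels too much noise between
correlated pairs and inflates type-I; fully shared → 0.11, fresh →
nominal), and `pool_inclusion = 0.80` at the default virome size of 250
contigs against a test depth of 100. At these settings the measured type-I
error over 200 null studies is 0.045 at nominal 0.05, and power at the
within-0.7/between-0.4 regime with 5 samples per group is 1.00 over 100
studies. These operating characteristics are re-measured by
`scripts/acceptance.py` on every run.

## Alpha and beta diversity

The homologous-virus diversity index (HVDI) is a read-weighted Shannon
entropy over clusters of mutually homologous contigs within one virome:
single-linkage connected components over admissible self-hits (same E < 1e-10
threshold as cross-virome comparisons), cluster weight = summed member read
counts, `H = −Σ p ln p` (natural log by default; the base is recorded). The
cluster construction is a reconstruction — the source protocol names the
index only as "based on Shannon diversity" — and is flagged as such here.

Jaccard distance for a pair combines the two directed shared counts,
`s = (|A→B| + |B→A|)/2` by default (min/max selectable), `u = |A| + |B| − s`,
`d = 1 − s/u`. PCoA is the eigendecomposition of the Gower-centered squared
distance matrix; coordinates are eigenvectors scaled by √eigenvalue for
positive eigenvalues, axis signs fixed by making each axis's
largest-magnitude loading positive, and negative eigenvalues counted but
excluded from variance proportions.

PERMANOVA partitions the same centered matrix by sequential (Type-I) sums of
squares — the adonis default — for one- or two-factor models with
interaction, in the caller's term order (diet before time for `~ diet ×
time`). Pseudo-F per term uses the full-model residual; p-values come from
seeded label permutations with add-one smoothing. Rank-deficient terms (an
interaction aliased with its margins, as happens when diet is a function of
week) get zero degrees of freedom and R² = 0 rather than an error. The
implementation agrees with vegan's `adonis2` term-by-term on fixtures (test
suite) and with exhaustive enumeration of all 720 label permutations at n=6.

## Annotation profiles

Functional categorization walks a contig's hits best-first and returns the
category of the first description matching a functional keyword at E ≤ 1e-5,
deliberately skipping past no-function best hits as long as a lower-ranked
functional hit still passes — so a contig whose best hit is "hypothetical
protein" is still categorized by its next informative hit. Family is parsed
from the bracketed organism of the best-ranked virus hit at E < 1e-20;
superkingdom (virus/bacterium/none) from the best passing hit. The keyword
taxonomy ships as a versioned, editable text file
(`src/viromeshare/data/keywords.tsv`); the exact lists behind the original
annotation tooling are unpublished, so these are a documented
reconstruction. Holin is its own category: timing proteins are not cell-wall
hydrolases and must not inflate lysin counts.

Family profiles weight contigs by read count, by 1, or by read counts floored
to the study-wide smallest sampling depth (depth normalization changes
results only through discretization — low-weight contigs floor to zero).
Lifestyle statistics count a contig as integrase- or lysin-positive when any
passing hit falls in the category (profiles of "contigs with integrase
homologues"), with the integrase:lysin ratio flagged undefined — not
infinite — when lysins are absent.

## Numerical and degenerate-input conventions

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical FASTA/metadata output and bit-identical test
  statistics.
- Permutation p-values are never 0: `(c+1)/(n+1)` throughout.
- Zero residual in PERMANOVA (perfect separation) yields pseudo-F = +inf with
  tie-counting, not an error; an all-zero distance matrix yields R² = 0 and
  p = 1.
- `gc_content` excludes ambiguous bases from the denominator and rejects
  sequences with none left; Shannon terms with p = 0 contribute 0.
- Majority-rule ties in consensus break A < C < G < T; equal-scoring trim
  segments resolve leftmost; greedy assembly ties break by unit index.

## Problem sizes

Default benchmark sizes were chosen to run in minutes on one core: 250
virus templates per sample for statistical studies (vs thousands of contigs
in real pooled viromes), 40–120 for sequence-level studies, 800-nt contig
windows, 1,000 test iterations at depth 100 in the calibration suites (the
full 10,000 × 1,000 defaults remain available and are pure resampling). The
acceptance script re-runs everything, including the 200-study null
calibration, in roughly ten minutes.

## Known limitations

- The aligner has no full gapped DP; indel-rich homologs rely on chaining or
  on imported external hits.
- The assembler is quadratic in read pairs and intended for per-sample pools
  at study scale, not shotgun-scale read sets.
- Depth normalization by integer flooring is one of several defensible
  readings of "normalized to the smallest sampling depth".
- The HVDI clustering rule and the keyword taxonomy are reconstructions, as
  flagged above.
- Cross-diet sharing is fixed at zero in the generator; a carry-over knob
  would be needed to study partial community turnover.
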