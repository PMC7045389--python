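# viromeshare

Comparative analysis of phage communities ("viromes") at the contig level,
for microbiome researchers who sequence purified virus-like particles from
pooled samples and want to ask: *do viromes share more homologous viruses
within a treatment group than between groups, and how does community
composition shift across an intervention such as a diet switch?*

The package implements the full analysis chain as a tested library:

- **read_qc** — Mott running-sum quality trimming (`limit − p_error`
  cumulative score), length [150, 300] nt, ≥8-homopolymer and ambiguity
  filters, pluggable host screening (E < 10⁻⁵).
- **assembly** — greedy overlap-layout-consensus at ≥98% identity over ≥50%
  read overlap (25 nt minimum), majority-rule consensus with A<C<G<T
  tie-breaking, contigs <200 nt dropped.
- **homology** — seed-and-extend nucleotide search with Karlin–Altschul
  E-values (`E = mn·2^{−(λS − ln K)/ln 2}`, +1/−2 scoring, λ=1.33, K=0.621),
  both strands, 12-column tabular hit import/export, directed shared
  fractions between virome pairs at E < 10⁻¹⁰.
- **overlap_permutation** — the resampling test of within- vs between-group
  overlap: subsample contigs per iteration and report
  `P = (1 + #{between ≥ within}) / (n_iter + 1)` with within/between means ±
  SD as a publication-style table.
- **community_metrics** — homologous-virus diversity index
  (`H = −Σ pᵢ ln pᵢ` over read-weighted single-linkage clusters of
  homologous contigs), Jaccard distances
  (`d = 1 − s/(|A| + |B| − s)`, s = mean of the two directed shared counts),
  G+C content.
- **ordination_stats** — PCoA (Gower double-centering, eigendecomposition),
  sequential-SS PERMANOVA for `~ diet × time` with permutation p-values,
  Welch t test, one-way ANOVA + Tukey HSD, Pearson correlation.
- **annotation_profiles** — keyword-based functional categories (structural
  genes, integrase, lysin, …; E ≤ 10⁻⁵ with fallback past "hypothetical"
  best hits), virus-family calls from best hits at E < 10⁻²⁰, read-weighted /
  contig-counted / depth-normalized family profiles, integrase:lysin
  lifestyle statistics, superkingdom read fractions.
- **synthetic_data** — a virome-study generator (virus templates with gene
  layouts and lifestyles, layered sharing pools, diet-shift effects on
  family mix / temperate fraction / G+C, log-series abundances, optional
  reads and ranked annotation fixtures) that records complete ground truth
  for every downstream statistic.

## Worked example

Simulate a two-group diet-switch study (60 viruses per pooled sample, weeks
4–15 on normal chow, 16–28 on high-fat diet), compare all viromes by
homology, and test diet structure:

```python
from viromeshare import synthetic_data as syn
from viromeshare.homology import cross_compare
from viromeshare.community_metrics import jaccard_matrix
from viromeshare.ordination_stats import permanova
from viromeshare.overlap_permutation import (
    GroupingScheme, incidence_from_shared_sets, overlap_test, summarize_table)

design = syn.StudyDesign(groups=("CTL", "STAT"), n_viruses_per_sample=60, seed=7)
viromes, truth, pool = syn.generate_study(design)

shared = cross_compare(viromes)                      # all-pairs homology
d = jaccard_matrix(viromes, shared)                  # beta diversity

scheme = GroupingScheme("diet", {s: v.diet for s, v in viromes.items()})
inc = incidence_from_shared_sets(viromes, shared)
rows = overlap_test(viromes, inc, scheme, n_iter=1000, n_contigs=50, seed=7)
print(summarize_table(rows).to_string(index=False))

res = permanova(d, {"diet": [viromes[s].diet for s in d.ids],
                    "time": [str(viromes[s].week) for s in d.ids]},
                n_perm=999, seed=7)
print(res.to_frame().round(3).to_string(index=False))
```

Output:

```
factor  group   pct_within pct_between p_value  significant
  diet normal 49.88 ± 0.49 0.00 ± 0.00    0.00         True
  diet    HFD 50.27 ± 0.83 0.00 ± 0.00    0.00         True
     term  df    SS    R2     F     p
     diet   1 1.554 0.466 5.377 0.005
     time   3 0.337 0.101 0.389 1.000
diet:time   0 0.000 0.000   NaN   NaN
 Residual   5 1.445 0.433   NaN   NaN
```

Reading it: within either diet, viromes share about half their contigs with
each other (the study was built with 50%+ same-diet sharing) and nothing
across the diet switch, so the overlap test rejects for both diet groups
(P = 1/1001, printed to two decimals). In Jaccard space the diet term
explains 47% of the variance (p = 0.005) while time within diet explains
little; the interaction is aliased (diet is a function of week) and gets 0
degrees of freedom, as in vegan's sequential decomposition.

The same steps are scriptable from the shell:

```bash
viromeshare simulate --out study/ --seed 7 --groups CTL,STAT --n-viruses 60
viromeshare overlap-test --study study/ --factor diet --iterations 1000 --contigs 50 --seed 7
```

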