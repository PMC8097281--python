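# Methods

`ploidyscan` implements a selection-scan and haplotype-origin analysis for
mixed diploid/autotetraploid resequencing panels, together with a synthetic
data generator that plants known signals for end-to-end validation. This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## The analysis

### Frequencies, filters and polarization

All statistics operate on derived-allele frequencies computed from genotype
dosages (0..ploidy copies of the derived allele). Genotypes with read depth
<= 8 are treated as missing; variants missing in >= 50% of any lineage are
dropped. Frequencies use AC/AN semantics: a partially missing genotype
contributes to neither numerator nor denominator, so the effective
chromosome count varies by site and is carried through to every estimator.

Polarity comes from an outgroup-consensus state when available (the `AA`
INFO tag of the VCF); otherwise the overall minor allele is taken as
derived, with exact 50/50 ties resolved to ALT and logged. For scans, each
diploid lineage is subsampled to 32 chromosomes (16 individuals, by highest
mean depth) and the tetraploid lineage to 160 chromosomes, balancing the
two ploidies at 160 chromosomes each.

### Differentiation scan

Per-SNP Hudson F_ST in the ratio-of-estimates form

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1),  F_ST = N/D

is computed for every missense site in two scan types: pooled diploids vs
tetraploids ("ploidy"), and all 10 diploid lineage pairs. The outlier
threshold for each contrast is the empirical 99th percentile (type-7
linear interpolation) of F_ST over synonymous SNPs genomewide — a
"neutral" null distribution that is conservative relative to the missense
one. Negative F_ST values are retained; they matter only below threshold.

### FineMAV

The per-site FineMAV score is `f_max * DAP^3.5 * C`, where `f_max` is the
largest group derived frequency, `DAP = f_max / sum(f)` is the derived
allele purity, and `C` is a functional score — the Grantham physicochemical
distance of the amino-acid pair, or the rescaled SIFT score (1 - raw, so 1
is most deleterious). Sites with no SIFT database entry are scored on
Grantham alone. The DAP exponent (3.5) is exposed in configuration.

The groups entering the DAP term follow the contrast: the five diploid
lineages for the diploid scan, and {pooled diploids, tetraploids} for the
ploidy scan. The alternative — a single six-lineage grouping for both scan
types — makes an allele shared by the tetraploids and one diploid lineage
(a parallel sweep) top out at DAP = 0.5, and `0.5^3.5 ~ 0.09` pushes every
such site out of the top-1% tail regardless of frequency or functional
score. Per-contrast groups keep purity meaningful for the question each
scan asks.

A site is a **candidate** when it exceeds its contrast's F_ST threshold and
the genomewide 1% FineMAV quantile for Grantham and (when available) for
SIFT. Candidates from the 10 diploid pairs are unioned and attributed to
the higher-frequency lineage. Gene-set (e.g. meiosis-gene) enrichment among
candidate genes is a two-sided Fisher's exact test.

### Modified McDonald-Kreitman test

Between a young autotetraploid and its diploid source there are virtually
no fixed differences, so divergence is redefined: sites in the upper 1% of
the diploid-tetraploid allele-frequency difference (AFD) count as
divergent; other sites are polymorphisms. Variants with overall derived
frequency < 0.15 across the combined panel are excluded to damp the
contribution of slightly deleterious segregating variants. With per-gene
and genomewide counts, `alpha = 1 - (Ds*Pn)/(Dn*Ps)`; significance is a
two-sided Fisher's exact test on the 2x2 table (per-gene counts are small,
so a chi-square approximation would be inappropriate). The AFD threshold is
recomputed from the data at hand and can be overridden in configuration.
Divergent sites are never double-counted as polymorphic. At the scale of
the bundled synthetic studies a single panel yields only ~50-80 divergent
sites, so alpha has a sampling sd near 0.25; calibration checks therefore
pool counts over replicate panels.

### De novo versus standing variation

A gene's candidate sites define a haplotype; three criteria must all hold
to call the tetraploid haplotype de novo:

* **A** — at least one candidate derived allele is absent from every
  individual of the full (unsubsampled) diploid panel;
* **B** — no diploid individual carries the derived allele at *all*
  candidate sites simultaneously (genotype co-occurrence; short-read
  mixed-ploidy data cannot be phased reliably, so phased haplotypes are
  deliberately not used);
* **C** — the diploid-tetraploid Hamming distance exceeds the diploid
  Hamming diameter.

Genotypic distance is a coarse 0/1 call per site, transcribed as explicit
lookup tables: diploid pairs differ only as opposite homozygotes
(|dosage difference| = 2); tetraploid pairs only when dosages differ by
>= 3; cross-ploidy pairs only when the diploid is homozygous and the
tetraploid carries <= 1 copy of the diploid's allele. The Hamming distance
sums these calls across a gene's candidate sites; the diameter is the
maximum within-group pairwise distance. Missing genotypes contribute 0
(they cannot assert a difference), and individuals missing more than half
of a gene's candidate sites are excluded from that gene's analysis.

The between-ploidy distance defaults to the **median** over all
diploid x tetraploid pairs (`min` is available in configuration). The
minimum is tempting as the most conservative reading, but under tetrasomic
inheritance a single tetraploid that carries only 0-2 copies of the swept
haplotype — a simplex or duplex genotype, expected in any realistic sample
— has distance 0 to every diploid, so the minimum answers a question about
the least-swept individual rather than about the haplotype.

Haplotype frequencies are reconstructed per population from M_i, the
population frequency of the allele that is major in the combined sample
(the panel is diploid-dominated by design, so the major allele is the
ancestral, diploid-like one): HAFd = min M_i, HAFa = 1 - max M_i,
HAFr = 1 - HAFd - HAFa. The triple always sums to one and each term lies
in [0,1] because min M <= max M.

A rarefaction analysis reports, for increasing diploid sample sizes, the
mean fraction of segregating diploid variants recovered over random
subsamples — the empirical answer to "was the diploid panel large enough
to exclude standing variation".

### Sweep ages and multinucleotide mutations

The relative sweep-age proxy is the count of segregating tetraploid SNPs
strictly between a gene's first and last candidate site (candidates
excluded), divided by that span in bp; a hard sweep clears linked variation
and new mutations accumulate with time, so a higher ratio means an older
sweep. "Segregating" is evaluated on the subsampled tetraploid panel
(0 < derived frequency < 1), a deterministic matrix-level definition.
Genes are ranked by descending ratio with min-rank ties.

MNM evidence per gene combines (i) a Wilcoxon rank-sum test of consecutive
candidate spacings against consecutive missense spacings genomewide
(consecutive, not all-pairs, within genes only; exact null below 20 total
observations, normal approximation with tie correction otherwise), and
(ii) a one-sided two-proportion z test for transversion excess over the
genomewide transversion fraction. The MNM flag requires both tests below
0.01 and the candidate median spacing to actually be shorter. At small
candidate counts the z test is discrete and its realized level wobbles
around nominal (between ~3% and ~8% depending on set size), which is why
calibration checks average over a range of set sizes.

### Conservation

Pairwise alignment identity (PAI) of an ortholog-MSA column is the
fraction of unordered sequence pairs with identical residues; pairs
involving a gap count as non-identical (a gap is zero identity), with a
gap-excluded variant available for sensitivity. Protein positions map to
columns through the reference sequence's non-gap residues. The contrast
compares PAI at tetraploid-exclusive candidate sites (ploidy-contrast
candidates minus those shared with the diploid scan) against diploid-scan
candidate sites, by two-sided Wilcoxon rank-sum.

## The synthetic data generator

The generator emulates a range-wide panel of a diploid/autotetraploid
complex: five diploid lineages (14 populations, 8 individuals each; 224
chromosomes) and one autotetraploid lineage (11 populations, 4 individuals
each; 176 chromosomes) — 156 individuals. The diploid excess is a design
requirement: HAF reconstruction assumes the combined-sample major allele is
the diploid one. Tetraploids are strictly autotetraploid (tetrasomic,
Binomial(4, f) dosages); no disomic mode exists.

Ancestral frequencies follow a neutral-like 1/p spectrum truncated to
[1/400, 1-1/400]; each lineage draws Beta(p(1-F)/F, (1-p)(1-F)/F) around
the ancestral value (Balding-Nichols drift, default F = 0.15 per lineage —
moderate range-wide differentiation; the real lineage-specific values are
unknown and the default is a free parameter). Depth is Poisson(25),
genotypes go missing at rate 0.05 plus whenever depth <= 8, so the depth
filter is genuinely exercised.

Planted signals, per the default study design (chosen once, by power
analysis against this model, then frozen):

* two **de novo** sweeps (5 candidate sites each, tetraploid haplotype
  frequency 0.9, diploid frequency exactly 0 — absence is guaranteed, not
  probabilistic);
* two **standing** sweeps (4 sites; the source diploid lineage carries the
  haplotype at a frequency drawn from [0.02, 0.15], so in some replicates
  it is genuinely unsampled — classification checks condition on sampled
  presence);
* one **parallel** sweep (4 sites at frequency 0.9 in both the tetraploids
  and one designated diploid lineage);
* one **MNM cluster** (8 clustered substitutions <= 19 bp apart on distinct
  codons, transversion probability 0.95, swept de novo). Background
  substitutions are transversions with probability 1/3.

A planted sweep is a single linked haplotype: each individual draws one
haplotype dosage per gene, reused across the gene's planted sites.
Independent per-site sampling would make haplotype co-occurrence (criterion
B) and HAF vacuous. Sweeps also clear segregating tetraploid variation
inside the candidate span and re-seed a configurable number of post-sweep
mutations, so sweep ages are orderable.

Planted amino-acid pairs are drawn from the strong tail of the Grantham
matrix (>= 180) and planted sites get raw SIFT in [0, 0.05]; background
missense sites get uniform pairs and constraint-dependent SIFT. This is
what double-outlier candidates look like by construction, and it keeps the
planted block inside the genomewide top-1% FineMAV quota (~33 of 5,000
missense sites at the default 150 genes x 60 SNPs; the planted total is
30). Each gene also gets an ortholog MSA (13-17 species): planted
tetraploid-exclusive sites sit on conserved columns (substitution
probability 0.02), parallel-sweep sites on neutral columns (0.35), so the
conservation contrast has a planted direction.

The generator writes VCF (with the ancestral allele in the `AA` tag,
emulating outgroup repolarization), annotation/popmap/SIFT/gene TSVs, the
bundled Grantham matrix, per-gene MSA FASTAs and a JSON truth record; the
whole bundle is bit-reproducible under a fixed seed.

### What the synthetic experiments show — and what they do not

Passing recovery tests shows the pipeline's statistics detect the signals
they were designed for under the generator's assumptions: free
recombination between genes, complete linkage of planted haplotypes, no
linked background selection, drift-only lineage structure with equal F, no
gene flow, annotation and polarization free of error, and functional
scores that genuinely correlate with the planted signal. Real data violate
all of these to some degree — mispolarization, uneven lineage divergence,
interploidy introgression and reference bias are specifically not
modelled — so recovery rates here are upper bounds, not field estimates.

## Problem sizes and reproducibility

Default analyses run on 150 genes x 60 SNPs (9,000 sites, 156 individuals)
in seconds. Calibration experiments use replicate panels: MK neutrality
pools 12 panels of 200 genes x 100 sites (pooled alpha sd ~0.07);
MNM detection uses 60-gene panels over 10 seeds; sweep-age ordering uses
20-gene two-epoch panels over 20 seeds. All randomness flows from a single
integer seed per run; pipeline outputs are written with fixed float
formatting and deterministic ordering, so identical configurations produce
byte-identical output trees (the run manifest hashes only scientific
parameters, not paths).

## Known limitations

* No phasing, no LD-based statistics; haplotype inference is genotype
  co-occurrence and frequency arithmetic only.
* Per-SNP F_ST outliers, not windowed scans; nearby hitchhiking sites can
  surface as (counted) false candidates attributed to the diploid side.
* The MK divergence class at desk scale contains few sites; per-gene alpha
  is reported but only pooled values are statistically meaningful.
* The genotypic-distance tables are deliberately coarse; dosage differences
  of 1-2 copies in tetraploids never register.
* The sweep-age ratio is a relative ranking, not a dating method.
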