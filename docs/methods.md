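# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical conventions, and the design choices
made where more than one reading was defensible.

## Estimators

**Weir–Cockerham F<sub>ST</sub>.** Per SNP, θ̂ is computed from the 1984
variance components for diploid data with heterozygote counts: with r
populations, per-population sample sizes nᵢ (called individuals only),
allele frequencies pᵢ and observed heterozygote frequencies hᵢ,

- a — among-population component,
- b — among-individual-within-population component,
- c — within-individual component (h̄/2),

and θ̂ = a/(a+b+c). Missing genotypes are excluded per SNP (pairwise
deletion; the data this models is GBS with ~28 % missing calls and no
imputation). SNPs monomorphic over all populations, or with an
uncallable population, are excluded from window sums. A window's value
is the ratio of sums Σa/Σ(a+b+c) over its SNPs — the standard windowed
form, which weights SNPs by information rather than averaging per-SNP
ratios. The genome-wide estimate is the mean of window values with an
empirical 95 % CI from the 2.5/97.5 window-value percentiles; the
alternative Σa/Σ(a+b+c) over all SNPs is also exposed
(`FstResult.overall_ratio`). Negative window values are retained in
averages for unbiasedness. The implementation is verified against an
independent ANOVA-mean-squares oracle (sums of squares over
per-individual allele frequencies), which reaches θ̂ by a different
computational route.

**Nucleotide diversity.** Per SNP, π̂ᵢ = (n/(n−1))·2p(1−p) over the n
called alleles — the unbiased per-site expected heterozygosity, equal to
the fraction of differing pairs among all allele pairs (the test-suite
oracle). Window value = Σπ̂ᵢ; per-kb value divides by the physical span
(last − first SNP position)/1000, reported missing when the span is
zero.

**Distances.** The proportion of differing sites p between two
accessions uses unphased allele sharing: per co-called SNP, 0 if the
dosages are equal, ½ if they share one allele, 1 if none. For group
distances, the SNP set is restricted to SNPs polymorphic in the union of
the two groups, and the group-pair entry is the mean Jukes–Cantor
corrected distance d = −¾ ln(1 − 4p/3) over inter-group accession pairs.
p ≥ 0.75 is outside the model's domain and raises; the accession-level
matrix clamps p just below 0.75 so that degenerate fully-differentiated
toy inputs remain representable. Neighbor joining is delegated to
scikit-bio; bootstrap support resamples SNPs with replacement and counts
bipartition recovery.

**LD.** r² is the composite (genotype-dosage) squared Pearson
correlation over co-called accessions — deterministic and well defined
on unphased diploids, unlike EM-phased haplotype r². Pairs need ≥ 4
co-called accessions and nonzero variance in both vectors. The 10 Mb
"window" is a maximum pairwise-distance cap. Per-population SNP
filtering (≤ 30 % missing, minor allele carried by ≥ 2 accessions) is
re-applied inside every sub-sampling replicate, since the whole analysis
is re-run per draw. Bins are half-open [lo, hi); a pair exactly on an
edge belongs to the right-hand bin. Default edges are 0–10 Mb in 100-kb
steps; coarser edges (e.g. 1-Mb) are used in tests where per-bin pair
counts must dominate noise.

Mean composite r² is biased upward by ~(1−ρ²)²/n in a sample of n
accessions. This is the reason for the equal-sample-size sub-sampling
design (12 accessions, 100 replicates, per-bin 2.5/97.5 percentile
bands), and it has a testing consequence: the n=12 CI cannot be expected
to cover a full-sample (n≫12) bin mean, which sits systematically lower.
CI calibration is therefore checked size-matched — the band from
sub-sampling a 40-accession pool must cover the bin means of an
independent 12-accession reference drawn from the same population —
aggregated over several simulated panels because a single panel offers
only ~10 bins of binomial evidence.

**Mantel test.** r is the Pearson correlation of the lower triangles;
the null permutes rows and columns of one matrix jointly;
p = (#{|r*| ≥ |r|} + 1)/(n_perm + 1). Two-sided by default (the
direction of an isolation-by-distance effect is positive, but sidedness
is a user choice); an exact enumeration over all n! permutations is
available for n ≤ 8. Accessions without coordinates are dropped before
either matrix is formed. Geographic distance is haversine on a 6371-km
sphere; a log(1+km) transform is available but off by default.

**Haplotype networks.** Accession allele vectors over the selected
variant sites (indels coded as single characters with unit weight — each
polymorphism one evolutionary event) are collapsed exact-match;
haplotypes are numbered by (count desc, sequence lexicographic) for
determinism. Network construction considers haplotype pairs in
increasing Hamming distance (ties by haplotype number) and adds a
connection of length j — with j−1 connection-private inferred
intermediates — whenever the pair is not already joined by a path of ≤ j
steps and j does not exceed the connection limit. Equal-length
alternatives encountered at the same stage are all retained, which is
what produces loops. The probabilistic derivation of the connection
limit (the statistical-parsimony probability recursion) is not
re-derived; the limit is a parameter, default 6 steps for a ~25-site
alignment. cpGroups are the connected components left after removing
connections longer than a grouping threshold; components with a single
sampled haplotype are independent haplotypes. The pipeline builds at
limit 6 and groups at threshold 2 by default — both configurable, since
building and grouping may legitimately use different limits. Ancestral
alleles require > 65 % frequency among outgroup accessions plus presence
in the ingroup; the remaining ingroup allele is derived; anything else
is unresolved.

**Domestication analysis.** The *RC* assay amplifies 236 bp spanning the
functional 14-bp deletion (deletion product 222 bp); *Bh4* amplifies
227 bp spanning its 22-bp deletion (product 205 bp); bands are matched
within ± 3 bp and scored wild / deletion / het. SNP selection around the
focal locus applies MAF > 0.05 and < 3 % missing over the two panels
combined, then a two-sided Fisher exact test on the 2×2 allele-count
table (heterozygotes contribute one allele to each class; chi-square
available as an option), keeping p < 1e−5. Fisher exact was chosen for
the unspecified "frequency test" because it is exact at small panel
sizes. The cultivated allele at each selected SNP is the majority allele
of the white-pericarp cultivated reference (ties drop the SNP);
accessions are painted cultivated / wild / heterozygous / missing. An
accession is *introgressed* when all three in-gene focal markers (two
SNPs + the 14-bp indel) carry a cultivated or heterozygous state, *wild*
when all three are wild, otherwise *inconsistent*. Phenotype/genotype
concordance treats the functional (color) alleles as dominant: red
pericarp pairs with ≥ 1 wild *RC* allele, white with homozygous
deletion; black hull with ≥ 1 wild *Bh4* allele, light with homozygous
deletion.

**Admixture and concordance.** An accession is assigned to its
maximum-ancestry group when that proportion is ≥ 0.75 (strictly below →
admixed; the boundary is assigned, matching the strict "< 75 %" reading
of the admixture rule). Concordance between subpopulations and species
labels is Pearson chi-square without continuity correction on the
group × label table, admixed accessions excluded by default. The effect
size is Cramér's V² = χ²/(n·min(r−1, c−1)), which lies in [0, 1], equals
1 exactly for a permutation-block table, and reduces to φ² = χ²/n for
two-column tables; it is the natural "r²-like" association measure for
such a table.

## Synthetic-data model

**Nuclear genotypes** follow Balding–Nichols: ancestral frequency
p ~ U(0.05, 0.95) per SNP; subpopulation k with differentiation Fₖ draws
its frequency from Beta(p(1−Fₖ)/Fₖ, (1−p)(1−Fₖ)/Fₖ) (point mass at p
when Fₖ = 0); pure accessions are Binomial(2, pₖ). Fₖ is exactly the
Weir–Cockerham estimand, so parameter recovery is a direct check.
Admixed accessions draw ancestry ~ Dirichlet(1,…,1) — which densely
spans the 0.75 threshold — and sample each allele copy from an
ancestry-weighted subpopulation. SNP positions are uniform over 12
rice-like chromosomes (23–45 Mb); missingness is uniform at the
configured rate. Defaults emulate the targeted study design: six
subpopulations (the smallest with 12 members), 72 admixed of 286
accessions (25 %), 28 % missing calls. The SNP count defaults to a
desk-scale 5 000 (statistics that need more windows can raise it).

Setting `recomb_block_bp` switches allele copies to mosaics over a small
per-group haplotype pool (default 8 haplotypes), with segment lengths
exponential with that mean — producing smoothly, monotonically decaying
r² without a recombination model. Caveat: the finite pool acts as extra
drift, inflating realized differentiation by roughly 1/pool-size above
the nominal Fₖ; parameter-recovery checks therefore use the
independent-SNP generator, and LD analyses the mosaic one.

**Geography** gives each subpopulation a centroid scattered around a
common base point (SD `centroid_spread_km`, default 2000 km — continental
scale) and jitters members around it (default 100 km); admixed
accessions sit at their ancestry-weighted centroid average, so genetic
and geographic distance correlate by construction.

**Chloroplast haplotypes** use stepwise mutation from a root: each
subpopulation founder derives `theta_cp` (default 3) group-private
sites; the first member of each group carries the founder exactly (so
every founder is a sampled network node) and later members add 0–2
further steps on reserve sites; outgroups share a 6-step divergence path
on outgroup-private sites; close-relative accessions carry the root.
Site 1 is a deletion analog (I/D) and site 2 a SNP nested inside it
(A/G), deriving in different subpopulations — mirroring the classic
chloroplast deletion polymorphism with an internal SNP found in
non-deletion types. The geometry guarantees founder clades are ≥ 2·3
steps apart while within-clade connections are ≤ 2 steps, so grouping at
threshold 2 recovers exactly the simulated clades.

**The domestication panel** plants a focal locus with a block of 40
near-fixed differentiated SNPs within ± 290 kb (including two in-gene
SNPs flanking the indel), background SNPs with shared frequencies, a
white-pericarp cultivated reference (n = 30), red-pericarp wild
accessions (n = 70), and a known set of introgressed accessions
(n = 10) carrying the deletion plus a homozygous cultivated block and
white pericarp. Optional planted discordants emulate seed-stock
heterogeneity (phenotype/genotype mismatches).

What the generators deliberately do **not** model: realistic site
frequency spectra or mutation-rate calibration, selection,
linked-selection or demographic history (no coalescent), genotyping
error beyond uniform missingness, and correlated missingness across
accessions or loci. Passing tests demonstrate that the estimators
recover the parameters of this statistical model at the configured
sizes; they do not certify behavior on real GBS data with structured
missingness or reference bias.

## Numerical conventions and reproducibility

- Dosages are alternate-allele counts in {0, 1, 2}, −1 for missing;
  phase is ignored everywhere; heterozygous dosage is 1.
- Positions are 1-based; intervals closed (VCF convention); multi-allelic
  sites are dropped at load, not split; chromosomes sort
  lexicographically everywhere, including in the generators, so written
  files re-read to identical objects.
- Filtering thresholds: call rate strictly > 0.5 (a SNP called in
  exactly half the panel is removed); MAC ≥ 4 over called alleles.
  Fractional thresholds compared with a 1e−9 epsilon to avoid float
  artifacts at boundaries like 30 % missing.
- All stochastic procedures take explicit integer seeds
  (`numpy.random.default_rng`); the pipeline expands a single run seed
  into per-stage seeds by a fixed counter scheme
  (seed + 10007·stage-index, mod 2³¹), so any stage re-runs identically
  in isolation. Generators are pure functions of (config, seed).
- Test problem sizes: parameter recovery uses 2 × 50 diploids × 5000
  SNPs (Monte-Carlo SDs of the genome-wide estimate from a 100-replicate
  pilot: 0.0013, 0.0035, 0.0058 at F = 0.05, 0.2, 0.5); LD checks use
  40–52 accessions × 600 SNPs with 2-Mb blocks and a 4-haplotype pool;
  Mantel calibration uses 500 seeds × 1000 permutations at n = 20.

## Known limitations

- The statistical-parsimony connection limit is an input, not derived
  from the probability model of the original method; users comparing to
  TCS output at a given confidence level must supply the matching limit.
- Loop intermediates are connection-private: two equal-length alternative
  connections never share inferred nodes, which can differ from how the
  original software merges them.
- The LD decay output is binned means; no decay-rate curve (e.g.
  Hill–Weir) is fitted.
- Group-level Fst of highly unequal F parameters reflects their average
  differentiation; no per-branch decomposition is attempted.
- Cramér's V² on a 6 × 2 table is one of several defensible "r²"
  association measures; alternatives (including admixed accessions, or a
  three-species table) are available through flags.
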