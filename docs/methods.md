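# Methods

This note documents the models and procedures implemented in `vespagen`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions adopted where the underlying
method leaves choices open.

## Genotype model and filters

Genotypes are held as ALT-allele dosages in {0, 1, 2} with a distinct
missing sentinel (−1); coordinates are 1-based inclusive as in VCF, and
positions are strictly increasing within each chromosome. Only biallelic
SNPs are modeled; multi-allelic and non-SNP records are skipped at load
time with a logged count.

Quality control composes in a fixed order:

1. **Hard site filter** (optional, for raw caller output): a site is dropped
   if any present annotation fails QD < 2.0, QUAL < 30.0, SOR > 3.0,
   FS > 60.0, MQ < 40.0, MQRankSum < −12.5 or ReadPosRankSum < −8.0. Absent
   fields are not tested.
2. **Genotype masking**: calls with GQ < 20 (phred) or depth ≤ 2 reads
   become missing. Masking is per call, not per locus: a locus-level
   mean-depth rule would make the subsequent missingness rule
   order-dependent, whereas per-call masking composes deterministically.
3. **Site missingness**: sites with > 10% missing calls are dropped.
4. **Polymorphism restriction** (where an analysis demands it): a site is
   kept iff both alleles are observed among the designated sample subset.

Both filters are idempotent, and each stage logs its removal counts.

## LD pruning

r² is the squared Pearson correlation of dosages over pairwise-complete
samples — a genotype (unphased) statistic, not an EM haplotype-frequency
estimate. This is deterministic and directly checkable against a naive
reference, at the cost of small numerical differences from haplotype-based
tools. An r² that is undefined (monomorphic over complete pairs, or fewer
than two complete pairs) is treated as "not in LD".

* **Physical-window dialect** (default 200 kb, r² > 0.1): greedy
  left-to-right scan per chromosome; a site is removed iff an already-kept
  site within the window upstream exceeds the threshold against it.
* **SNP-window dialect** (default 50 SNPs, 5-SNP step, r² > 0.8): windows
  slide over each chromosome (trailing partial windows included); within a
  window, while any kept pair exceeds the threshold, the later member of
  the first offending pair in index order is removed.

Tie-break convention in both dialects: the site with the larger genome
coordinate loses. This makes output deterministic and order-stable; it is a
declared convention, with no claim of tie-level compatibility with any
particular external implementation. The first site of a chromosome is never
removed. Overlapping windows memoize r² values, making the SNP-window scan
linear in practice.

For relatedness estimation the physically pruned set is further thinned to
every 90th locus by default — appropriate for whole-genome panels with
>10⁵ unlinked loci. The bundled fixture configuration sets the step to 1
because its panel has only ~5,000 SNPs to begin with.

## Relatedness

The default estimator is the symmetrized Queller–Goodnight moment
estimator (see README for the closed form), computed on loci that are
pairwise-complete and polymorphic in the frequency panel, with allele
frequencies estimated from the full female analysis panel pooled across
populations. The estimator interface is pluggable (`estimator=` argument)
so a likelihood or other moment estimator can be swapped in.

Properties worth knowing:

* For a biallelic heterozygote, p_a + p_b = 1, so an all-heterozygous pair
  of genotypes contributes zero to both numerator and denominator at every
  locus; such input raises an undefined-relatedness error rather than a
  value. In practice homozygous loci dominate both sums.
* The estimator is unbiased when frequencies are known. Estimating
  frequencies from a small panel that itself contains the relatives
  shrinks estimates toward the panel mean (relative pairs inflate the
  frequency of their shared alleles); the test suite therefore checks point
  recovery (±0.05 of r ∈ {0, 0.5, 0.75}) on panels of 200 independent
  pairs × 5,000 loci, and checks only the qualitative bimodal
  within-nest/cross-nest pattern on the small nest-structured fixture.
* Per-population mean ± SE is computed over within-population pairs; pair
  non-independence makes this SE anti-conservative, and it is reported as
  descriptive only.

**Kin pruning** builds a graph with an edge for every pair above the cutoff
(default 0.33, the conventional midpoint between first- and second-order
relatedness) and repeatedly deletes the highest-degree vertex, breaking
ties toward the lexicographically smallest sample id, until no edge
remains. The post-condition (no retained pair above the cutoff) is
re-verified by a full pair scan on every call. Greedy max-degree deletion
is a standard 2-approximation-style heuristic for this relationship-removal
problem; exact minimum vertex cover is used only as a test oracle on graphs
of ≤ 12 vertices.

## ROH detection and fROH

The detector follows the classic sliding-window semantics, restated as five
deterministic steps (window scoring → SNP flagging → run splitting at gaps →
trimming to homozygous ends → acceptance thresholds). Parameters, with
defaults:

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 50 | scanning window size (SNPs) |
| `window_het_max` | 1 | max heterozygous calls per passing window |
| `window_missing_max` | 5 | max missing calls per passing window |
| `hit_threshold` | 0.05 | min fraction of passing windows containing a SNP |
| `min_snps` | 50 | min SNPs per accepted segment |
| `min_length_kb` | 500 | length floor; run at {500, 1000, 2000} |
| `density_kb_per_snp` | 60 | max kb per SNP within a segment |
| `gap_kb` | 500 | split segments at larger inter-SNP gaps |
| `segment_het_max` | unlimited | optional per-segment het cap |

Conventions chosen where the window semantics are underdetermined:

* Only windows fully contained in a chromosome are enumerated; SNPs near
  chromosome ends are judged by fewer windows, and chromosomes with fewer
  sites than one window yield no calls.
* Segment length is `end − start + 1` bp between terminal SNP positions;
  physical chromosome ends are unobservable from a SNP table.
* Candidates are trimmed so both terminal SNPs are homozygous and
  non-missing *before* the acceptance thresholds are applied.

These are self-consistent conventions validated by equivalence to an
independent naive implementation on randomized instances (100 seeds,
≤ 500 SNPs, randomized parameters), not a claim of bit-compatibility with
any external caller.

**fROH** divides a sample's total accepted ROH length by ROH_max, the total
for a synthetic individual homozygous at every site of the same SNP set,
computed with the same parameters — including the same length floor, so
ROH_max is recomputed per (SNP set, minimum length). On SNP sets whose
per-chromosome spans exceed the largest floor and contain no gap larger
than `gap_kb` — any realistic whole-genome set, and the bundled fixture —
ROH_max is identical across the three floors, which is why fROH is monotone
non-increasing in the length floor in every test. fROH is 1.0 exactly for
the fully homozygous individual and 0 for a fully heterozygous one.
Within-population profiles recompute both the polymorphic SNP set and
ROH_max per population; because sites fixed within a population (always
homozygous there) are excluded, within-population fROH runs lower than
pooled fROH on average. Haploid males carry no heterozygosity signal and
are excluded from all ROH computation. For descriptive grouping, fROH
values are binned as zero (= 0), intermediate (0 < fROH ≤ 0.02) and high
(> 0.02).

## PCA

Sites are standardized with binomial (Patterson) scaling using the panel
ALT frequency; missing calls are imputed to the site mean (0 after
centering); monomorphic sites are dropped with a warning. Scores come from
an exact SVD of the re-centered matrix; the number of components is capped
at min(samples − 1, sites). Each component's sign is fixed by forcing its
largest-magnitude site loading positive, so output is fully reproducible
and invariant (up to that sign rule) to sample order.

## Mitochondrial super-barcoding

Input is a panel of equal-length consensus sequences called against a fixed
reference — no gaps, no alignment step — with an optional per-site depth
track. The QC order is fixed: depth masking (< 100× → N, per site), then
sample dropping (> 0.4% N), then column dropping (any N or IUPAC ambiguity
anywhere); the sample rule is evaluated on the post-masking sequences.
IUPAC ambiguity codes are treated exactly like N throughout. Re-running the
trim on trimmed output is the identity.

The site census classifies *sites*: constant (one allele),
parsimony-informative (≥ 2 alleles each in ≥ 2 samples), singleton
(everything else variable). A three-allele column whose two minor alleles
each occur once counts as one singleton site, so the three counts always
partition the alignment length. Mitotypes are equivalence classes of
identical post-trim sequences, labeled `mt-1`, `mt-2`, … in first-occurrence
order; the partition, not the labels, is the meaningful output.

Whether "regions below 100× mean depth" should be read per site or as a
windowed mean is ambiguous; masking is per site here, which is the stricter
reading and the one that composes with the downstream N rules.

## Synthetic data generator

The generator emulates the study design this toolkit targets, with exact
machine-readable truth:

* **Populations**: ancestral ALT frequencies from Beta(0.8, 0.8) clipped to
  [0.05, 0.95]; per-population frequencies via the Balding–Nichols
  construction Beta(p(1−F)/F, (1−p)(1−F)/F) at differentiation F
  (default 0.1).
* **Haplodiploid nests**: each nest has one mother (two haplotypes) and one
  father (a single haplotype shared intact by every daughter), so daughters
  are super-sisters with pedigree relatedness 0.75; mothers are emitted as
  samples, fathers exist only in the pedigree truth. Males are emitted as
  single haplotypes coded homozygous and flagged male so downstream
  exclusion rules can be demonstrated.
* **Planted autozygosity**: per-individual target fractions are realized by
  copying haplotype A over haplotype B inside disjoint tracts (default 1 Mb)
  placed by largest-remainder apportionment across chromosomes with random
  jitter inside evenly spaced slots — guaranteeing disjointness at any
  feasible target and an exact truth fraction of the SNP-covered span.
* **Per-call metadata**: depth from a negative binomial (mean 19,
  overdispersion 5, mimicking a ~19× short-read panel), integer GQ from a
  clipped normal (mean 60, sd 15), and 2% missingness by default.
* **Mitogenomes**: a random root sequence (16 kb) with per-lineage private
  substitutions; per-sample depth tracks with planted low-depth patches,
  plus a configurable number of samples whose patch is long enough to
  exceed the 0.4% N cap after masking. Substitution sites are confined to
  the last 10% of the molecule and patches to the first 85%, so masking
  never erases a haplotype-defining site — the recovery test isolates the
  trimming logic from the (real) possibility of haplotype collapse under
  extreme coverage loss.

Defaults define the bundled fixture: 2 chromosomes × 10 Mb at ~4 kb mean
SNP spacing (~5,000 SNPs), 3 populations, 2 nests × 4 daughters + mother,
3 unrelated females and 2 males per population. All outputs are a pure
function of the configuration including its seed; same-seed runs produce
byte-identical files.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: linkage and recombination (inheritance is
per-site independent, so background LD comes only from population structure
and kinship, and background ROH is essentially absent), mutation/selection,
genotype-error correlation with depth, reference bias, multi-allelic sites,
indels, and real mitogenome features (gene content, frameshift checks,
alignment). Tract planting gives exact truth fractions but not the
length distribution of autozygosity generated by pedigree loops.

## Problem sizes and runtime

Tests and the acceptance script run on deliberately small instances chosen
to exercise every code path while completing in seconds: the ~5,000-SNP
fixture panel for end-to-end stages, 500-SNP instances for exhaustive
brute-force comparisons, 200 pairs × 5,000 loci for estimator calibration,
~40 samples × ~5,000 pruned SNPs for PCA separation, and graphs of ≤ 12
vertices where an exact minimum vertex cover is enumerable. The full test
suite runs in about a minute; `scripts/acceptance.py` in well under one.

## Known limitations

* The moment relatedness estimator degrades on panels dominated by close
  kin (frequency-estimation attenuation, documented above); a
  likelihood-based estimator behind the pluggable interface would be the
  natural extension.
* The ROH caller is a fixed-parameter sliding-window scan; no HMM/likelihood
  calling, no demographic dating of ROH age, and no X/autosome distinction
  beyond excluding haploid males.
* Kin pruning is heuristic; optimality is only guaranteed within the greedy
  bound.
* The SE on per-population mean relatedness ignores pair dependence.
* VCF round-tripping preserves dosages, positions, DP/GQ and the site
  annotations used by the hard filter, not arbitrary INFO/FORMAT content.
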