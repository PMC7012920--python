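# Methods

`poolmap` implements a bulked-segregant QTL-Seq workflow for F₂ populations
of a biparental cross (parent A, the trait parent, × parent B), together
with the synthetic data machinery needed to verify every stage without
external data. This note records the models, the conventions, the defaults
and why, and what the synthetic tests do and do not show.

## F₂ population simulator (`popsim`)

**Genome and markers.** The default synthetic genome is 10 chromosomes of
30 Mb (named `A01`–`A10`) with 5,000 uniformly spaced biallelic markers per
chromosome, a desk-scale stand-in for a dense (million-site) parental SNP
backbone. Both parents are fully homozygous and opposite at every marker,
as for doubled-haploid parent lines. All sizes are configurable; tests use
sparser maps (usually 200–1,000 markers per chromosome) since window
statistics depend on markers per window, not absolute density.

**Gametes.** Each F₁ gamete draws its genome-wide crossover count
uniformly from the closed integer range
`[round(m·(1−b)), round(m·(1+b))]` with mean `m = 25` and bias `b = 0.2`,
i.e. 20–30 crossovers, which averages 2.5 per chromosome on ten equal
chromosomes. The bias term is interpreted as a symmetric ±20% range on the
count — the simplest mechanism consistent with "about 25, within 20%".
Crossovers are apportioned to chromosomes multinomially in proportion to
physical length and placed uniformly; the starting parental phase of each
chromosome is an independent fair coin (independent assortment). No
crossover interference is modeled.

**F₂ genotypes.** One egg and one pollen haplotype are paired per
individual, uniformly without replacement (both gamete pools are permuted
and zipped). Genotypes are stored as parent-B allele dosage (0 = AA,
1 = AB, 2 = BB) and segregate 1:2:1 marker-wise.

**Trait model.** Six unlinked loci: one *dominant suppressor* whose
suppressing allele is carried by the non-trait parent B (on `A02` by
default), and five *recessive direct* loci with effects 0.6 (`A04`) and
4 × 0.1 (`A06`–`A09`), summing to 1. An individual carrying ≥1 suppressor
allele scores 0; otherwise it scores the sum of effects of the direct loci
at which it is homozygous for parent A's allele. This fixes the anchors:
parent A scores 1.0, parent B scores 0.0, and the fully heterozygous F₁
scores 0.0 (it carries one suppressor allele). Phenotypes are rounded to
12 decimals so sums of decimal effects compare exactly.

**Pools and reads.** The high pool is 25 individuals drawn uniformly from
those with phenotype > 0.7, the low pool 25 from those with phenotype
exactly 0; a deficient side raises an informative error. Pooled
sequencing draws exactly `depth = 30` reads per marker (Poisson depth is
available as an option; fixed depth keeps unit tests exact): each read
picks a pool member uniformly, one of its two alleles uniformly, and flips
allele with probability `error_rate = 0.01` (sequencing/mapping error;
configurable). Reads are conditionally independent given the pool, so the
counts are drawn binomially at the exact per-marker probability — a
distributional identity, not an approximation.

### A structural property of this trait model worth knowing

Under the six-locus model the high-phenotype class is doubly constrained:
phenotype > 0.7 requires homozygosity for the non-suppressor allele
(probability ¼), homozygosity at the 0.6 locus (¼), and homozygosity at
two or more of the four 0.1 loci (67/256). The classes multiply to
67/4096 ≈ 1.6%, so a 200-plant F₂ contains on average only ~3.3 such
individuals, and a 25-member high pool cannot be filled at that population
size — `select_pools` raises, by design. A population of ~2,500 is needed
to fill such pools reliably; the worked example in the README uses that
size.

Moreover, *any* individual with nonzero phenotype is necessarily
homozygous non-suppressor, so the high pool is fixed for parent A's allele
at the suppressor locus as well as at the 0.6 locus, while the
phenotype-0 pool is *more* skewed at the suppressor (A-allele frequency
≈ 0.38) than at the masked direct locus (≈ 0.49). The expected pooled
contrast is therefore largest at the *epistatic suppressor*
(combined Δ ≈ 1.24) rather than at the direct-effect locus (≈ 1.02), and
the full-population LOD scan also peaks at the suppressor
(R² ≈ 0.38 vs 0.14). Under this model, faithfully implemented, the
extreme-pool scan and the linkage scan *agree* on the suppressor
chromosome; a divergence in which the pooled contrast singles out the
direct locus is not reproduced by single-marker statistics at these
defaults. The acceptance test that encodes the divergence expectation is
kept and reports its observed success count honestly.

## QTL-Seq statistics (`qtlseq`)

**SNP-index and orientation.** The SNP-index of a pool at a marker,
relative to a named reference parent P, is the fraction of the pool's
reads carrying P's allele. Markers with pooled depth < 5 (per pool,
echoing the parental DP filter) are flagged missing. Per reference,
Δ = mean(high pool) − mean(low pool) per window; the combined
two-reference statistic is `Δ_combined = Δ_refA − Δ_refB`, oriented so
that high-pool enrichment for parent A's alleles is positive in both
terms, with range −2..+2 attained exactly by fixed opposite pools. For
shared marker sets `Δ_refB = −Δ_refA` identically, so a same-orientation
sum would cancel; the subtraction (equivalently, summing on complementary
orientations) is the non-degenerate reading and is asserted as the
algebraic identity `Δ_combined = 2·Δ_refA` on shared markers. In
real-data mode the two references are meant to be the two disjoint
variant sets (sites where parent A, respectively parent B, differs from
the assembly); `partition_reference_sets` emulates that split on synthetic
data.

**Co-segregation filter.** The default removes a marker only if its index
is < 0.3 in *both* pools or > 0.7 in *both* pools — both pools showing the
same extreme genotype means no between-pool segregation. The stricter
alternative (drop when extreme in *either* pool) is selectable but would
delete fixed causal regions; `keep-extreme` disables the filter.

**Windows.** 200-kb windows advancing by 20 kb, 1-based inclusive;
trailing partial windows are emitted with their true span and flagged.
Window means are computed per pool per reference over non-missing markers
via prefix sums.

**Confidence envelope.** The null distribution of a window's Δ_combined is
simulated directly: each replicate draws `pool_size` genotypes per pool
from 1:2:1 independently of phenotype (markers within a 200-kb window are
treated as fully linked within an individual — the dominant noise source
is genotype sampling, not read sampling), then draws reads at the window's
mean depth for each of its markers, and the (1±level)/2 percentiles over
`n_sims = 1000` replicates give the per-window band. Windows sharing
marker count and rounded depth share one simulation. Calibration is
checked end to end: on trait-free data ~95% of windows fall inside the
95% band (±2 pp). At depth 30, pools of 25, ~33 markers per window the
95% band is roughly ±0.4 — window-level null excursions of |Δ| ≈ 0.3 are
therefore ordinary, and significance should always be read against the
simulated envelope rather than a fixed cutoff.

**Candidate interval.** Among runs of k = 5 step-adjacent windows, the run
maximizing the minimum Δ_combined (ties: larger sum, then leftmost) is
selected; its intersection `[start of last window, end of first window]`
has length `window − (k−1)·step` = 120 kb at the defaults. Bounds are
then refined to SNP support: the default snaps *inward* to the outermost
retained SNPs inside the raw interval, so the refined interval is the
SNP-delimited extent of the evidence and is at most the raw length —
matching how a refined interval can be slightly shorter than the
window-arithmetic 120 kb. An `outward` mode (nearest retained SNP at or
beyond each bound) is available where a conservative superset is wanted.

## Linkage scan (`linkage`)

A deliberate simplification of composite-interval "MQM"-style mapping: at
each marker (or majority-genotype bin of consecutive markers) the
phenotype is fit by least squares on additive dosage plus a dominance
indicator — with three genotype classes this is the saturated cell-means
model — and `LOD = (n/2)·log10(RSS₀/RSS₁)`, equivalently
`(n/2)·log10(1/(1−R²))`. RSS₁ is floored at 1e−12·RSS₀ to keep perfect
fits finite. Missing genotypes are dropped pairwise; constant phenotypes
yield an all-zero profile with a warning. Genome-wide significance comes
from phenotype permutations, taking the conservative (ceil) order
statistic of the permuted maxima so that by construction fewer than α of
the null scans exceed the threshold. Scans are indexed by physical
position; no genetic map, cofactor selection or between-marker interval
mapping is attempted — the sampling-design contrast between
full-population association and extreme-pool contrast is the object of
study, not MQM itself.

## Depth-dip scan (`depthscan`)

An insertion present in one pool but absent from the mapping reference
suppresses mapped depth in a halo around the insertion point (reads
spanning the breakpoints fail to map). The simulator draws per-base
Poisson(30) depth for both pools and multiplies the affected pool's rate
by `dip_factor` within ±`insertion_halo` of the insertion. Detection
smooths both pools with a 50-bp moving average and scans the ratio
`(d_affected + 1)/(d_other + 1)` for maximal runs below 0.5 of length
≥ 50 bp, testing each pool as affected (so label swaps swap attribution,
never the interval). Defaults were chosen to detect a ~100-bp-halo dip at
20–30× with margin while keeping the false-call rate on dip-free data
effectively zero (smoothed Poisson(30) over 50 bp has a ratio SD of
~0.04, so 0.5 is >10 SD from the null mean). Optional per-pool median
normalization compensates unequal total yield. Breakpoint-level assembly
and split-read evidence are out of scope.

## Candidate genes (`candidates`)

Genes (from GFF3, 1-based inclusive) overlapping the refined interval by
≥ 1 bp are reported in positional order, annotated against a packaged,
user-extensible anthocyanin-pathway table (the *BrMYBL2.1* negative
regulator and the *BrEGL3.1/BrEGL3.2* positive regulators, with their
*B. rapa* coordinates). The ranked report places genes with both a
pathway role and a contained depth dip first, then role-only, then
dip-only, then the rest. The pathway table is curated input, not a
recomputed ortholog inference.

## Pipeline, formats, seeds (`io`, `pipeline`, `cli`)

All tables are TSVs with one `#`-prefixed header line; genotypes are coded
0/1/2 for AA/AB/BB. The minimal VCF v4.2 writer emits parent GT (+DP) and
pool AD columns so synthetic output can exercise the real-data entry
points; the parental filter drops records with QUAL < 10, per-parent
DP < 5, multi-allelic alternates, heterozygous or missing parent calls,
and parent-monomorphic sites. Every stochastic stage takes an explicit
seed; `run_all` derives per-stage seeds deterministically from the study
seed and logs them, and identical seeds reproduce byte-identical outputs.

## Problem sizes used in tests

Unit and property tests run on small genomes (2–10 chromosomes, 50–1,000
markers per chromosome) chosen so each window still holds several markers;
the study-level checks use 200 F₂ individuals at 200–500 markers per
chromosome, a 1,000-replicate envelope, 200 permutations, and 1-Mb
depth-scan regions. These sizes keep the full suite under half a minute
while leaving every statistic estimable at its stated tolerance.

## Known limitations

- Crossovers are placed without interference and gamete counts are
  uniform in a range, not Poisson; only allele counts are simulated, not
  reads, so mapping artifacts, indels and depth heterogeneity beyond
  Poisson are absent.
- The confidence envelope assumes 1:2:1 segregation and full within-window
  linkage; segregation distortion or very sparse windows would miscalibrate
  it slightly.
- The linkage scan is single-marker; closely spaced causal loci are not
  deconvolved.
- Real-data mode consumes a VCF and per-base depth tables; alignment and
  variant calling are upstream of this package.
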