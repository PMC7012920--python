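# poolmap

Bulked-segregant **QTL-Seq** mapping for F₂ populations, with a built-in
in-silico population generator that makes the whole pipeline testable
without any external data.

The package targets the common mapping situation in crops such as purple
*Brassica rapa* (anthocyanin enrichment): a biparental F₂ population,
two phenotype-extreme pools sequenced to modest depth, and a trait that
may be controlled by several loci under different genetic models — e.g. a
dominant epistatic suppressor masking a set of recessive direct-effect
loci. It provides:

- **`popsim`** — F₂ simulator: recombinant gametes (~25 crossovers per
  gamete, ±20%), 1:2:1 genotypes, a six-locus epistatic trait model
  (one dominant suppressor + recessive direct loci of 60% + 4×10%),
  extreme-pool selection and pooled read sampling (~30× per SNP).
- **`qtlseq`** — per-site SNP-index per pool and reference parent,
  co-segregation filtering (0.3/0.7), 200-kb/20-kb sliding-window
  Δ(SNP-index) per parent and combined (range −2..+2), null-resampling
  confidence envelopes, and candidate-interval extraction (intersection
  of the five best neighboring windows = 120 kb, SNP-refined).
- **`linkage`** — a single-marker LOD scan (additive + dominance) with
  permutation-based genome-wide thresholds.
- **`depthscan`** — pool-contrast per-base depth analysis flagging
  insertion halos as one-sided depth collapses.
- **`candidates`** — interval → gene overlap (GFF3) annotated against a
  packaged anthocyanin-pathway gene table, ranked by pathway role and
  depth-dip support.

## The statistic

For a pool and a reference parent P, the SNP-index at a site is the
fraction of pooled reads carrying P's allele. Per 200-kb window (20-kb
step) and per reference,

```
Δ_P = mean SNP-index(high pool) − mean SNP-index(low pool)      ∈ [−1, 1]
Δ_combined = Δ_parentA − Δ_parentB                              ∈ [−2, 2]
```

oriented so high-pool enrichment for parent A's alleles is positive in
both terms (on shared markers `Δ_combined = 2·Δ_parentA`; with the
dual-reference variant sets of a real run the terms carry independent
information). Significance is read against a simulated null envelope
(pools drawn 1:2:1 independent of phenotype, reads at the window's depth).
The LOD scan fits phenotype ~ additive + dominance per marker,
`LOD = (n/2)·log10(RSS₀/RSS₁)`.

See `docs/methods.md` for the full model description, defaults, and known
limitations — including a structural analysis of when extreme-pool and
full-population scans agree or disagree under dominant epistasis.

## Worked example

```python
import pandas as pd
from poolmap import popsim, qtlseq, linkage

# a denser F2 population so that 25 individuals exceed the 0.7 threshold
ms = popsim.default_marker_set(markers_per_chrom=1000)
arch = popsim.default_architecture(ms)
eggs, _ = popsim.simulate_gametes(ms, 2500, mean_crossovers=25, bias=0.2, seed=1)
pollen, _ = popsim.simulate_gametes(ms, 2500, mean_crossovers=25, bias=0.2, seed=2)
pop = popsim.assign_phenotypes(popsim.make_f2_population(ms, eggs, pollen, seed=3), arch)
print(f"{(pop.phenotypes > 0.7).sum()} of {pop.n_individuals} F2 exceed phenotype 0.7")

high, low = popsim.select_pools(pop.phenotypes, 0.7, 0.0, pool_size=25, seed=4)
depths = pd.concat([
    popsim.simulate_pool_reads(pop, high, depth=30, error_rate=0.01, seed=5),
    popsim.simulate_pool_reads(pop, low, depth=30, error_rate=0.01, seed=6),
], ignore_index=True)

idx_a = qtlseq.filter_cosegregating(qtlseq.compute_snp_index(depths, "A"))
idx_b = qtlseq.filter_cosegregating(qtlseq.compute_snp_index(depths, "B"))
windows = qtlseq.window_deltas(idx_a, idx_b, chrom_lengths=ms.chrom_lengths())
iv = qtlseq.find_candidate_interval(
    windows, k=5, snp_positions=idx_a[["chrom", "pos"]].drop_duplicates())
print(f"QTL-Seq peak interval {iv.chromosome}:{iv.refined_start}-{iv.refined_end} "
      f"(raw {iv.raw_length} bp, peak combined Δ = {iv.peak_delta:.2f})")

peak = linkage.peak_summary(linkage.lod_scan(pop))
print(f"linkage peak: LOD {peak['lod']:.1f} at {peak['chrom']}:{peak['pos']}")
```

This prints:

```
34 of 2500 F2 exceed phenotype 0.7
QTL-Seq peak interval A02:14910000-15000000 (raw 120000 bp, peak combined Δ = 1.31)
linkage peak: LOD 244.1 at A02:15000000
```

What the numbers mean: the high-phenotype class is rare (34/2500 ≈ 1.4%,
as the six-locus model predicts), the five-window intersection is exactly
120 kb (200 kb − 4×20 kb), and *both* scans peak on `A02` — the dominant
suppressor's chromosome, which sits at 15 Mb. Because every individual
with a nonzero phenotype must be homozygous non-suppressor, the
extreme-pool contrast at the suppressor (Δ ≈ 1.31) exceeds that at the
60% direct-effect locus on `A04` (Δ ≈ 1.17): under dominant epistasis the
pooled scan is pulled toward the suppressor too, not only the linkage
scan. The per-chromosome Δ maxima (`windows.groupby("chrom")["delta_combined"].max()`)
make the two-locus architecture visible at a glance.

A full study (simulate → pools → QTL-Seq + linkage → depth-scan fixture →
candidate report, with a JSON manifest) runs from the shell:

```bash
poolmap run-all --seed 5 --outdir study/        # uses config defaults
poolmap qtlseq --depth-table study/allele_depths.tsv --window 200000 --step 20000
poolmap candidates --interval A07:25112903-25230669
```

Note that with the literal study defaults (200 individuals, 25-member
pools at phenotype > 0.7) pool selection fails with an informative error —
a 200-plant F₂ contains on average only ~3 individuals above that
threshold under this trait model; see `docs/methods.md`.

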