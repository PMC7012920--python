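"""Single-marker LOD linkage scan over F2 genotypes and phenotypes.

At each marker (or majority-genotype marker bin) the phenotype is fit by
least squares on an additive dosage plus a dominance indicator.  With the
three F2 genotype classes this is the saturated cell-means model, so the
residual sum of squares equals the within-genotype-class sum of squares and

    LOD = (n/2) * log10(RSS0 / RSS1)

against the intercept-only null, equivalently (n/2)*log10(1/(1-R^2)).
Scans are indexed by physical position; no genetic map is estimated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .popsim import F2Population

__all__ = [
    "lod_scan",
    "peak_summary",
    "permutation_lod_threshold",
]

MISSING = 255  # genotype code treated as missing
_RSS_FLOOR_FRACTION = 1e-12  # RSS1 floored at this fraction of RSS0


def _bin_genotypes(pop: F2Population, bin_size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse consecutive markers (within chromosomes) into bins by
    per-individual majority genotype; returns (G, chrom, pos)."""
    chrom_all = pop.marker_set.markers["chrom"].to_numpy()
    pos_all = pop.marker_set.markers["pos"].to_numpy()
    G_cols, chroms, poss = [], [], []
    for chrom in dict.fromkeys(chrom_all):
        cols = np.flatnonzero(chrom_all == chrom)
        for i in range(0, len(cols), bin_size):
            block = pop.genotypes[:, cols[i : i + bin_size]]
            counts = np.stack([(block == g).sum(axis=1) for g in (0, 1, 2)])
            G_cols.append(counts.argmax(axis=0).astype(np.uint8))
            mid = cols[i : i + bin_size][len(cols[i : i + bin_size]) // 2]
            chroms.append(chrom_all[mid])
            poss.append(pos_all[mid])
    return np.stack(G_cols, axis=1), np.array(chroms), np.array(poss)


def _scan(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker cell-means fit; returns (lod, additive, dominance).

    Missing genotypes (code 255) are dropped pairwise per marker.
    """
    n_ind, m = G.shape
    masks = [(G == g) for g in (0, 1, 2)]
    n_g = np.stack([mk.sum(axis=0) for mk in masks])          # (3, m)
    s_g = np.stack([y @ mk for mk in masks])                  # (3, m)
    q_g = np.stack([(y * y) @ mk for mk in masks])            # (3, m)
    n_tot = n_g.sum(axis=0).astype(float)
    s_tot = s_g.sum(axis=0)
    q_tot = q_g.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss0 = q_tot - s_tot**2 / n_tot
        ssw = q_g - np.where(n_g > 0, s_g**2 / np.maximum(n_g, 1), 0.0)
        rss1 = np.where(n_g > 0, ssw, 0.0).sum(axis=0)
        rss1 = np.maximum(rss1, _RSS_FLOOR_FRACTION * rss0)
        lod = np.where(
            rss0 > 0, (n_tot / 2.0) * np.log10(np.maximum(rss0, 1e-300) / np.maximum(rss1, 1e-300)), 0.0
        )
        means = np.where(n_g > 0, s_g / np.maximum(n_g, 1), np.nan)
    additive = (means[2] - means[0]) / 2.0
    dominance = means[1] - (means[0] + means[2]) / 2.0
    return np.maximum(lod, 0.0), additive, dominance


def lod_scan(pop: F2Population, bin_size: int | None = None) -> pd.DataFrame:
    """Genome scan of single-marker LOD scores.

    Parameters
    ----------
    pop
        Population with phenotypes assigned.
    bin_size
        Optional number of consecutive markers collapsed into one test by
        per-individual majority genotype (reduces marker-level noise and
        compute on dense maps).

    Returns
    -------
    DataFrame with columns ``chrom, pos, lod, additive, dominance``.
    """
    if pop.phenotypes is None:
        raise ValueError("phenotypes must be assigned before scanning")
    y = np.asarray(pop.phenotypes, dtype=float)
    if bin_size is not None and bin_size > 1:
        G, chrom, pos = _bin_genotypes(pop, bin_size)
    else:
        G = pop.genotypes
        chrom = pop.marker_set.markers["chrom"].to_numpy()
        pos = pop.marker_set.markers["pos"].to_numpy()
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: LOD profile is identically zero")
        lod = np.zeros(G.shape[1])
        add = np.zeros(G.shape[1])
        dom = np.zeros(G.shape[1])
    else:
        lod, add, dom = _scan(G, y)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "lod": lod, "additive": add, "dominance": dom}
    )


def peak_summary(profile: pd.DataFrame) -> dict:
    """Genome-wide maximum-LOD record; ties broken by leftmost genomic
    coordinate (chromosome order of the profile, then position).  An
    all-zero profile returns the first marker flagged ``no_signal``."""
    if len(profile) == 0:
        raise ValueError("empty LOD profile")
    lod = profile["lod"].to_numpy()
    best = int(np.argmax(lod))  # argmax returns the first (leftmost) maximum
    row = profile.iloc[best]
    return {
        "chrom": str(row["chrom"]),
        "pos": int(row["pos"]),
        "lod": float(row["lod"]),
        "no_signal": bool(lod[best] == 0.0),
    }


def permutation_lod_threshold(
    pop: F2Population,
    n_permutations: int = 200,
    alpha: float = 0.05,
    bin_size: int | None = None,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide significance threshold by phenotype permutation.

    Returns the conservative (1-alpha) order statistic of the permuted
    genome-wide maximum LOD scores, together with the null maxima.
    """
    if pop.phenotypes is None:
        raise ValueError("phenotypes must be assigned")
    rng = np.random.default_rng(seed)
    y = np.asarray(pop.phenotypes, dtype=float)
    if bin_size is not None and bin_size > 1:
        G, _, _ = _bin_genotypes(pop, bin_size)
    else:
        G = pop.genotypes
    maxima = np.empty(n_permutations)
    for i in range(n_permutations):
        lod, _, _ = _scan(G, rng.permutation(y))
        maxima[i] = lod.max()
    threshold = float(np.quantile(maxima, 1 - alpha, method="higher"))
    return threshold, maxima
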