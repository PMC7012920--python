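"""SNP-index statistics for bulked-segregant QTL-Seq mapping.

The per-site SNP-index of a pool, taken with respect to a named reference
parent, is the fraction of that pool's reads carrying the reference parent's
allele.  The per-parent Δ(SNP-index) of a window is the high-pool mean minus
the low-pool mean; the combined two-reference statistic is

    Δ_combined = Δ_refA − Δ_refB    (range −2 .. +2)

so that high-pool enrichment for parent A's alleles is positive in both
terms.  For marker sets shared between the two references this equals
2·Δ_refA; with the paper-style dual variant-calling passes (disjoint marker
sets per reference) the two terms carry independent information.

Confidence envelopes are built by null resampling: pools of F2 genotypes
drawn 1:2:1 independently of phenotype, reads drawn at the window's mean
depth, and the per-window percentiles of the resulting null Δ_combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SNP_INDEX_COLUMNS",
    "CandidateInterval",
    "compute_snp_index",
    "filter_cosegregating",
    "partition_reference_sets",
    "window_deltas",
    "confidence_envelope",
    "attach_envelope",
    "find_candidate_interval",
    "plot_windows",
]

SNP_INDEX_COLUMNS = ("chrom", "pos", "pool", "depth", "ref_count", "snp_index")


@dataclass(frozen=True)
class CandidateInterval:
    """Window-intersection candidate region with SNP-refined bounds."""

    chromosome: str
    raw_start: int
    raw_end: int
    refined_start: int
    refined_end: int
    peak_delta: float

    @property
    def raw_length(self) -> int:
        return self.raw_end - self.raw_start + 1

    @property
    def refined_length(self) -> int:
        return self.refined_end - self.refined_start + 1


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def compute_snp_index(
    depths: pd.DataFrame,
    reference_parent: str = "A",
    min_depth: int = 5,
) -> pd.DataFrame:
    """Per-marker, per-pool SNP-index relative to one reference parent.

    Parameters
    ----------
    depths
        Long-format allele-depth table with columns
        ``chrom, pos, pool, count_a, count_b``.
    reference_parent
        'A' or 'B'; the index is the fraction of reads carrying this
        parent's allele.
    min_depth
        Markers whose total read count in a pool is below this are flagged
        missing (NaN index) and excluded downstream.
    """
    if reference_parent not in ("A", "B"):
        raise ValueError(f"unknown reference parent {reference_parent!r}")
    ref_col = "count_a" if reference_parent == "A" else "count_b"
    total = (depths["count_a"] + depths["count_b"]).to_numpy(dtype=float)
    ref_count = depths[ref_col].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(total >= min_depth, ref_count / total, np.nan)
    out = pd.DataFrame(
        {
            "chrom": depths["chrom"].to_numpy(),
            "pos": depths["pos"].to_numpy(),
            "pool": depths["pool"].to_numpy(),
            "depth": total.astype(int),
            "ref_count": ref_count.astype(int),
            "snp_index": index,
        }
    )
    out.attrs["reference_parent"] = reference_parent
    return out


def _pivot(idx: pd.DataFrame) -> pd.DataFrame:
    """Wide per-marker view: one row per (chrom, pos), index/depth per pool."""
    wide = idx.pivot_table(
        index=["chrom", "pos"],
        columns="pool",
        values=["snp_index", "depth"],
        aggfunc="first",
        observed=True,
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def filter_cosegregating(
    idx: pd.DataFrame,
    low: float = 0.3,
    high: float = 0.7,
    mode: str = "both-pools",
) -> pd.DataFrame:
    """Remove markers whose index is extreme the same way in both pools.

    A marker with index < ``low`` in BOTH pools, or > ``high`` in BOTH
    pools, shows the same co-segregating genotype in the two pools and
    carries no between-pool contrast; the default mode removes exactly
    those markers.  ``mode='either-pool'`` instead removes any marker that
    is extreme in at least one pool (more aggressive; also deletes fixed
    causal regions).  ``mode='keep-extreme'`` disables the filter.
    """
    if low >= high:
        raise ValueError("low must be < high")
    if mode not in ("both-pools", "either-pool", "keep-extreme"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if mode == "keep-extreme":
        return idx.copy()
    wide = _pivot(idx)
    hi_i = wide.get("snp_index_high")
    lo_i = wide.get("snp_index_low")
    if hi_i is None or lo_i is None:
        raise ValueError("both 'high' and 'low' pools required per marker")
    if mode == "both-pools":
        drop = ((hi_i < low) & (lo_i < low)) | ((hi_i > high) & (lo_i > high))
    else:
        drop = (hi_i < low) | (lo_i < low) | (hi_i > high) | (lo_i > high)
    drop = drop.fillna(False)
    bad = set(map(tuple, wide.loc[drop.to_numpy(), ["chrom", "pos"]].itertuples(index=False)))
    keep = [
        (c, p) not in bad
        for c, p in zip(idx["chrom"].to_numpy(), idx["pos"].to_numpy())
    ]
    out = idx.loc[keep].reset_index(drop=True)
    out.attrs = dict(idx.attrs)
    return out


def partition_reference_sets(
    idx_ref_a: pd.DataFrame,
    idx_ref_b: pd.DataFrame,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly split shared markers into disjoint refA / refB sets,
    emulating the two variant-calling passes of a real dual-reference run."""
    markers = idx_ref_a[["chrom", "pos"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    to_a = rng.random(len(markers)) < 0.5
    a_set = set(map(tuple, markers[to_a].itertuples(index=False)))
    keys_a = list(zip(idx_ref_a["chrom"], idx_ref_a["pos"]))
    keys_b = list(zip(idx_ref_b["chrom"], idx_ref_b["pos"]))
    out_a = idx_ref_a.loc[[k in a_set for k in keys_a]].reset_index(drop=True)
    out_b = idx_ref_b.loc[[k not in a_set for k in keys_b]].reset_index(drop=True)
    out_a.attrs, out_b.attrs = dict(idx_ref_a.attrs), dict(idx_ref_b.attrs)
    return out_a, out_b


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def _window_means(idx: pd.DataFrame, starts: np.ndarray, ends: np.ndarray,
                  chrom: str) -> dict[str, np.ndarray]:
    """Mean index per pool plus marker/depth bookkeeping for one chromosome's
    windows, via prefix sums over position-sorted markers."""
    sub = idx[(idx["chrom"] == chrom) & idx["snp_index"].notna()]
    out: dict[str, np.ndarray] = {}
    nw = len(starts)
    depth_sum = np.zeros(nw)
    depth_n = np.zeros(nw)
    n_common = None
    for pool in ("high", "low"):
        p = sub[sub["pool"] == pool].sort_values("pos")
        pos = p["pos"].to_numpy()
        vals = p["snp_index"].to_numpy()
        deps = p["depth"].to_numpy(dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        cumd = np.concatenate([[0.0], np.cumsum(deps)])
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="right")
        n = i1 - i0
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (cum[i1] - cum[i0]) / np.maximum(n, 1), np.nan)
        out[f"mean_{pool}"] = mean
        out[f"n_{pool}"] = n
        depth_sum += cumd[i1] - cumd[i0]
        depth_n += n
        n_common = n if n_common is None else np.minimum(n_common, n)
    with np.errstate(invalid="ignore"):
        out["mean_depth"] = np.where(depth_n > 0, depth_sum / np.maximum(depth_n, 1), np.nan)
    out["n_snps"] = n_common
    return out


def window_deltas(
    idx_ref_a: pd.DataFrame,
    idx_ref_b: pd.DataFrame,
    window: int = 200_000,
    step: int = 20_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window Δ(SNP-index) per reference parent plus the combined
    two-reference statistic.

    Windows are 1-based inclusive, advancing by ``step``; the final window
    of each chromosome may be shorter and is flagged ``partial``.  Windows
    with no usable marker in a reference set carry NaN deltas.
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    if chrom_lengths is None:
        chrom_lengths = {}
        for df in (idx_ref_a, idx_ref_b):
            for c, p in df.groupby("chrom", sort=False)["pos"].max().items():
                chrom_lengths[c] = max(chrom_lengths.get(c, 0), int(p))
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, max(length - window + 1, 1) + 1, step)
        # ensure tail coverage: extend with partial windows up to the end
        last_full_end = starts[-1] + window - 1
        if last_full_end < length:
            extra = np.arange(starts[-1] + step, length + 1, step)
            starts = np.concatenate([starts, extra])
        ends = np.minimum(starts + window - 1, length)
        stats_a = _window_means(idx_ref_a, starts, ends, chrom)
        stats_b = _window_means(idx_ref_b, starts, ends, chrom)
        delta_a = stats_a["mean_high"] - stats_a["mean_low"]
        delta_b = stats_b["mean_high"] - stats_b["mean_low"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            mean_depth = np.nanmean(
                np.vstack([stats_a["mean_depth"], stats_b["mean_depth"]]), axis=0
            )
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "n_snps_ref_a": stats_a["n_snps"],
                "n_snps_ref_b": stats_b["n_snps"],
                "mean_high_ref_a": stats_a["mean_high"],
                "mean_low_ref_a": stats_a["mean_low"],
                "mean_high_ref_b": stats_b["mean_high"],
                "mean_low_ref_b": stats_b["mean_low"],
                "delta_ref_a": delta_a,
                "delta_ref_b": delta_b,
                "delta_combined": delta_a - delta_b,
                "mean_depth": mean_depth,
                "partial": ends - starts + 1 < window,
            }
        )
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_snps_ref_a", "n_snps_ref_b",
                "mean_high_ref_a", "mean_low_ref_a", "mean_high_ref_b",
                "mean_low_ref_b", "delta_ref_a", "delta_ref_b",
                "delta_combined", "mean_depth", "partial",
            ]
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Null-resampling confidence envelope
# ---------------------------------------------------------------------------

def _null_delta_draws(
    n_markers: int,
    depth: int,
    pool_size: int,
    n_sims: int,
    rng: np.random.Generator,
    error_rate: float = 0.0,
) -> np.ndarray:
    """Null Δ_combined replicates for one window geometry.

    Pool members' genotypes are drawn 1:2:1 once per window (markers within
    a 200-kb window are in near-complete linkage within an individual), and
    each of the window's markers receives an independent read draw.
    """
    deltas = np.empty(n_sims)
    for pool_idx in range(2):
        geno = rng.choice([0, 1, 2], size=(n_sims, pool_size), p=[0.25, 0.5, 0.25])
        q = geno.mean(axis=1) / 2.0
        p_b = q * (1 - error_rate) + (1 - q) * error_rate
        # mean SNP-index over the window's markers, reads ~ Binom(depth, p)
        counts = rng.binomial(depth, p_b[:, None], size=(n_sims, n_markers))
        idx_a = 1.0 - counts.mean(axis=1) / depth  # index w.r.t. parent A
        if pool_idx == 0:
            deltas = idx_a.copy()
        else:
            deltas -= idx_a
    return 2.0 * deltas  # combined = delta_refA - delta_refB = 2*delta_refA


def confidence_envelope(
    windows: pd.DataFrame,
    pool_size: int = 25,
    n_sims: int = 1000,
    levels: tuple[float, ...] = (0.95, 0.99),
    seed: int | None = None,
    error_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-window null percentile bounds of Δ_combined.

    Windows sharing the same marker count and (rounded) mean depth share
    one simulation.  Windows with zero usable depth get a missing envelope.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    n_snps = windows["n_snps_ref_a"].to_numpy()
    if "n_snps_ref_b" in windows:
        n_snps = np.minimum(n_snps, windows["n_snps_ref_b"].to_numpy())
    depth = windows["mean_depth"].to_numpy(dtype=float)
    cache: dict[tuple[int, int], np.ndarray] = {}
    out = {f"ci_low_{lv:g}": np.full(len(windows), np.nan) for lv in levels}
    out.update({f"ci_high_{lv:g}": np.full(len(windows), np.nan) for lv in levels})
    for i in range(len(windows)):
        nm = int(n_snps[i]) if np.isfinite(n_snps[i]) else 0
        d = int(round(depth[i])) if np.isfinite(depth[i]) else 0
        if nm == 0 or d == 0:
            continue
        key = (nm, d)
        if key not in cache:
            cache[key] = _null_delta_draws(nm, d, pool_size, n_sims, rng, error_rate)
        draws = cache[key]
        for lv in levels:
            lo_q, hi_q = 100 * (1 - lv) / 2, 100 * (1 + lv) / 2
            out[f"ci_low_{lv:g}"][i] = np.percentile(draws, lo_q)
            out[f"ci_high_{lv:g}"][i] = np.percentile(draws, hi_q)
    return pd.DataFrame(out, index=windows.index)


def attach_envelope(windows: pd.DataFrame, envelope: pd.DataFrame) -> pd.DataFrame:
    return pd.concat([windows, envelope], axis=1)


# ---------------------------------------------------------------------------
# Candidate interval
# ---------------------------------------------------------------------------

def find_candidate_interval(
    windows: pd.DataFrame,
    k: int = 5,
    snp_positions: pd.DataFrame | None = None,
    refine: str = "inward",
) -> CandidateInterval:
    """Intersection of the k consecutive windows with the highest Δ_combined.

    Among all runs of ``k`` step-adjacent windows on one chromosome, selects
    the run maximizing the minimum Δ_combined (ties broken by summed Δ,
    then leftmost) and returns the intersection
    ``[start of last window, end of first window]``.

    If ``snp_positions`` (columns ``chrom, pos``, the retained SNPs) is
    given, bounds are refined: ``inward`` snaps each bound to the outermost
    retained SNP inside the raw interval (the SNP-supported extent);
    ``outward`` snaps to the nearest retained SNP at or beyond each bound.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    best = None  # (min_delta, sum_delta, -order) for max comparison
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        delta = grp["delta_combined"].to_numpy(dtype=float)
        if len(grp) < k:
            continue
        step = np.diff(starts).min() if len(starts) > 1 else 0
        for i in range(len(grp) - k + 1):
            run_starts = starts[i : i + k]
            if k > 1 and not np.all(np.diff(run_starts) == step):
                continue
            run_delta = delta[i : i + k]
            if np.isnan(run_delta).any():
                continue
            key = (run_delta.min(), run_delta.sum())
            cand = (
                key,
                chrom,
                int(run_starts[-1]),  # raw_start: start of last window
                int(ends[i]),         # raw_end: end of first window
                float(run_delta.max()),
            )
            if best is None or cand[0] > best[0]:
                best = cand
    if best is None:
        raise ValueError(f"no chromosome has {k} consecutive windows with data")
    _, chrom, raw_start, raw_end, peak = best
    refined_start, refined_end = raw_start, raw_end
    if snp_positions is not None:
        pos = np.sort(
            snp_positions.loc[snp_positions["chrom"] == chrom, "pos"].unique()
        )
        if len(pos):
            if refine == "inward":
                inside = pos[(pos >= raw_start) & (pos <= raw_end)]
                if len(inside):
                    refined_start, refined_end = int(inside[0]), int(inside[-1])
            elif refine == "outward":
                left = pos[pos <= raw_start]
                right = pos[pos >= raw_end]
                if len(left):
                    refined_start = int(left[-1])
                if len(right):
                    refined_end = int(right[0])
            else:
                raise ValueError(f"unknown refine mode {refine!r}")
    return CandidateInterval(chrom, raw_start, raw_end, refined_start, refined_end, peak)


# ---------------------------------------------------------------------------
# Plotting (Fig. 1a-style track)
# ---------------------------------------------------------------------------

def plot_windows(windows: pd.DataFrame, out_path: str, level: float = 0.95) -> None:
    """Δ_combined along chromosomes with optional CI tracks, one panel per
    chromosome, written to ``out_path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(2.2 * len(chroms), 2.8), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub["delta_combined"], color="purple", lw=1)
        for col, ls in ((f"ci_low_{level:g}", "-"), (f"ci_high_{level:g}", "-")):
            if col in sub:
                ax.plot(mid, sub[col], color="red", lw=0.8, ls=ls)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(chrom, fontsize=8)
        ax.set_xlabel("Mb", fontsize=7)
    axes[0][0].set_ylabel("Δ(SNP-index), combined")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
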