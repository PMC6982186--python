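"""SNP-index and delta-SNP-index mapping with simulated null intervals.

The SNP index of a bulk at one SNP is the fraction of reads carrying the
alternate allele (0 = all reads match the reference genome).  Averaging
indices in sliding windows (1 Mb window, 10 kb step by default) smooths
read-sampling noise; the delta SNP index of a window is the long-bulk mean
minus the short-bulk mean.  Away from the trait locus both bulks are
random samples of the population and the delta fluctuates around zero;
around a recessive locus the short bulk is fixed for the causal allele
(index 1 with the short parent's allele as alternate) while the long bulk
carries it at frequency 1/3, so the expected delta is 1/3 - 1 = -2/3.

Significance is judged against a two-stage binomial null simulated per
read depth: a bulk's allele count is Binomial(2*bulk_size, 1/2) (F2 with
no locus), then reads are Binomial(depth, bulk frequency); the empirical
quantiles of the simulated delta give the confidence bounds.  Windows
whose delta escapes the bounds in a consistent direction over several
consecutive windows are merged into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "NullCiTable",
    "WINDOW_COLUMNS",
    "REGION_COLUMNS",
    "snp_index",
    "add_indices",
    "filter_snps",
    "sliding_windows",
    "simulate_null_ci",
    "attach_ci_and_call_regions",
    "plot_delta_profile",
]

WINDOW_COLUMNS = (
    "chrom", "start", "end", "n_snps",
    "mean_index_L", "mean_index_S", "delta", "eff_depth",
)
REGION_COLUMNS = ("chrom", "start", "end", "peak_delta", "peak_pos", "n_windows")


@dataclass(frozen=True)
class FilterReport:
    """Counts removed by each SNP filter rule."""

    n_input: int
    n_removed_depth: int
    n_removed_index: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_depth - self.n_removed_index


@dataclass
class NullCiTable:
    """Per-depth empirical null bounds for the single-SNP delta index.

    ``bounds[confidence]`` is a DataFrame (depth, lower, upper).  Bounds
    widen as depth decreases and are symmetric around zero in expectation.
    """

    bulk_size: int
    reps: int
    bounds: dict[float, pd.DataFrame]

    @property
    def depths(self) -> np.ndarray:
        first = next(iter(self.bounds.values()))
        return first["depth"].to_numpy()

    def lookup(self, depth: float, confidence: float) -> tuple[float, float]:
        """Bounds at the simulated depth nearest to ``depth``."""
        if confidence not in self.bounds:
            raise KeyError(f"confidence {confidence} not simulated")
        tab = self.bounds[confidence]
        i = int(np.argmin(np.abs(tab["depth"].to_numpy() - depth)))
        return float(tab["lower"].iloc[i]), float(tab["upper"].iloc[i])


def snp_index(ref_depth: int, alt_depth: int) -> float:
    """alt / (ref + alt); NaN (missing) when the SNP has no reads."""
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("read depths must be non-negative")
    total = ref_depth + alt_depth
    if total == 0:
        return float("nan")
    return alt_depth / total


def add_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with index_L / index_S columns (NaN at zero depth)."""
    out = records.copy()
    for pool in ("L", "S"):
        total = out[f"{pool}_ref"] + out[f"{pool}_alt"]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"index_{pool}"] = np.where(total > 0, out[f"{pool}_alt"] / total, np.nan)
    return out


def filter_snps(
    records: pd.DataFrame,
    min_total_depth_per_pool: int = 7,
    min_index_either_pool: float = 0.3,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop low-depth and monomorphic-looking SNPs.

    A record is kept iff both pools have total depth >=
    ``min_total_depth_per_pool`` and the larger of the two pool indices is
    >= ``min_index_either_pool`` (a SNP matching the reference in both
    bulks carries no mapping signal).  Thresholds of (0, 0) return the
    input unchanged.
    """
    if min_total_depth_per_pool < 0 or min_index_either_pool < 0:
        raise ValueError("filter thresholds must be >= 0")
    df = add_indices(records)
    depth_ok = pd.Series(True, index=df.index)
    for pool in ("L", "S"):
        depth_ok &= (df[f"{pool}_ref"] + df[f"{pool}_alt"]) >= min_total_depth_per_pool
    max_index = df[["index_L", "index_S"]].max(axis=1)
    index_ok = max_index.fillna(-1.0) >= min_index_either_pool if min_index_either_pool > 0 \
        else pd.Series(True, index=df.index)

    n_removed_depth = int((~depth_ok).sum())
    n_removed_index = int((depth_ok & ~index_ok).sum())
    kept = records.loc[depth_ok & index_ok].reset_index(drop=True)
    return kept, FilterReport(len(records), n_removed_depth, n_removed_index)


def _window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    if length <= window_size:
        return np.array([1], dtype=np.int64)
    n = (length - window_size) // step + 1
    return 1 + step * np.arange(n, dtype=np.int64)


def sliding_windows(
    records: pd.DataFrame,
    window_size: int = 1_000_000,
    step: int = 10_000,
    chromosome_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean SNP indices and delta per sliding window.

    Windows start at 1, 1+step, ... and span [start, start+window_size)
    (1-based, half-open at the right).  The per-pool window statistic is
    the unweighted mean of member SNP indices; delta is the long-pool mean
    minus the short-pool mean.  SNPs with zero depth in either pool are
    excluded; windows with no usable SNP carry NaN.  ``eff_depth`` is the
    mean per-SNP per-pool read depth of the window, used downstream for
    the null-CI lookup.
    """
    if not (window_size >= step > 0):
        raise ValueError("need window_size >= step > 0")
    df = add_indices(records)
    df = df.dropna(subset=["index_L", "index_S"]).sort_values(["chrom", "pos"], kind="stable")
    if chromosome_lengths is None:
        chromosome_lengths = {
            str(c): int(g["pos"].max()) for c, g in df.groupby("chrom", sort=True)
        }

    rows = []
    for chrom in sorted(chromosome_lengths):
        length = chromosome_lengths[chrom]
        grp = df[df["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        cum_l = np.concatenate([[0.0], np.cumsum(grp["index_L"].to_numpy())])
        cum_s = np.concatenate([[0.0], np.cumsum(grp["index_S"].to_numpy())])
        per_snp_depth = (
            grp[["L_ref", "L_alt", "S_ref", "S_alt"]].sum(axis=1).to_numpy() / 2.0
        )
        cum_d = np.concatenate([[0.0], np.cumsum(per_snp_depth)])

        starts = _window_starts(length, window_size, step)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_l = np.where(n > 0, (cum_l[hi] - cum_l[lo]) / n, np.nan)
            mean_s = np.where(n > 0, (cum_s[hi] - cum_s[lo]) / n, np.nan)
            eff_d = np.where(n > 0, (cum_d[hi] - cum_d[lo]) / n, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_size - 1,
                    "n_snps": n,
                    "mean_index_L": mean_l,
                    "mean_index_S": mean_s,
                    "delta": mean_l - mean_s,
                    "eff_depth": eff_d,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[list(WINDOW_COLUMNS)]


def simulate_null_ci(
    read_depths: list[int] | np.ndarray,
    bulk_size: int,
    reps: int = 10_000,
    confidence: tuple[float, ...] = (0.95, 0.99),
    seed: int = 0,
) -> NullCiTable:
    """Empirical null bounds of the single-SNP delta index per read depth.

    One replicate draws, independently for each bulk, an allele count
    k ~ Binomial(2*bulk_size, 1/2) — the bulk's composition in an F2 with
    no segregating locus — and then an alternate-read count
    ~ Binomial(depth, k/(2*bulk_size)).  The replicate's delta is
    index_L - index_S; bounds are the (1-conf)/2 and 1-(1-conf)/2
    empirical quantiles over ``reps`` replicates, separately per depth.
    Deterministic under a fixed seed.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    depths = np.unique(np.asarray(read_depths, dtype=np.int64))
    if depths.size == 0 or depths[0] < 1:
        raise ValueError("read depths must be positive")

    rng = np.random.default_rng(seed)
    per_conf: dict[float, list[tuple[int, float, float]]] = {c: [] for c in confidence}
    for depth in depths:
        deltas = _null_deltas(rng, int(depth), bulk_size, reps)
        for conf in confidence:
            alpha = (1.0 - conf) / 2.0
            lower, upper = np.quantile(deltas, [alpha, 1.0 - alpha])
            per_conf[conf].append((int(depth), float(lower), float(upper)))
    bounds = {
        conf: pd.DataFrame(vals, columns=["depth", "lower", "upper"])
        for conf, vals in per_conf.items()
    }
    return NullCiTable(bulk_size=bulk_size, reps=reps, bounds=bounds)


def _null_deltas(
    rng: np.random.Generator, depth: int, bulk_size: int, reps: int
) -> np.ndarray:
    """Vectorized draw of ``reps`` null delta-index replicates."""
    n_alleles = 2 * bulk_size
    k_l = rng.binomial(n_alleles, 0.5, size=reps)
    k_s = rng.binomial(n_alleles, 0.5, size=reps)
    idx_l = rng.binomial(depth, k_l / n_alleles) / depth
    idx_s = rng.binomial(depth, k_s / n_alleles) / depth
    return idx_l - idx_s


def attach_ci_and_call_regions(
    windows: pd.DataFrame,
    ci: NullCiTable,
    min_consecutive: int = 3,
    confidence: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag windows outside the null bounds and merge runs into regions.

    Each non-empty window gets the bounds of the nearest simulated depth
    (its rounded ``eff_depth``).  Runs of >= ``min_consecutive``
    consecutive significant windows with a consistent delta sign are
    merged into maximal candidate regions; each region reports its
    extreme-|delta| window as the peak.  An empty window list yields an
    empty region list.
    """
    out = windows.copy()
    if out.empty:
        out["ci_lower"] = out["ci_upper"] = out["significant"] = pd.Series(dtype=float)
        return out, pd.DataFrame(columns=list(REGION_COLUMNS))

    tab = ci.bounds.get(confidence)
    if tab is None:
        raise KeyError(f"confidence {confidence} not in the null CI table")
    depths = tab["depth"].to_numpy()
    eff = out["eff_depth"].to_numpy()
    nearest = np.argmin(np.abs(depths[None, :] - np.nan_to_num(eff)[:, None]), axis=1)
    lower = tab["lower"].to_numpy()[nearest]
    upper = tab["upper"].to_numpy()[nearest]
    empty = ~(out["n_snps"].to_numpy() > 0)
    out["ci_lower"] = np.where(empty, np.nan, lower)
    out["ci_upper"] = np.where(empty, np.nan, upper)
    delta = out["delta"].to_numpy()
    sig = ~empty & ((delta < out["ci_lower"].to_numpy()) | (delta > out["ci_upper"].to_numpy()))
    out["significant"] = sig

    regions = []
    for chrom, grp in out.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        run: list[int] = []
        run_sign = 0

        def flush() -> None:
            if len(run) >= min_consecutive:
                block = grp.loc[run]
                peak = block.loc[block["delta"].abs().idxmax()]
                regions.append(
                    (
                        chrom,
                        int(block["start"].iloc[0]),
                        int(block["end"].iloc[-1]),
                        float(peak["delta"]),
                        int(peak["start"]),
                        len(block),
                    )
                )

        for idx, row in grp.iterrows():
            sign = int(np.sign(row["delta"])) if row["significant"] else 0
            if sign != 0 and sign == run_sign:
                run.append(idx)
            else:
                flush()
                run = [idx] if sign != 0 else []
                run_sign = sign
        flush()
    return out, pd.DataFrame(regions, columns=list(REGION_COLUMNS))


def plot_delta_profile(windows: pd.DataFrame, path: str, regions: pd.DataFrame | None = None):
    """Plot the delta-SNP-index profile per chromosome (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, chrom in zip(axes, chroms):
        grp = windows[windows["chrom"] == chrom]
        mb = grp["start"] / 1e6
        ax.plot(mb, grp["delta"], lw=0.8, color="tab:blue")
        if "ci_lower" in grp:
            ax.plot(mb, grp["ci_lower"], lw=0.6, ls="--", color="gray")
            ax.plot(mb, grp["ci_upper"], lw=0.6, ls="--", color="gray")
        if regions is not None:
            for _, reg in regions[regions["chrom"] == chrom].iterrows():
                ax.axvspan(reg["start"] / 1e6, reg["end"] / 1e6, color="tab:red", alpha=0.2)
        ax.axhline(0.0, lw=0.5, color="black")
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
    axes[0].set_ylabel(r"$\Delta$ SNP index (L $-$ S)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
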