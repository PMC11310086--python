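"""Repeat ages, landscapes, and region association tests.

Kimura divergence-to-age conversion under a neutral clock, repeat
landscape binning, a binomial test for repeat-family expansion inside a
genomic region, a permutation test for association of repeat copies with
rearrangement breakpoints, and the differential-activity filter for
repeat expression statistics.

The repeat table is BED-like: columns ``copy_id``, ``family``,
``class``, ``chromosome``, ``start``, ``end`` (0-based half-open) and
``divergence`` (Kimura % to consensus, CpG-corrected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "divergence_to_age",
    "landscape",
    "region_expansion_test",
    "breakpoint_association_test",
    "repeat_de_filter",
]

#: neutral substitution rate estimated for the brittle star lineage,
#: substitutions per bp per year (from 4-fold degenerate sites)
DEFAULT_RATE = 1.885e-9


def divergence_to_age(divergence, rate: float = DEFAULT_RATE):
    """Convert divergence-to-consensus into an insertion age in Myr.

    The consensus approximates the ancestral sequence, and copies decay
    at the neutral rate r, so age = divergence / r (years), reported in
    Myr. E.g. 2% divergence at r = 1.885e-9 -> 10.6 Myr.

    Parameters
    ----------
    divergence : float or array
        Fraction (0.02 for 2%), not percent.
    rate : float
        Substitutions per bp per year; must be positive.
    """
    if rate <= 0:
        raise ValueError("substitution rate must be > 0")
    div = np.asarray(divergence, dtype=float)
    if np.any(div < 0):
        raise ValueError("divergence must be >= 0")
    age = div / rate / 1e6
    return float(age) if np.isscalar(divergence) else age


def landscape(
    repeats: pd.DataFrame,
    genome_length: float,
    bin_width: float = 1.0,
    merge_overlaps: bool = False,
) -> pd.DataFrame:
    """Repeat landscape: genome coverage per divergence bin per class.

    Bins partition [0, max divergence) with width ``bin_width`` (percent
    units, default 1%); coverage of a bin is the summed copy length of
    that bin divided by the genome length, stacked by repeat class.
    Overlapping copies are double-counted unless ``merge_overlaps``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    df = repeats.copy()
    df["length"] = df["end"] - df["start"]
    if merge_overlaps:
        # resolve overlaps within (class, bin, chromosome) via interval union
        df["bin"] = (df["divergence"] // bin_width) * bin_width
        rows = []
        for (cls, b, chrom), sub in df.groupby(["class", "bin", "chromosome"]):
            ivs = sorted(zip(sub["start"], sub["end"]))
            total, cur_s, cur_e = 0, None, None
            for s, e in ivs:
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
            rows.append((cls, b, total))
        agg = (
            pd.DataFrame(rows, columns=["class", "bin", "length"])
            .groupby(["class", "bin"])["length"]
            .sum()
        )
    else:
        df["bin"] = (df["divergence"] // bin_width) * bin_width
        agg = df.groupby(["class", "bin"])["length"].sum()
    out = (agg / genome_length).rename("coverage").reset_index()
    return out


def region_expansion_test(
    repeats: pd.DataFrame,
    region: tuple,
    genome_length: float,
    alpha: float = 0.05,
    min_length: int = 50,
) -> pd.DataFrame:
    """Binomial test for repeat-family expansion within a region.

    For a family with n copies genome-wide and k copies whose start
    falls in ``region`` = (chromosome, start, end), the one-sided
    p-value is P(X >= k) with X ~ Binomial(n, region_length /
    genome_length); BH correction across families. Copies shorter than
    ``min_length`` bp are ignored.
    """
    chrom, start, end = region
    if not (0 <= start < end <= genome_length):
        raise ValueError("region must lie within the genome")
    df = repeats[(repeats["end"] - repeats["start"]) >= min_length]
    frac = (end - start) / genome_length
    rows = []
    for fam, sub in df.groupby("family"):
        n = len(sub)
        if n == 0:
            continue
        k = int(
            (
                (sub["chromosome"] == chrom)
                & (sub["start"] >= start)
                & (sub["start"] < end)
            ).sum()
        )
        p = float(stats.binom.sf(k - 1, n, frac))
        rows.append((fam, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["family", "n_copies", "k_in_region", "pvalue"])
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < alpha
    return out


def breakpoint_association_test(
    repeats: pd.DataFrame,
    breakpoints,
    region: tuple,
    window: float = 10_000,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test for repeat-family association with breakpoints.

    The statistic is the number of copies of a family whose span
    intersects any breakpoint +/- ``window``. The null re-places the
    family's copies uniformly within ``region`` (lengths preserved)
    ``n_perm`` times; empirical p = (r + 1)/(N + 1) with r the number
    of replicates reaching the observed statistic; BH across families.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    start, end = region
    bps = np.asarray(sorted(breakpoints), dtype=float)
    if np.any((bps < start) | (bps > end)):
        raise ValueError("breakpoints must lie inside the region")
    lo = bps - window
    hi = bps + window
    rng = np.random.default_rng(seed)

    def stat(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        # copy [s, e) intersects some window [lo, hi] iff s <= hi and e > lo
        s = starts[..., None]
        e = ends[..., None]
        return ((s <= hi) & (e > lo)).any(axis=-1).sum(axis=-1)

    rows = []
    for fam, sub in repeats.groupby("family"):
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        if np.any(lengths > end - start):
            raise ValueError(
                f"region shorter than the longest copy of family {fam!r}"
            )
        obs = int(stat(sub["start"].to_numpy(float), sub["end"].to_numpy(float)))
        null_starts = start + rng.random((n_perm, len(sub))) * (
            (end - start) - lengths
        )
        null = stat(null_starts, null_starts + lengths)
        r = int((null >= obs).sum())
        rows.append((fam, len(sub), obs, (r + 1) / (n_perm + 1)))
    out = pd.DataFrame(
        rows, columns=["family", "n_copies", "n_near_breakpoint", "pvalue"]
    )
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < alpha
    return out


def repeat_de_filter(
    stats_table: pd.DataFrame,
    alpha: float = 0.001,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Differentially active repeat families.

    Retains rows with absolute log2 fold change strictly greater than
    ``lfc`` AND adjusted p below ``alpha`` (defaults |log2FC| > 1,
    p_adj < 0.001). If only raw p-values are present they are
    BH-adjusted first.
    """
    if "log2fc" not in stats_table.columns:
        raise ValueError("missing column log2fc")
    df = stats_table.copy()
    if "padj" not in df.columns:
        if "pvalue" not in df.columns:
            raise ValueError("missing padj (or pvalue) column")
        df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    keep = (df["log2fc"].abs() > lfc) & (df["padj"] < alpha)
    return df[keep].reset_index(drop=True)
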