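"""Pooled in-vivo shRNA dropout-screen scoring.

The scoring chain mirrors the two screen designs:

* screen 1 (genome-of-interest pool, 6 tumors per line): per-sample
  normalisation -> log10 transform -> robust-Z outlier masking across tumor
  replicates (|Z| > 5, at most 2 of 6 excluded, >= 4 retained) -> mean
  tumor/T0 log ratio -> Z-standardisation across shRNAs within cell line ->
  dropout if Z < -1.96 -> gene hit if >= 2 dropout shRNAs;
* screen 2 (small validation pool, 4 lines): the across-shRNA Z is not
  applicable (non-Gaussian, high hit fraction), so an shRNA scores on a raw
  log-ratio cutoff of -0.69 (fivefold depletion, log10) and gene hits are
  tiered high / medium / low by scoring in >= 3 / 2 / 1 of the 4 lines.

Robust Z uses the scale-robust estimate (x - median) / (1.4826 * MAD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ScreenCounts

__all__ = [
    "normalize_counts",
    "log_transform",
    "robust_z_exclude",
    "check_gaussian",
    "dropout_z",
    "gene_hits_screen1",
    "gene_hits_screen2",
    "fisher_exact_2x2",
    "score_screen1",
    "score_screen2",
    "tier_of",
]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826        # 1/Phi^-1(3/4): MAD -> sigma for a normal
MEANAD_SCALE = 1.2533     # sqrt(pi/2): mean absolute deviation -> sigma


def normalize_counts(raw: ScreenCounts, target_total: float = 1e7) -> ScreenCounts:
    """Scale every sample column to the same total read count.

    Preserves within-sample proportions (and therefore rank order); a sample
    with zero total reads is an error.
    """
    totals = raw.counts.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    scaled = raw.counts * (target_total / totals)
    return ScreenCounts(counts=scaled, gene_of=raw.gene_of.copy(),
                        samples=raw.samples.copy())


def log_transform(x: ScreenCounts, pseudocount: float = 0.1) -> ScreenCounts:
    """log10(count + pseudocount); the pseudocount keeps zeros representable."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return ScreenCounts(counts=np.log10(x.counts + pseudocount),
                        gene_of=x.gene_of.copy(), samples=x.samples.copy(),
                        log_scale=True)


def _robust_z_row(values: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); MAD = 0 falls back to scaled mean
    absolute deviation, and an all-equal row scores 0 everywhere."""
    med = np.median(values)
    dev = values - med
    mad = np.median(np.abs(dev))
    if mad > 0:
        return dev / (MAD_SCALE * mad)
    mean_ad = np.mean(np.abs(dev))
    if mean_ad == 0:
        return np.zeros_like(values)
    logger.info("MAD = 0 with unequal replicates; using mean absolute deviation")
    return dev / (MEANAD_SCALE * mean_ad)


def robust_z_exclude(
    log_counts: ScreenCounts,
    threshold: float = 5.0,
    max_excluded: int = 2,
) -> dict[str, pd.DataFrame]:
    """Flag outlier tumor replicates per (shRNA, cell line) by robust Z.

    Returns, per cell line, a DataFrame with the tumor-replicate robust-Z
    matrix and a boolean ``excluded`` mask of the same shape.  At most
    ``max_excluded`` replicates are dropped per shRNA, never leaving fewer
    than 4, choosing the largest |Z| first (ties by sample order).
    """
    out: dict[str, pd.DataFrame] = {}
    for line in log_counts.cell_lines:
        tumor_cols = log_counts.tumor_samples(line)
        n_reps = len(tumor_cols)
        if n_reps < 4:
            raise ValueError(
                f"cell line {line!r} has {n_reps} tumor replicates; need >= 4"
            )
        allowed = min(max_excluded, n_reps - 4)
        x = log_counts.counts[tumor_cols].to_numpy(dtype=float)
        z = np.apply_along_axis(_robust_z_row, 1, x)
        excluded = np.zeros_like(z, dtype=bool)
        flagged = np.abs(z) > threshold
        for i in np.nonzero(flagged.any(axis=1))[0]:
            cols = np.nonzero(flagged[i])[0]
            # largest |Z| first; np.argsort is stable so ties keep sample order
            order = cols[np.argsort(-np.abs(z[i, cols]), kind="stable")]
            excluded[i, order[:allowed]] = True
        out[line] = pd.DataFrame(
            {"shrna": np.repeat(log_counts.shrna_ids, n_reps),
             "sample": np.tile(tumor_cols, len(log_counts.shrna_ids)),
             "robust_z": z.ravel(),
             "excluded": excluded.ravel()}
        )
    return out


def check_gaussian(values, alpha: float = 0.01) -> tuple[float, float, bool]:
    """D'Agostino-Pearson omnibus (skewness + kurtosis) normality check.

    Advisory: a failing check emits a warning rather than aborting, since
    the downstream Z-scoring only needs approximate normality.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 20:
        raise ValueError("normality check needs >= 20 values")
    if np.std(arr) == 0:
        raise ValueError("normality check undefined for a constant vector")
    stat, p = stats.normaltest(arr)
    ok = bool(p >= alpha)
    if not ok:
        warnings.warn(
            f"log tumor/T0 ratios deviate from a Gaussian pattern "
            f"(normaltest p = {p:.3g}); Z-score dropout calls may be "
            f"miscalibrated", stacklevel=2,
        )
    return float(stat), float(p), ok


def _mean_log_ratios(
    normalized: ScreenCounts,
    line: str,
    excluded_mask: pd.DataFrame | None,
    pseudocount: float,
) -> pd.Series:
    """Per-shRNA log10(mean retained tumor reads / T0 reads) for one line."""
    tumor_cols = normalized.tumor_samples(line)
    t0_cols = normalized.t0_samples(line)
    tumor = normalized.counts[tumor_cols].to_numpy(dtype=float)
    t0 = normalized.counts[t0_cols].to_numpy(dtype=float).mean(axis=1)
    if excluded_mask is not None:
        mask = (
            excluded_mask.pivot(index="shrna", columns="sample", values="excluded")
            .reindex(index=normalized.counts.index, columns=tumor_cols)
            .to_numpy(dtype=bool)
        )
        tumor = np.ma.masked_array(tumor, mask=mask)
        mean_tumor = tumor.mean(axis=1).filled(np.nan)
    else:
        mean_tumor = tumor.mean(axis=1)
    ratio = np.log10(mean_tumor + pseudocount) - np.log10(t0 + pseudocount)
    return pd.Series(ratio, index=normalized.counts.index, name=line)


def dropout_z(
    log_ratios: pd.Series, z_cut: float = -1.96
) -> pd.DataFrame:
    """Standardise mean log ratios across shRNAs and call dropouts.

    z = (x - mean) / SD over all shRNAs within the cell line; dropout iff
    z < z_cut (default -1.96, two-tailed p < 0.05).  A zero across-shRNA SD
    is an error: Z-scores are undefined on a degenerate screen.
    """
    x = log_ratios.to_numpy(dtype=float)
    sd = x.std(ddof=0)
    if not sd > 0:
        raise ValueError("across-shRNA SD is zero; Z-scores undefined")
    z = (x - x.mean()) / sd
    return pd.DataFrame(
        {"log_ratio": x, "z": z, "dropout": z < z_cut}, index=log_ratios.index
    )


def tier_of(n_hit_lines: int) -> str:
    """Hit tier from the number of scoring cell lines (4-line design)."""
    if n_hit_lines >= 3:
        return "high"
    if n_hit_lines == 2:
        return "medium"
    if n_hit_lines == 1:
        return "low"
    return "none"


def _gene_line_hits(
    scoring: pd.DataFrame, gene_of: pd.Series, min_shrnas: int
) -> pd.DataFrame:
    """Per-gene per-line scoring-shRNA counts and hit flags.

    ``scoring`` is shRNA x line boolean."""
    counts = scoring.groupby(gene_of).sum()
    return counts >= min_shrnas


def gene_hits_screen1(
    dropouts: dict[str, pd.DataFrame], gene_of: pd.Series, min_shrnas: int = 2
) -> pd.DataFrame:
    """Gene-level hits: >= min_shrnas dropout shRNAs in a line.

    ``dropouts`` maps cell line -> the per-shRNA table from :func:`dropout_z`.
    Returns one row per gene with per-line hit flags, the number of hit lines
    and an ``any_line`` / ``all_lines`` summary.
    """
    scoring = pd.DataFrame({line: df["dropout"] for line, df in dropouts.items()})
    hits = _gene_line_hits(scoring, gene_of, min_shrnas)
    out = hits.copy()
    out["n_hit_lines"] = hits.sum(axis=1)
    out["any_line"] = hits.any(axis=1)
    out["all_lines"] = hits.all(axis=1)
    return out


def gene_hits_screen2(
    log_ratios: pd.DataFrame,
    gene_of: pd.Series,
    cutoff: float = -0.69,
    min_shrnas: int = 2,
) -> pd.DataFrame:
    """Cutoff-based gene hits with cross-line tiers.

    ``log_ratios`` is shRNA x cell-line mean log10(tumor/T0).  An shRNA
    scores in a line iff its log ratio <= cutoff (fivefold depletion at
    -0.69); a gene is a line hit with >= min_shrnas scoring shRNAs, and tiers
    are high / medium / low for >= 3 / 2 / 1 hit lines.
    """
    scoring = log_ratios <= cutoff
    hits = _gene_line_hits(scoring, gene_of, min_shrnas)
    out = hits.copy()
    out["n_hit_lines"] = hits.sum(axis=1)
    out["tier"] = out["n_hit_lines"].map(tier_of)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass convention: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.  A zero margin makes the table degenerate; p = 1 by
    convention (with a warning).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("2x2 table has a zero margin; p = 1 by convention",
                      stacklevel=2)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# end-to-end scoring


@dataclass
class ScreenScores:
    """Full screen-1-style scoring output for one counts table."""

    per_shrna: dict[str, pd.DataFrame]       # cell line -> shRNA table
    outliers: dict[str, pd.DataFrame]        # cell line -> robust-Z table
    gene_hits: pd.DataFrame
    gaussian_check: dict[str, tuple[float, float, bool]]


def score_screen1(
    raw: ScreenCounts,
    target_total: float = 1e7,
    pseudocount: float = 0.1,
    robust_threshold: float = 5.0,
    max_excluded: int = 2,
    z_cut: float = -1.96,
    min_shrnas: int = 2,
) -> ScreenScores:
    """Screen-1 pipeline: normalise, mask outliers, Z-score, call gene hits."""
    normalized = normalize_counts(raw, target_total=target_total)
    logged = log_transform(normalized, pseudocount=pseudocount)
    outliers = robust_z_exclude(logged, threshold=robust_threshold,
                                max_excluded=max_excluded)
    per_shrna: dict[str, pd.DataFrame] = {}
    gaussian: dict[str, tuple[float, float, bool]] = {}
    for line in raw.cell_lines:
        ratios = _mean_log_ratios(normalized, line, outliers[line], pseudocount)
        if ratios.size >= 20:
            gaussian[line] = check_gaussian(ratios)
        per_shrna[line] = dropout_z(ratios, z_cut=z_cut)
    hits = gene_hits_screen1(per_shrna, raw.gene_of, min_shrnas=min_shrnas)
    return ScreenScores(per_shrna=per_shrna, outliers=outliers,
                        gene_hits=hits, gaussian_check=gaussian)


def score_screen2(
    raw: ScreenCounts,
    target_total: float = 1e7,
    pseudocount: float = 0.1,
    robust_threshold: float = 5.0,
    max_excluded: int = 2,
    cutoff: float = -0.69,
    min_shrnas: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen-2 pipeline: raw log-ratio cutoff with cross-line tiers.

    Returns (shRNA x line mean log-ratio matrix, tiered gene-hit table).
    """
    normalized = normalize_counts(raw, target_total=target_total)
    logged = log_transform(normalized, pseudocount=pseudocount)
    outliers = robust_z_exclude(logged, threshold=robust_threshold,
                                max_excluded=max_excluded)
    ratios = pd.DataFrame(
        {line: _mean_log_ratios(normalized, line, outliers[line], pseudocount)
         for line in raw.cell_lines}
    )
    hits = gene_hits_screen2(ratios, raw.gene_of, cutoff=cutoff,
                             min_shrnas=min_shrnas)
    return ratios, hits
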