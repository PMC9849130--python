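"""Category-level disease-association enrichment via matched resampling.

For a set of annotated variants (e.g. one clinical-significance category)
we count how many have at least one association below each P value
threshold, then compare against 1,000 random draws of intergenic variants
matched on allele frequency (15 equal-count quantile bins of the
category's AF distribution) and genomic position (same fixed 3-Mb window),
yielding empirical P values.  Also houses the founder-population
enrichment flag (cohort AF more than twice the external reference AF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantRecord

DEFAULT_THRESHOLDS = (1e-4, 1e-5, 1e-6, 5e-8)


@dataclass
class EnrichmentResult:
    category: str
    thresholds: tuple[float, ...]
    observed: np.ndarray          # (n_thresholds,) counts
    null_counts: np.ndarray       # (n_samples, n_thresholds)
    empirical_p: np.ndarray       # (n_thresholds,)
    fallback_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_null = self.null_counts.shape[0]
        lo, hi = 1.0 / (n_null + 1), 1.0
        if np.any(self.empirical_p < lo - 1e-12) or np.any(self.empirical_p > hi + 1e-12):
            raise ValueError("empirical p outside [1/(n_null+1), 1]")


def assign_af_bins(category: Sequence[VariantRecord], pool: Sequence[VariantRecord],
                   n_bins: int = 15) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Equal-count AF bins of the category; map category and pool into them.

    Returns ``(edges, category_bins, pool_bins)``; ``pool_bins`` is -1 for
    pool variants whose AF falls outside the category's AF range.
    """
    cat_af = np.array([v.af_alt for v in category], dtype=float)
    pool_af = np.array([v.af_alt for v in pool], dtype=float)
    if np.any(~((cat_af > 0) & (cat_af < 1))) or (len(pool_af) and
                                                  np.any(~((pool_af > 0) & (pool_af < 1)))):
        raise ValueError("allele frequencies must lie in (0, 1)")
    if len(cat_af) < n_bins:
        raise ValueError(
            f"category has {len(cat_af)} variants, fewer than {n_bins} bins; "
            "reduce n_af_bins")
    cat_bins, edges = pd.qcut(cat_af, n_bins, labels=False, retbins=True, duplicates="drop")
    cat_bins = np.asarray(cat_bins, dtype=int)
    pool_bins = np.searchsorted(edges[1:-1], pool_af, side="left")
    out_of_range = (pool_af < edges[0]) | (pool_af > edges[-1])
    pool_bins = np.where(out_of_range, -1, pool_bins)
    return edges, cat_bins, pool_bins


def _window(v: VariantRecord, window_bp: int) -> tuple[str, int]:
    """Fixed non-overlapping tiles anchored at chromosome start (pos 1-based)."""
    return v.chrom, (v.pos - 1) // window_bp


def observed_hit_counts(category: Sequence[VariantRecord], best_p: Mapping[str, float],
                        thresholds: Sequence[float]) -> np.ndarray:
    """Number of category variants with >= 1 association below each threshold."""
    p = np.array([best_p.get(v.key, 1.0) for v in category], dtype=float)
    return np.array([(p < t).sum() for t in thresholds], dtype=int)


def sample_matched_null(category: Sequence[VariantRecord], pool: Sequence[VariantRecord],
                        best_p: Mapping[str, float], n_samples: int = 1000,
                        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                        n_bins: int = 15, window_bp: int = 3_000_000,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, list[str]]:
    """Null hit-count matrix from AF- and position-matched intergenic draws.

    Each of the ``n_samples`` draws picks, for every category variant, one
    pool variant from the same AF bin AND the same ``window_bp`` tile,
    without replacement within the sample.  When a (bin, window) cell has
    no remaining candidate the draw falls back to bin-only matching and
    the event is logged.  Returns ``(null_counts, fallback_log)``.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is mandatory for null sampling")
        rng = np.random.default_rng(seed)
    _, cat_bins, pool_bins = assign_af_bins(category, pool, n_bins=n_bins)
    pool_windows = [_window(v, window_bp) for v in pool]
    pool_p = np.array([best_p.get(v.key, 1.0) for v in pool], dtype=float)
    thresholds = tuple(thresholds)

    # candidate index lists per (bin, window) and per bin
    by_cell: dict[tuple[int, str, int], list[int]] = {}
    by_bin: dict[int, list[int]] = {}
    for i, (b, w) in enumerate(zip(pool_bins, pool_windows)):
        if b < 0:
            continue
        by_cell.setdefault((b, *w), []).append(i)
        by_bin.setdefault(b, []).append(i)

    log: list[str] = []
    null = np.zeros((n_samples, len(thresholds)), dtype=int)
    cat_keys = [(b, *_window(v, window_bp)) for b, v in zip(cat_bins, category)]
    for s in range(n_samples):
        used: set[int] = set()
        drawn: list[int] = []
        for (cell, b, v) in zip(cat_keys, cat_bins, category):
            cands = [i for i in by_cell.get(cell, ()) if i not in used]
            if not cands:
                cands = [i for i in by_bin.get(int(b), ()) if i not in used]
                if not cands:
                    raise ValueError(
                        f"pool exhausted for AF bin {int(b)} (variant {v.key}); "
                        "enlarge the intergenic pool")
                log.append(f"sample {s}: bin-only fallback for {v.key} (empty cell {cell})")
            pick = cands[int(rng.integers(len(cands)))]
            used.add(pick)
            drawn.append(pick)
        ps = pool_p[drawn]
        null[s] = [(ps < t).sum() for t in thresholds]
    return null, log


def empirical_p(observed: int | np.ndarray, null: np.ndarray) -> float | np.ndarray:
    """Add-one empirical P: ``(1 + #{null >= observed}) / (1 + n_null)``."""
    null = np.asarray(null)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if null.ndim == 1:
        return float((1 + (null >= observed).sum()) / (1 + len(null)))
    observed = np.asarray(observed)
    n = null.shape[0]
    return (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n)


def run_enrichment(category_label: str, category: Sequence[VariantRecord],
                   pool: Sequence[VariantRecord], best_p: Mapping[str, float],
                   n_samples: int = 1000, thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                   n_bins: int = 15, window_bp: int = 3_000_000,
                   seed: int | None = None) -> EnrichmentResult:
    observed = observed_hit_counts(category, best_p, thresholds)
    null, log = sample_matched_null(category, pool, best_p, n_samples=n_samples,
                                    thresholds=thresholds, n_bins=n_bins,
                                    window_bp=window_bp, seed=seed)
    return EnrichmentResult(category=category_label, thresholds=tuple(thresholds),
                            observed=observed, null_counts=null,
                            empirical_p=np.asarray(empirical_p(observed, null)),
                            fallback_log=log)


def fin_enrichment(af_cohort: float, af_ref_pop: float,
                   ratio_threshold: float = 2.0) -> tuple[float, bool]:
    """Founder-enrichment flag: cohort AF / reference AF above threshold.

    A reference frequency of exactly 0 yields an infinite ratio and the
    enriched flag (documented convention).
    """
    if not 0.0 < af_cohort <= 1.0:
        raise ValueError(f"af_cohort must be in (0,1], got {af_cohort}")
    if not 0.0 <= af_ref_pop <= 1.0:
        raise ValueError(f"af_ref_pop must be in [0,1], got {af_ref_pop}")
    if af_ref_pop == 0.0:
        return float("inf"), True
    ratio = af_cohort / af_ref_pop
    return ratio, ratio > ratio_threshold
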