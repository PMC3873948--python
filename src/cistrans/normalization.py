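"""Trimmed mean of M-values (TMM) scaling across the four count columns.

The two parental libraries and the two hybrid allele columns are put on a
common scale by treating each of the four count columns as a library.
TMM computes, for every column against a reference column, the
doubly-trimmed (by log-ratio M and by absolute log-intensity A),
precision-weighted mean of gene-wise log2 expression ratios; the
resulting scaling factors multiply the raw library totals into effective
library sizes.  Factors are rescaled so their geometric mean is 1.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats as scipy_stats

__all__ = ["NormalizationFactors", "tmm_factors", "normalized_value"]

log = logging.getLogger(__name__)

COLUMNS = ("p1", "p2", "h1", "h2")


@dataclasses.dataclass(frozen=True)
class NormalizationFactors:
    """Per-column TMM scaling factors and effective library sizes.

    ``effective_sizes[i] = raw_totals[i] * factors[i]``; the geometric
    mean of the factors is 1 by convention, so depth differences live in
    the raw totals and composition differences in the factors.
    """

    factors: tuple[float, float, float, float]
    raw_totals: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        if np.any(f <= 0):
            raise ValueError(f"TMM factors must be positive, got {self.factors}")
        if abs(float(np.exp(np.mean(np.log(f)))) - 1.0) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_sizes(self) -> tuple[float, float, float, float]:
        return tuple(
            t * f for t, f in zip(self.raw_totals, self.factors)
        )  # type: ignore[return-value]

    def effective_size(self, column: int | str) -> float:
        return self.effective_sizes[_col_index(column)]

    @classmethod
    def identity(
        cls, raw_totals: Sequence[float] = (1.0, 1.0, 1.0, 1.0)
    ) -> "NormalizationFactors":
        """Unit factors — no composition correction (e.g. simulations)."""
        return cls(factors=(1.0,) * 4, raw_totals=tuple(float(t) for t in raw_totals))


def _col_index(column: int | str) -> int:
    if isinstance(column, str):
        return COLUMNS.index(column)
    return int(column)


def _quantile_depth_fraction(counts: np.ndarray, totals: np.ndarray, p: float = 0.75) -> np.ndarray:
    # per-column p-quantile of count/libsize, edgeR's reference heuristic
    return np.quantile(counts / totals, p, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    min_usable: int,
) -> float:
    """TMM factor of one column against the reference column.

    Genes with a zero in either column are excluded (no pseudo-counts in
    normalization); with fewer than ``min_usable`` usable genes the factor
    falls back to 1.0 with a warning.
    """
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if obs.size < min_usable:
        log.warning(
            "TMM: only %d usable genes in pair (min %d); factor falls back to 1.0",
            obs.size,
            min_usable,
        )
        return 1.0
    po, pr = obs / n_obs, ref / n_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # inverse asymptotic variance of M under Poisson-binomial sampling
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(M)) < 1e-6:  # identical composition
        return 1.0
    n = M.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = scipy_stats.rankdata(M)  # average ranks on ties
    rank_a = scipy_stats.rankdata(A)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2) or np.sum(1.0 / w[keep2]) == 0:
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    count_matrix: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | str = "auto",
    min_usable_genes: int = 10,
    raw_totals: Sequence[float] | None = None,
) -> NormalizationFactors:
    """TMM scaling factors for a genes x columns count matrix.

    Parameters
    ----------
    count_matrix
        Non-negative integer matrix, one row per gene, columns in the
        order ``p1 p2 h1 h2`` (any column count >= 2 is accepted).
    trim_m, trim_a
        Two-sided trim fractions on the log-ratio (M) and absolute
        log-intensity (A) scales; defaults 30% / 5%.
    reference
        Reference column index, or ``"auto"``: the column whose
        75th-percentile count fraction is closest to the mean of those
        fractions.
    min_usable_genes
        Below this many jointly-positive genes in a pair, the pair's
        factor falls back to 1.0 (warning logged).
    raw_totals
        Library sizes used for effective sizes; defaults to the column
        sums of ``count_matrix``.  Pass full-library (pre-filter) totals
        when the matrix holds a filtered gene subset.
    """
    x = np.asarray(count_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("count_matrix must be 2-D with at least 2 columns")
    totals = x.sum(axis=0)
    if np.any(totals <= 0):
        bad = [i for i, t in enumerate(totals) if t <= 0]
        raise ValueError(f"column(s) {bad} have zero total; cannot normalize")
    if reference == "auto":
        q = _quantile_depth_fraction(x, totals)
        ref_idx = int(np.argmin(np.abs(q - q.mean())))
    else:
        ref_idx = _col_index(reference)
    f = np.ones(x.shape[1])
    for i in range(x.shape[1]):
        if i == ref_idx:
            continue
        f[i] = _tmm_pair(
            x[:, i], x[:, ref_idx], totals[i], totals[ref_idx],
            trim_m, trim_a, min_usable_genes,
        )
    f = f / np.exp(np.mean(np.log(f)))
    if raw_totals is None:
        raw_totals = totals
    return NormalizationFactors(
        factors=tuple(float(v) for v in f),
        raw_totals=tuple(float(t) for t in raw_totals),
    )


def normalized_value(
    count: float, column: int | str, factors: NormalizationFactors
) -> float:
    """Count rescaled to the mean effective depth of the four columns.

    ``count / effective_size(column) * mean(effective_sizes)``; zero maps
    to zero and the map is monotone in ``count``.
    """
    eff = factors.effective_sizes
    return float(count) / eff[_col_index(column)] * float(np.mean(eff))
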