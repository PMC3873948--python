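"""Gene-wise G-tests for total, cis- and trans-regulatory divergence.

Three likelihood-ratio (G) tests are run per gene, each on 1 degree of
freedom:

* **TDE** (total differential expression): the two parental counts
  against the null ratio of effective parental library sizes.
* **cis**: the two F1 allele counts against the null ratio of effective
  allele-column sizes, multiplied by the gene's residual mapping-bias
  factor — an allelic imbalance inside the common F1 cellular
  environment is evidence of cis-regulatory divergence.
* **trans**: a 2x2 independence test of the parental count pair against
  the F1 allele count pair (both rescaled to common depth) — a change in
  the allelic ratio between parental and hybrid background is evidence
  of trans-regulatory divergence.

TDE and cis use the goodness-of-fit form with a *fixed* null ratio
(library-size ratios are treated as known constants, backed by millions
of reads); the trans test uses the independence form because both ratios
are gene-level measurements.  No Williams or continuity correction is
applied.  Raw p-values are Benjamini-Hochberg adjusted separately per
test family.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import GeneCountRecord, LibraryTotals
from .normalization import NormalizationFactors

__all__ = [
    "DegenerateTableError",
    "TestResult",
    "Magnitudes",
    "g_test_2x2",
    "g_test_given_ratio",
    "tde_test",
    "cis_test",
    "trans_test",
    "bh_adjust",
    "magnitudes",
    "run_all_tests",
]

log = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin; the G statistic is undefined."""


def _xlogy(o: np.ndarray, e: np.ndarray) -> np.ndarray:
    # O * ln(O/E) with the 0 * ln(0) = 0 convention
    return np.where(o > 0, o * np.log(np.where(o > 0, o, 1.0) / e), 0.0)


def g_2x2_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2x2 G-test. Returns (G, p, degenerate mask).

    Degenerate tables (a zero row or column margin) get G = 0, p = 1 and
    a True mask entry; the scalar wrapper raises instead.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    degenerate = (r1 == 0) | (r2 == 0) | (c1 == 0) | (c2 == 0)
    safe_n = np.where(n > 0, n, 1.0)
    G = np.zeros(np.broadcast(a, b, c, d).shape)
    for o, er, ec in ((a, r1, c1), (b, r1, c2), (c, r2, c1), (d, r2, c2)):
        e = np.where(degenerate, 1.0, er * ec / safe_n)
        G = G + _xlogy(o, e)
    G = np.where(degenerate, 0.0, 2.0 * G)
    G = np.maximum(G, 0.0)  # clip tiny negative round-off
    p = np.where(degenerate, 1.0, stats.chi2.sf(G, df=1))
    return G, p, degenerate


def g_test_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """G-test of independence on the 2x2 table ``[[a, b], [c, d]]``.

    ``G = 2 * sum O * ln(O/E)`` with expectations from the row/column
    margins; p from the chi-square distribution with 1 df.  Raises
    :class:`DegenerateTableError` on a zero margin (callers map this to
    G = 0, p = 1 and log the gene).
    """
    G, p, degenerate = g_2x2_arrays(a, b, c, d)
    if bool(degenerate):
        raise DegenerateTableError(f"zero margin in table ({a}, {b} / {c}, {d})")
    return float(G), float(p)


def g_gof_arrays(
    x1: np.ndarray, x2: np.ndarray, null_ratio: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized goodness-of-fit G-test of ``x1:x2`` against a fixed ratio.

    Expected counts split the observed total in proportion
    ``null_ratio : 1``.  Returns (G, p, degenerate mask); degenerate
    means ``x1 + x2 == 0``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    r = np.asarray(null_ratio, dtype=float)
    if np.any(r <= 0):
        raise ValueError("null_ratio must be positive")
    tot = x1 + x2
    degenerate = tot == 0
    safe_tot = np.where(degenerate, 1.0, tot)
    e1 = safe_tot * r / (1.0 + r)
    e2 = safe_tot / (1.0 + r)
    G = 2.0 * (_xlogy(x1, e1) + _xlogy(x2, e2))
    G = np.where(degenerate, 0.0, np.maximum(G, 0.0))
    p = np.where(degenerate, 1.0, stats.chi2.sf(G, df=1))
    return G, p, degenerate


def g_test_given_ratio(
    x1: int, x2: int, null_ratio: float
) -> tuple[float, float]:
    """Goodness-of-fit G-test of the pair ``(x1, x2)`` against a known ratio.

    The null expects ``x1 / x2 = null_ratio``.  A zero total is
    degenerate and returns (0.0, 1.0) with a logged flag.
    """
    G, p, degenerate = g_gof_arrays(x1, x2, null_ratio)
    if bool(degenerate):
        log.debug("degenerate ratio test: x1 = x2 = 0")
        return 0.0, 1.0
    return float(G), float(p)


# ---------------------------------------------------------------------------
# per-gene tests


def tde_test(
    record: GeneCountRecord,
    totals: LibraryTotals,
    factors: NormalizationFactors,
) -> tuple[float, float]:
    """Total differential expression between the parents.

    Compares ``p1 : p2`` to the ratio of effective parental library
    sizes.
    """
    eff = factors.effective_sizes
    return g_test_given_ratio(record.p1, record.p2, eff[0] / eff[1])


def cis_test(
    record: GeneCountRecord,
    totals: LibraryTotals,
    factors: NormalizationFactors,
) -> tuple[float, float]:
    """Allele-specific expression in the F1 hybrid (cis-effects).

    Compares ``h1 : h2`` to the global allelic ratio (effective
    allele-column sizes) scaled by the gene's residual mapping-bias
    factor, so that the null already accounts for alignment preference.
    """
    eff = factors.effective_sizes
    return g_test_given_ratio(
        record.h1, record.h2, record.bias_factor * eff[2] / eff[3]
    )


def _trans_table(
    record: GeneCountRecord,
    factors: NormalizationFactors,
    apply_bias: bool = True,
) -> tuple[int, int, int, int]:
    """Bias-corrected, depth-rescaled integer 2x2 table for the trans test."""
    eff = np.asarray(factors.effective_sizes)
    mean_eff = eff.mean()
    h1 = record.h1 / record.bias_factor if apply_bias else record.h1
    raw = np.array([record.p1, record.p2, h1, record.h2], dtype=float)
    primed = np.rint(raw / eff * mean_eff).astype(int)  # half-to-even
    return tuple(int(v) for v in primed)  # type: ignore[return-value]


def trans_test(
    record: GeneCountRecord,
    factors: NormalizationFactors,
    apply_bias: bool = True,
) -> tuple[float, float]:
    """Change of the allelic ratio between parents and hybrid (trans-effects).

    2x2 independence G-test of the parental pair against the F1 allele
    pair; counts are bias-corrected (``h1 / bias_factor``, switchable via
    ``apply_bias``), rescaled to common effective depth and rounded
    half-to-even.  A zero margin after rounding is degenerate: G = 0,
    p = 1, flag logged.
    """
    a, b, c, d = _trans_table(record, factors, apply_bias)
    try:
        return g_test_2x2(a, b, c, d)
    except DegenerateTableError:
        log.debug("gene %s: degenerate trans table %s", record.gene_id, (a, b, c, d))
        return 0.0, 1.0


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# effect sizes


@dataclasses.dataclass(frozen=True)
class Magnitudes:
    """Signed and absolute cis/trans log2 effect sizes for one gene.

    cis magnitude is |log2| of the normalized hybrid allelic ratio;
    trans magnitude is |log2 parental ratio - log2 hybrid allelic ratio|.
    Ratios are computed on normalized, bias-corrected values; a
    pseudo-count keeps them finite when a raw count is zero.
    """

    cis_log2: float
    trans_log2: float
    defined: bool = True

    @property
    def cis_mag(self) -> float:
        return abs(self.cis_log2)

    @property
    def trans_mag(self) -> float:
        return abs(self.trans_log2)


def magnitudes(
    record: GeneCountRecord,
    factors: NormalizationFactors,
    pseudo: float = 0.5,
) -> Magnitudes:
    """Cis/trans effect magnitudes on normalized, bias-corrected values.

    If any of the four counts is zero: with ``pseudo > 0`` the
    pseudo-count is added to all four normalized values first; with
    ``pseudo = 0`` the magnitudes are undefined (``defined = False``,
    both log-ratios NaN).
    """
    eff = np.asarray(factors.effective_sizes)
    raw = np.array(
        [record.p1, record.p2, record.h1 / record.bias_factor, record.h2],
        dtype=float,
    )
    vals = raw / eff * eff.mean()
    if np.any(raw == 0):
        if pseudo <= 0:
            return Magnitudes(float("nan"), float("nan"), defined=False)
        vals = vals + pseudo
    cis_log2 = float(np.log2(vals[2] / vals[3]))
    parental_log2 = float(np.log2(vals[0] / vals[1]))
    return Magnitudes(cis_log2=cis_log2, trans_log2=parental_log2 - cis_log2)


# ---------------------------------------------------------------------------
# batch driver


@dataclasses.dataclass(frozen=True)
class TestResult:
    """All three G-tests for one gene with BH-adjusted q-values."""

    gene_id: str
    G_tde: float
    p_tde: float
    q_tde: float
    G_cis: float
    p_cis: float
    q_cis: float
    G_trans: float
    p_trans: float
    q_trans: float
    sig_tde: bool
    sig_cis: bool
    sig_trans: bool


def run_all_tests(
    records: Sequence[GeneCountRecord],
    totals: LibraryTotals,
    factors: NormalizationFactors,
    fdr_threshold: float = 0.05,
    pseudo: float = 0.5,
    trans_apply_bias: bool = True,
    form: str = "gof",
) -> pd.DataFrame:
    """Run TDE / cis / trans tests over all (filtered) genes.

    Each family is BH-adjusted separately across genes; significance
    flags compare q-values to ``fdr_threshold``.  Magnitudes and signed
    log-ratios are attached; degenerate tables are kept (non-significant)
    with a flag so gene sets stay aligned across outputs.

    ``form`` selects how the TDE and cis tests treat the library ratio:
    ``"gof"`` (default) takes it as a known constant (goodness-of-fit,
    the library totals sit on millions of reads); ``"independence"``
    re-estimates it from a full 2x2 table whose second row is the rest of
    the library — a sensitivity analysis that should barely move the
    statistics.  ``trans_apply_bias`` switches the mapping-bias division
    of ``h1`` inside the trans test.

    Returns a DataFrame with one row per gene in input order.
    """
    if len(records) == 0:
        raise ValueError("no records to test")
    if form not in ("gof", "independence"):
        raise ValueError(f"unknown G-test form {form!r}")
    eff = np.asarray(factors.effective_sizes)
    p1 = np.array([r.p1 for r in records], dtype=float)
    p2 = np.array([r.p2 for r in records], dtype=float)
    h1 = np.array([r.h1 for r in records], dtype=float)
    h2 = np.array([r.h2 for r in records], dtype=float)
    bias = np.array([r.bias_factor for r in records], dtype=float)

    if form == "gof":
        G_tde, p_tde, deg_tde = g_gof_arrays(p1, p2, eff[0] / eff[1])
        G_cis, p_cis, deg_cis = g_gof_arrays(h1, h2, bias * eff[2] / eff[3])
    else:
        t1, t2 = float(totals.p1), float(totals.p2)
        G_tde, p_tde, deg_tde = g_2x2_arrays(p1, p2, t1 - p1, t2 - p2)
        a1 = np.rint(h1 / bias)
        t3, t4 = float(totals.h1), float(totals.h2)
        G_cis, p_cis, deg_cis = g_2x2_arrays(a1, h2, t3 - a1, t4 - h2)
    hb = h1 / bias if trans_apply_bias else h1
    primed = np.rint(
        np.column_stack([p1, p2, hb, h2]) / eff * eff.mean()
    )
    G_trans, p_trans, deg_trans = g_2x2_arrays(
        primed[:, 0], primed[:, 1], primed[:, 2], primed[:, 3]
    )

    q_tde = bh_adjust(p_tde)
    q_cis = bh_adjust(p_cis)
    q_trans = bh_adjust(p_trans)

    mags = [magnitudes(r, factors, pseudo=pseudo) for r in records]
    n_deg = int(deg_tde.sum() + deg_cis.sum() + deg_trans.sum())
    if n_deg:
        log.info("degenerate tables mapped to G=0, p=1: %d", n_deg)

    flags = [
        ";".join(
            name
            for name, d in (
                ("deg_tde", dt), ("deg_cis", dc), ("deg_trans", dr)
            )
            if d
        )
        for dt, dc, dr in zip(deg_tde, deg_cis, deg_trans)
    ]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "G_tde": G_tde, "p_tde": p_tde, "q_tde": q_tde,
            "G_cis": G_cis, "p_cis": p_cis, "q_cis": q_cis,
            "G_trans": G_trans, "p_trans": p_trans, "q_trans": q_trans,
            "sig_tde": q_tde <= fdr_threshold,
            "sig_cis": q_cis <= fdr_threshold,
            "sig_trans": q_trans <= fdr_threshold,
            "cis_log2": [m.cis_log2 for m in mags],
            "trans_log2": [m.trans_log2 for m in mags],
            "cis_mag": [m.cis_mag for m in mags],
            "trans_mag": [m.trans_mag for m in mags],
            "mag_defined": [m.defined for m in mags],
            "flags": flags,
        }
    )
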