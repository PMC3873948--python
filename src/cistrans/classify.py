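"""Regulatory categories and inheritance modes.

The joint significance pattern of the three tests (TDE between parents,
cis in the hybrid, trans between backgrounds) maps each gene onto one of
seven regulatory categories:

=========  ===  ===  =====
category   TDE  cis  trans
=========  ===  ===  =====
conserved   -    -    -
cis         +    +    -
trans       +    -    +
compensatory -   +    +   (cis and trans cancel in total expression)
cis+trans   +    +    +   cis and trans effects act in the same direction
cis-by-trans +   +    +   cis and trans effects act in opposite directions
ambiguous   every other pattern
=========  ===  ===  =====

Inheritance modes compare F1 total expression to the two parents:
additive (intermediate), dominant towards either parent, over-/
under-dominant (outside the parental range, jointly "misexpressed"),
or conserved expression.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import GeneCountRecord, LibraryTotals
from .gtests import bh_adjust, g_gof_arrays
from .normalization import NormalizationFactors

__all__ = [
    "CATEGORIES",
    "MODES",
    "regulatory_category",
    "classify_regulatory",
    "run_inheritance_tests",
    "inheritance_mode",
    "classify_inheritance",
    "summarize",
    "magnitude_comparison",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "conserved",
    "ambiguous",
)

MODES = (
    "additive",
    "dominant_p1",
    "dominant_p2",
    "overdominant",
    "underdominant",
    "conserved_expression",
)


def _sign(x: float) -> int:
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def regulatory_category(
    sig_tde: bool,
    sig_cis: bool,
    sig_trans: bool,
    cis_log2: float = 0.0,
    trans_log2: float = 0.0,
) -> str:
    """Map one gene's significance pattern (and effect directions) to a category.

    The direction split of the all-significant pattern uses the signs of
    the cis log-ratio and the trans log-ratio difference: same sign means
    the two effects reinforce (cis+trans), opposite non-zero signs mean
    they oppose (cis-by-trans).  A zero direction in that branch is
    uninterpretable and goes to ambiguous.
    """
    t, c, r = bool(sig_tde), bool(sig_cis), bool(sig_trans)
    if not t and not c and not r:
        return "conserved"
    if t and c and not r:
        return "cis"
    if t and not c and r:
        return "trans"
    if not t and c and r:
        return "compensatory"
    if t and c and r:
        sc, sr = _sign(cis_log2), _sign(trans_log2)
        if sc == 0 or sr == 0:
            log.debug("zero effect direction in all-significant pattern -> ambiguous")
            return "ambiguous"
        return "cis_plus_trans" if sc == sr else "cis_by_trans"
    return "ambiguous"


def classify_regulatory(results: pd.DataFrame) -> pd.DataFrame:
    """Categorize every gene of a :func:`~cistrans.gtests.run_all_tests` frame.

    Returns gene_id, category and the +/-/0 effect directions.
    """
    cats = [
        regulatory_category(
            row.sig_tde, row.sig_cis, row.sig_trans, row.cis_log2, row.trans_log2
        )
        for row in results.itertuples(index=False)
    ]
    dir_char = {1: "+", -1: "-", 0: "0"}
    return pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "category": pd.Categorical(cats, categories=CATEGORIES),
            "cis_dir": [dir_char[_sign(v)] for v in results["cis_log2"]],
            "trans_dir": [dir_char[_sign(v)] for v in results["trans_log2"]],
        }
    )


# ---------------------------------------------------------------------------
# inheritance


def run_inheritance_tests(
    records: Sequence[GeneCountRecord],
    totals: LibraryTotals,
    factors: NormalizationFactors,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Three expression-intensity comparisons per gene, BH-adjusted per family.

    F1 total expression is ``h1 + h2`` with effective size equal to the
    sum of the two allele-column effective sizes.  Each comparison
    (P1 vs P2, F1 vs P1, F1 vs P2) is a goodness-of-fit G-test against
    the corresponding effective-size ratio, corrected across genes within
    its own family.  Also reports the depth-normalized expression values
    used for the ordering of the three samples.
    """
    eff = np.asarray(factors.effective_sizes)
    mean_eff = eff.mean()
    eff_f1 = eff[2] + eff[3]
    p1 = np.array([r.p1 for r in records], dtype=float)
    p2 = np.array([r.p2 for r in records], dtype=float)
    f1 = np.array([r.h1 + r.h2 for r in records], dtype=float)

    _, p_p1p2, _ = g_gof_arrays(p1, p2, eff[0] / eff[1])
    _, p_f1p1, _ = g_gof_arrays(f1, p1, eff_f1 / eff[0])
    _, p_f1p2, _ = g_gof_arrays(f1, p2, eff_f1 / eff[1])

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "sig_p1_p2": bh_adjust(p_p1p2) <= fdr_threshold,
            "sig_f1_p1": bh_adjust(p_f1p1) <= fdr_threshold,
            "sig_f1_p2": bh_adjust(p_f1p2) <= fdr_threshold,
            "P1_norm": p1 / eff[0] * mean_eff,
            "P2_norm": p2 / eff[1] * mean_eff,
            "F1_norm": f1 / eff_f1 * mean_eff,
        }
    )


def inheritance_mode(
    sig_p1_p2: bool,
    sig_f1_p1: bool,
    sig_f1_p2: bool,
    p1_norm: float,
    p2_norm: float,
    f1_norm: float,
) -> str:
    """One gene's inheritance mode from the three comparisons and the ordering.

    Over-/under-dominance: F1 significantly outside the parental range on
    both sides.  Additive: parents differ, F1 differs from both and lies
    strictly between them.  Dominant: parents differ and F1 is
    indistinguishable from exactly one of them.  Every residual pattern
    folds into conserved expression, so the modes partition all genes.
    """
    lo, hi = min(p1_norm, p2_norm), max(p1_norm, p2_norm)
    if sig_f1_p1 and sig_f1_p2:
        if f1_norm > hi:
            return "overdominant"
        if f1_norm < lo:
            return "underdominant"
        if sig_p1_p2 and lo < f1_norm < hi:
            return "additive"
        return "conserved_expression"
    if sig_p1_p2 and not sig_f1_p1 and sig_f1_p2:
        return "dominant_p1"
    if sig_p1_p2 and sig_f1_p1 and not sig_f1_p2:
        return "dominant_p2"
    return "conserved_expression"


def classify_inheritance(inh: pd.DataFrame) -> pd.DataFrame:
    """Mode per gene from a :func:`run_inheritance_tests` frame."""
    modes = [
        inheritance_mode(
            row.sig_p1_p2, row.sig_f1_p1, row.sig_f1_p2,
            row.P1_norm, row.P2_norm, row.F1_norm,
        )
        for row in inh.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "gene_id": inh["gene_id"],
            "inheritance_mode": pd.Categorical(modes, categories=MODES),
        }
    )


# ---------------------------------------------------------------------------
# summaries


def summarize(
    calls: pd.DataFrame,
    modes: pd.DataFrame | None = None,
    results: pd.DataFrame | None = None,
) -> dict:
    """Tallies and percentages over a call set.

    Includes the derived totals: overall number of cis-significant and
    trans-significant genes (cut across categories, including the
    ambiguous ones whose cis/trans test fired), the misexpressed count
    (over- plus under-dominant) and the dominant split by parent.
    """
    n = len(calls)
    cat_counts = (
        calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
        if n else pd.Series(0, index=CATEGORIES)
    )
    out: dict = {
        "n_genes": int(n),
        "categories": {
            k: {"count": int(v), "percent": float(round(100.0 * v / n, 1)) if n else 0.0}
            for k, v in cat_counts.items()
        },
    }
    if results is not None and n:
        merged = calls.merge(results, on="gene_id")
        out["total_cis_significant"] = int(merged["sig_cis"].sum())
        out["total_trans_significant"] = int(merged["sig_trans"].sum())
        amb = merged["category"] == "ambiguous"
        out["ambiguous_cis_significant"] = int((amb & merged["sig_cis"]).sum())
        out["ambiguous_trans_significant"] = int((amb & merged["sig_trans"]).sum())
    if modes is not None:
        m = len(modes)
        mode_counts = (
            modes["inheritance_mode"].value_counts().reindex(MODES, fill_value=0)
            if m else pd.Series(0, index=MODES)
        )
        out["modes"] = {
            k: {"count": int(v), "percent": float(round(100.0 * v / m, 1)) if m else 0.0}
            for k, v in mode_counts.items()
        }
        out["modes"]["dominant"] = {
            "count": int(mode_counts["dominant_p1"] + mode_counts["dominant_p2"]),
            "percent": float(round(
                100.0 * (mode_counts["dominant_p1"] + mode_counts["dominant_p2"]) / m, 1
            )) if m else 0.0,
        }
        out["misexpressed"] = int(
            mode_counts["overdominant"] + mode_counts["underdominant"]
        )
    return out


def magnitude_comparison(
    additive: Sequence[float], other: Sequence[float]
) -> tuple[float, float]:
    """One-tailed rank-sum comparison of cis-magnitudes by inheritance mode.

    Tests whether the additive group's cis-magnitudes are stochastically
    greater than those of the other significant inheritance modes
    (dominant, over- and under-dominant; conserved-expression genes are
    excluded by the caller).  Normal approximation with tie and
    continuity correction.

    Returns (U statistic of the additive group, one-sided p).
    """
    a = np.asarray(additive, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 values per group, got {a.size} and {b.size}"
        )
    res = stats.mannwhitneyu(
        a, b, alternative="greater", use_continuity=True, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
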