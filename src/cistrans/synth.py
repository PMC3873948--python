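"""Synthetic allele-specific count tables with known regulatory truth.

The generator emulates what the analysis sees after allele-specific read
counting: per-gene Poisson counts for two parental libraries and the two
F1 allele columns, produced from a mixture of regulatory architectures.
Every gene carries a latent parental log2 imbalance ``m_P`` and a hybrid
(allelic) log2 imbalance ``m_H``:

* conserved        m_P = m_H = 0
* cis              m_P = m_H != 0   (the allelic effect carries through)
* trans            m_P != 0, m_H = 0
* compensatory     m_P = 0, m_H != 0 (a trans effect cancels the cis one)
* cis+trans        m_H and m_P - m_H share their sign
* cis-by-trans     m_H and m_P - m_H have opposite signs

Rates follow the Poisson power model: at expression level ``n`` and
ratio ``r = 2**m`` the pair is ``2n/(1+r)`` and ``2nr/(1+r)`` (halved
for the hybrid alleles), then scaled by library-depth multipliers, with
the gene's mapping-bias factor multiplied onto the first hybrid allele
rate.  Expression levels are log-normal, effect sizes exponential, bias
factors log-normal around 1 — simple stand-ins that create the realistic
power gradient across expression levels but none of the overdispersion,
length bias or correlation structure of real RNA-Seq.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import GeneCountRecord

__all__ = [
    "TRUE_CATEGORIES",
    "SynthConfig",
    "generate_dataset",
    "benchmark_config",
    "study_scale_config",
    "recovery_report",
]

TRUE_CATEGORIES = (
    "cis",
    "trans",
    "cis_plus_trans",
    "cis_by_trans",
    "compensatory",
    "conserved",
)

#: default architecture mixture, loosely mirroring the relative abundance
#: of regulatory classes reported in intra-specific ASE studies
DEFAULT_FRACTIONS: dict[str, float] = {
    "conserved": 0.55,
    "trans": 0.16,
    "cis": 0.09,
    "compensatory": 0.08,
    "cis_plus_trans": 0.06,
    "cis_by_trans": 0.06,
}


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Attributes
    ----------
    n_genes : int
        Number of genes to simulate.
    category_fractions : mapping
        Architecture mixture over :data:`TRUE_CATEGORIES`; must sum to 1.
    effect_mean_log2 : float
        Mean of the exponential |log2 imbalance| distribution, drawn
        independently for the cis and trans components.
    min_log2_effect : float
        Floor added to every drawn effect size (0 = none); benchmark
        presets use it to guarantee strong effects.
    expr_median, expr_log_sd : float
        Log-normal expression-level distribution (counts per library).
    expr_min : float
        Lower clip on expression levels.
    bias_log_sd : float
        Log-normal spread of per-gene mapping-bias factors around 1.
    depth_multipliers : (float, float, float)
        Relative depths of the parent-1, parent-2 and hybrid libraries.
    mean_snps : float
        Mean number of fixed SNPs per gene beyond the mandatory one.
    seed : int
        Random seed; identical configs give byte-identical outputs.
    """

    n_genes: int = 2000
    category_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    effect_mean_log2: float = 1.0
    min_log2_effect: float = 0.0
    expr_median: float = 100.0
    expr_log_sd: float = 1.0
    expr_min: float = 1.0
    bias_log_sd: float = 0.0
    depth_multipliers: tuple[float, float, float] = (1.0, 1.2, 0.9)
    mean_snps: float = 3.4
    seed: int = 0

    def __post_init__(self) -> None:
        fr = dict(self.category_fractions)
        unknown = set(fr) - set(TRUE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in fractions: {sorted(unknown)}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(
                f"category fractions must sum to 1, got {sum(fr.values())}"
            )


def benchmark_config(n_genes: int = 5000, seed: int = 0) -> SynthConfig:
    """Strong-effect benchmark: |log2 gamma| >= 2 (gamma >= 4), n >= 500.

    Pure cis and trans architectures against a conserved background, no
    mapping bias, equal depths — the regime where recovery of the two
    pure categories should be nearly perfect and conserved genes are
    mislabelled at no more than a few percent (BH adaptivity across the
    three families).  Mixtures with combined architectures dilute the
    TDE signal of cis-by-trans genes and are exercised separately.
    """
    return SynthConfig(
        n_genes=n_genes,
        category_fractions={
            "conserved": 0.80,
            "cis": 0.10,
            "trans": 0.10,
        },
        effect_mean_log2=0.5,
        min_log2_effect=2.0,
        expr_median=1000.0,
        expr_log_sd=0.5,
        expr_min=500.0,
        bias_log_sd=0.0,
        depth_multipliers=(1.0, 1.0, 1.0),
        seed=seed,
    )


def study_scale_config(seed: int = 0) -> SynthConfig:
    """Default mixture at the scale of the fly study (7631 tested genes)."""
    return SynthConfig(n_genes=7631, bias_log_sd=0.05, seed=seed)


def _imbalances(
    cats: np.ndarray, e_cis: np.ndarray, e_trans: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (m_P, m_H) log2 imbalances per gene from its architecture."""
    m_h = np.zeros(cats.size)
    m_p = np.zeros(cats.size)
    is_ = {c: cats == c for c in TRUE_CATEGORIES}
    m_h[is_["cis"]] = (signs * e_cis)[is_["cis"]]
    m_p[is_["cis"]] = m_h[is_["cis"]]
    m_p[is_["trans"]] = (signs * e_trans)[is_["trans"]]
    m_h[is_["compensatory"]] = (signs * e_cis)[is_["compensatory"]]
    both = is_["cis_plus_trans"]
    m_h[both] = (signs * e_cis)[both]
    m_p[both] = (signs * (e_cis + e_trans))[both]
    opp = is_["cis_by_trans"]
    m_h[opp] = (signs * e_cis)[opp]
    m_p[opp] = (signs * (e_cis - e_trans))[opp]
    return m_p, m_h


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[GeneCountRecord], pd.DataFrame]:
    """Draw a count table plus its ground-truth table.

    Returns the records (gene order g000000, g000001, ...) and a truth
    DataFrame with columns ``gene_id true_category gamma_P gamma_H
    sign_P sign_H n bias_factor``, where the gammas are the magnitude
    (>= 1) of the latent imbalances and the signs their direction.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_genes
    fr = dict(config.category_fractions)
    cat_names = np.array([c for c in TRUE_CATEGORIES if fr.get(c, 0) > 0])
    probs = np.array([fr[c] for c in cat_names])
    cats = rng.choice(cat_names, size=m, p=probs / probs.sum())
    n = np.maximum(
        config.expr_median * np.exp(rng.normal(0.0, config.expr_log_sd, m)),
        config.expr_min,
    )
    e_cis = config.min_log2_effect + rng.exponential(config.effect_mean_log2, m)
    e_trans = config.min_log2_effect + rng.exponential(config.effect_mean_log2, m)
    signs = rng.choice([-1.0, 1.0], size=m)
    bias = (
        np.exp(rng.normal(0.0, config.bias_log_sd, m))
        if config.bias_log_sd > 0
        else np.ones(m)
    )
    n_snps = 1 + rng.poisson(config.mean_snps, m)

    m_p, m_h = _imbalances(cats, e_cis, e_trans, signs)
    r_p, r_h = 2.0**m_p, 2.0**m_h
    d1, d2, dh = config.depth_multipliers
    lam = np.column_stack(
        [
            d1 * 2.0 * n / (1.0 + r_p),
            d2 * 2.0 * n * r_p / (1.0 + r_p),
            dh * bias * n / (1.0 + r_h),
            dh * n * r_h / (1.0 + r_h),
        ]
    )
    counts = rng.poisson(lam)

    gene_ids = [f"g{i:06d}" for i in range(m)]
    records = [
        GeneCountRecord(
            gene_id=gid,
            p1=int(c[0]), p2=int(c[1]), h1=int(c[2]), h2=int(c[3]),
            n_snps=int(s), bias_factor=float(b),
        )
        for gid, c, s, b in zip(gene_ids, counts, n_snps, bias)
    ]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_category": cats,
            "gamma_P": 2.0 ** np.abs(m_p),
            "gamma_H": 2.0 ** np.abs(m_h),
            "sign_P": np.sign(m_p).astype(int),
            "sign_H": np.sign(m_h).astype(int),
            "n": n,
            "bias_factor": bias,
        }
    )
    return records, truth


def recovery_report(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion matrix and per-category recovery metrics.

    ``calls`` is the regulatory-call frame (gene_id, category); ``truth``
    the generator's truth table.  Gene sets must match exactly.
    """
    call_ids = set(calls["gene_id"])
    truth_ids = set(truth["gene_id"])
    if call_ids != truth_ids:
        missing = sorted(truth_ids - call_ids)[:10]
        extra = sorted(call_ids - truth_ids)[:10]
        raise ValueError(
            f"gene sets differ: missing from calls {missing}, extra {extra}"
        )
    merged = truth.merge(calls, on="gene_id")
    all_cats = list(TRUE_CATEGORIES) + ["ambiguous"]
    cm = pd.crosstab(
        pd.Categorical(merged["true_category"], categories=all_cats),
        pd.Categorical(merged["category"], categories=all_cats),
        dropna=False,
    )
    cm.index.name = "true"
    cm.columns.name = "called"
    sensitivity = {}
    precision = {}
    for cat in TRUE_CATEGORIES:
        row_n = int(cm.loc[cat].sum())
        col_n = int(cm[cat].sum())
        sensitivity[cat] = float(cm.loc[cat, cat] / row_n) if row_n else float("nan")
        precision[cat] = float(cm.loc[cat, cat] / col_n) if col_n else float("nan")
    cons = merged["true_category"] == "conserved"
    false_rate = (
        float((merged.loc[cons, "category"] != "conserved").mean())
        if cons.any()
        else float("nan")
    )
    return {
        "confusion_matrix": {t: {c: int(cm.loc[t, c]) for c in all_cats} for t in all_cats},
        "sensitivity": sensitivity,
        "precision": precision,
        "conserved_false_assignment_rate": false_rate,
        "n_genes": int(len(merged)),
    }
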