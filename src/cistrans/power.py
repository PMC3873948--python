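"""Monte-Carlo power of the cis- and trans-tests under a Poisson model.

Counts are Poisson around rates that encode an allelic imbalance
``gamma >= 1``: for expression level ``n`` the parental rates are
``lambda_1 = 2n / (gamma + 1)`` and ``lambda_2 = 2n * gamma / (gamma + 1)``
(the hybrid allele rates are the halved analogues, because each allele
contributes half the gene's expression in the F1).  Effect types:

* ``cis``  — the imbalance shows in parents and hybrid alike
  (P ~ Poi(lambda_i), H ~ Poi(lambda_i / 2)); detected by the cis test.
* ``trans`` — the imbalance shows only between parents, the hybrid
  alleles are balanced (H ~ Poi(n / 2)); detected by the trans test.
* ``combined`` — separate imbalances gamma_P (parents) and gamma_H
  (hybrid), indexed by ``|gamma_P - gamma_H| + 1``; detected by the
  trans test.

Power at each grid point is the rejection proportion over ``n_genes``
simulated genes whose expression levels are resampled from an observed
(or log-normal stand-in) distribution.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .gtests import bh_adjust, g_2x2_arrays, g_gof_arrays

__all__ = [
    "PowerGridPoint",
    "lambda_pair",
    "simulate_gene",
    "simulate_genes",
    "power_curve",
    "default_gamma_grid",
    "lognormal_levels",
    "combined_gammas",
]

EffectType = Literal["cis", "trans", "combined"]
RejectionRule = Literal["nominal_alpha", "bh_fdr"]


@dataclasses.dataclass(frozen=True)
class PowerGridPoint:
    """Monte-Carlo power estimate at one imbalance value."""

    effect_type: str
    gamma: float  # for combined effects: the index |gamma_P - gamma_H| + 1
    power: float
    n_genes: int
    rejection_rule: str
    alpha_or_fdr: float
    seed: int
    gamma_p: float | None = None  # component imbalances (combined effects)
    gamma_h: float | None = None


def default_gamma_grid() -> np.ndarray:
    """Imbalance grid from 1 to 10 in steps of 0.2 (46 points)."""
    return np.round(np.linspace(1.0, 10.0, 46), 10)


def lambda_pair(n: float, gamma: float) -> tuple[float, float]:
    """Poisson rates encoding imbalance ``gamma`` at expression level ``n``.

    ``lambda_1 + lambda_2 = 2 n`` exactly and ``lambda_2 / lambda_1 = gamma``.
    """
    if not n > 0:
        raise ValueError(f"expression level must be positive, got {n}")
    if gamma < 1:
        raise ValueError(f"allelic imbalance is defined >= 1, got {gamma}")
    return 2.0 * n / (gamma + 1.0), 2.0 * n * gamma / (gamma + 1.0)


def combined_gammas(index: float) -> tuple[float, float]:
    """(gamma_P, gamma_H) pair realizing a combined-effect index value.

    The index is ``|gamma_P - gamma_H| + 1``.  Both component effects are
    present and act in the same direction: ``gamma_H = (index + 1) / 2``
    and ``gamma_P = gamma_H + (index - 1)``, so index 1 degenerates to the
    balanced null.
    """
    if index < 1:
        raise ValueError(f"combined-effect index must be >= 1, got {index}")
    gamma_h = (index + 1.0) / 2.0
    return gamma_h + (index - 1.0), gamma_h


def _rates(
    effect_type: str, n: np.ndarray, gamma_p: np.ndarray, gamma_h: np.ndarray
) -> np.ndarray:
    lam = np.empty((n.size, 4))
    lam[:, 0] = 2.0 * n / (gamma_p + 1.0)
    lam[:, 1] = lam[:, 0] * gamma_p
    lam[:, 2] = n / (gamma_h + 1.0)
    lam[:, 3] = lam[:, 2] * gamma_h
    return lam


def simulate_genes(
    effect_type: EffectType,
    n: np.ndarray | float,
    gamma: np.ndarray | float | tuple[float, float],
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw Poisson count rows ``(p1, p2, h1, h2)`` for many genes at once.

    For ``combined``, ``gamma`` is the pair ``(gamma_P, gamma_H)``; for
    pure effects it is a scalar (cis: parents and hybrid share it;
    trans: hybrid alleles are balanced at rate n/2).
    """
    if effect_type == "combined":
        gamma_p, gamma_h = gamma  # type: ignore[misc]
    elif effect_type == "cis":
        gamma_p = gamma_h = gamma  # type: ignore[assignment]
    elif effect_type == "trans":
        gamma_p, gamma_h = gamma, 1.0  # type: ignore[assignment]
    else:
        raise ValueError(f"unknown effect type {effect_type!r}")
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if size is not None and n.size == 1:
        n = np.repeat(n, size)
    gamma_p = np.broadcast_to(np.asarray(gamma_p, dtype=float), n.shape)
    gamma_h = np.broadcast_to(np.asarray(gamma_h, dtype=float), n.shape)
    if np.any(gamma_p < 1) or np.any(gamma_h < 1):
        raise ValueError("allelic imbalance is defined >= 1")
    return rng.poisson(_rates(effect_type, n, gamma_p, gamma_h))


def simulate_gene(
    effect_type: EffectType,
    n: float,
    gamma: float | tuple[float, float],
    rng: np.random.Generator,
) -> tuple[int, int, int, int]:
    """One gene's simulated ``(p1, p2, h1, h2)`` counts."""
    row = simulate_genes(effect_type, n, gamma, rng)[0]
    return tuple(int(v) for v in row)  # type: ignore[return-value]


def _detection_pvalues(effect_type: str, counts: np.ndarray) -> np.ndarray:
    # cis genes are detected by the cis test, trans and combined genes by
    # the trans test (library ratios known and balanced in simulation)
    if effect_type == "cis":
        _, p, _ = g_gof_arrays(counts[:, 2], counts[:, 3], 1.0)
    else:
        _, p, _ = g_2x2_arrays(
            counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3]
        )
    return p


def power_curve(
    expression_levels: Sequence[float],
    gamma_grid: Sequence[float] | None = None,
    effect_type: EffectType = "cis",
    rejection_rule: RejectionRule = "nominal_alpha",
    level: float = 0.05,
    n_genes: int = 10000,
    seed: int = 0,
) -> list[PowerGridPoint]:
    """Estimated power of the matching test along an imbalance grid.

    Per grid point, ``n_genes`` genes are simulated with expression
    levels resampled (with replacement) from ``expression_levels``, the
    matching test is run with balanced known library ratios, and the
    rejection proportion is reported — per-gene at nominal ``level``
    (default) or after BH adjustment across the simulated genes
    (``bh_fdr``).  Fully reproducible from ``seed``.
    """
    if effect_type not in ("cis", "trans", "combined"):
        raise ValueError(f"unknown effect type {effect_type!r}")
    if rejection_rule not in ("nominal_alpha", "bh_fdr"):
        raise ValueError(f"unknown rejection rule {rejection_rule!r}")
    levels = np.asarray(expression_levels, dtype=float)
    if levels.size == 0 or np.any(levels <= 0):
        raise ValueError("expression_levels must be non-empty and positive")
    grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    rng = np.random.default_rng(seed)
    out = []
    for gamma in grid:
        n = rng.choice(levels, size=n_genes, replace=True)
        g = (
            combined_gammas(float(gamma))
            if effect_type == "combined"
            else float(gamma)
        )
        counts = simulate_genes(effect_type, n, g, rng)
        p = _detection_pvalues(effect_type, counts)
        if rejection_rule == "bh_fdr":
            rejected = bh_adjust(p) <= level
        else:
            rejected = p <= level
        out.append(
            PowerGridPoint(
                effect_type=effect_type,
                gamma=float(gamma),
                power=float(np.mean(rejected)),
                n_genes=n_genes,
                rejection_rule=rejection_rule,
                alpha_or_fdr=level,
                seed=seed,
                gamma_p=g[0] if effect_type == "combined" else None,
                gamma_h=g[1] if effect_type == "combined" else None,
            )
        )
    return out


def lognormal_levels(
    n: int, median: float = 100.0, log_sd: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Log-normal stand-in for observed per-gene expression levels."""
    rng = np.random.default_rng(seed)
    return median * np.exp(rng.normal(0.0, log_sd, size=n))
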