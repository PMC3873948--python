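"""Shared fixtures: deterministic matrices and synthetic datasets."""

from __future__ import annotations

import numpy as np
import openpyxl
import pytest

from cistrans.data import library_totals
from cistrans.pipeline import analyze
from cistrans.synth import benchmark_config, generate_dataset


def make_tmm_matrix(seed: int = 42, n_genes: int = 200) -> np.ndarray:
    """Random 4-column count matrix with depth and composition differences."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(4.0, 1.2, size=(n_genes, 1))
    depth = np.array([1.0, 1.6, 0.8, 1.1])
    noise = rng.lognormal(0.0, 0.3, size=(n_genes, 4))
    return rng.poisson(base * depth * noise)


@pytest.fixture(scope="session")
def tmm_matrix() -> np.ndarray:
    return make_tmm_matrix()


@pytest.fixture(scope="session")
def benchmark_run():
    """Strong-effect synthetic benchmark analyzed by the full pipeline.

    gamma >= 4, n >= 500, 5000 genes, no mapping bias; shared across the
    recovery tests because the analysis is the expensive part.
    """
    records, truth = generate_dataset(benchmark_config(n_genes=5000, seed=7))
    result = analyze(records, library_totals(records))
    return records, truth, result


def make_summary_workbook(path, records, calls, modes):
    """Synthetic stand-in for the deposited gene-summary spreadsheet layout."""
    call_map = dict(zip(calls["gene_id"], calls["category"].astype(str)))
    mode_map = dict(zip(modes["gene_id"], modes["inheritance_mode"].astype(str)))
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(
        ["gene_id", "ps88_raw", "ps94_raw", "hybrid_ps88_raw", "hybrid_ps94_raw",
         "n_snps", "bias_factor", "regulatory_type", "inheritance_mode"]
    )
    for r in records:
        ws.append(
            [r.gene_id, r.p1, r.p2, r.h1, r.h2, r.n_snps, r.bias_factor,
             call_map.get(r.gene_id), mode_map.get(r.gene_id)]
        )
    wb.save(path)
    return path


@pytest.fixture(scope="session")
def summary_workbook_writer():
    return make_summary_workbook
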