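# cistrans

Cis/trans dissection of regulatory divergence from allele-specific
RNA-Seq counts.

When two inbred lines are crossed, both parental alleles of every gene
share one cellular environment in the F1 hybrid. An allelic imbalance
inside the F1 therefore points to *cis*-regulatory divergence (promoter,
UTR, mRNA stability — anything linked to the allele itself), while a
change of the allelic ratio between the parents and the F1 points to
*trans*-acting divergence (diffusible factors). `cistrans` implements
this contrast for a replicate-free design — two parental libraries plus
one pooled F1 library, read pairs assigned to alleles at fixed SNPs —
and is aimed at people analyzing the count tables an allele-specific
expression counter produces.

Per gene with parental counts (p1, p2) and F1 allele counts (h1, h2),
three G-tests (likelihood-ratio, 1 df, G = 2·Σ O·ln(O/E)) are run:

- **TDE** — p1 : p2 against the effective parental library-size ratio;
- **cis** — h1 : h2 against the global allelic ratio times the gene's
  mapping-bias correction factor;
- **trans** — 2×2 independence test of (p1, p2) against bias-corrected,
  depth-rescaled (h1, h2).

Benjamini–Hochberg correction is applied per family (FDR ≤ 0.05). The
significance pattern classifies each gene as cis, trans, cis+trans,
cis-by-trans, compensatory, conserved or ambiguous; F1-vs-parent
comparisons assign inheritance modes (additive, dominant, over-/
under-dominant, conserved). Effect sizes are
cis-magnitude = |log2(h1′/h2′)| and
trans-magnitude = |log2(p1′/p2′) − log2(h1′/h2′)|.
Libraries are put on a common scale with TMM normalization (verified
against edgeR), and a Poisson power simulation quantifies the
detectability of cis, trans and combined effects across allelic
imbalances γ ∈ [1, 10]. A synthetic-data generator with known
architecture per gene backs the validation suite. See
[docs/methods.md](docs/methods.md) for the full model.

## Worked example

Generate a synthetic dataset with known regulatory architecture, run
the pipeline, and estimate trans-test power:

```sh
cistrans synth --n-genes 2000 --seed 42 --out counts.tsv --truth truth.tsv
cistrans run --counts counts.tsv --out results/
cistrans powersim --effect trans --gamma-min 1 --gamma-max 3 \
    --gamma-step 1 --n-genes 5000 --seed 42 --out power.tsv
```

The run prints the tally summary (abridged):

```json
{
  "n_genes": 1986,
  "categories": {
    "cis":          {"count": 119,  "percent": 6.0},
    "trans":        {"count": 188,  "percent": 9.5},
    "cis_plus_trans": {"count": 19, "percent": 1.0},
    "cis_by_trans": {"count": 18,   "percent": 0.9},
    "compensatory": {"count": 75,   "percent": 3.8},
    "conserved":    {"count": 1371, "percent": 69.0},
    "ambiguous":    {"count": 196,  "percent": 9.9}
  },
  "total_cis_significant": 255,
  "total_trans_significant": 326
}
```

1 986 of the 2 000 generated genes pass the parental coverage filter
(p1 + p2 ≥ 20). The generator planted 55% conserved genes; power is
limited at low expression, so weak-effect genes fall back to
`conserved` and the called conserved fraction lands higher (69%).
`total_cis_significant` counts every gene whose cis test fired,
cutting across categories (cis + cis±trans + compensatory + the
cis-significant slice of ambiguous). `results/` also receives
`tests.tsv` (per-gene G/p/q and magnitudes), `calls.tsv` (category,
effect directions, inheritance mode), `run.log` and the serialized
config. The power table shows the trans test waking up along the
imbalance grid at the generator's default expression levels:

```
effect  gamma  power     n_genes  seed
trans   1      0.052400  5000     42
trans   2      0.719800  5000     42
trans   3      0.892600  5000     42
```

At γ = 1 (no imbalance) the rejection rate is the nominal 5% type-I
error; a twofold imbalance is already detected in ~72% of genes.

The same machinery is available as a library:

```python
from cistrans import RunConfig, analyze, read_count_table

records, totals = read_count_table("counts.tsv")
result = analyze(records, totals, RunConfig(fdr_threshold=0.05))
print(result.summary["categories"]["trans"])
```

A gene-summary spreadsheet holding raw counts and published labels can
be re-analyzed with `cistrans reproduce-s4 --xls table.xlsx --out
report.json`, which reports recomputed tallies beside the published
ones and per-gene agreement.

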