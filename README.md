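# cgievol

How do CpG islands (CGIs) that are *methylated* in the germline keep
their CpG-rich sequences?  Methylated cytosines in CpG dinucleotides
deaminate to thymine far more often than unmethylated ones, so a
constitutively methylated island should bleed CpGs on an evolutionary
timescale — unless it is protected by germline hypomethylation, by
purifying selection on CpGs, by biased gene conversion, or by frequent
TpG/CpA → CpG back-substitution ("CpG fixation").

`cgievol` is a tested, reusable pipeline for asking that question from
standard genomics inputs.  It is aimed at comparative epigenomics
analyses that combine bisulfite methylomes with primate
ancestral-alignment data.  It provides:

* **Positional classification** of CGIs against gene models into
  5′ / 3′ / intragenic / intergenic categories (strict priority
  5′ > 3′ > intragenic), each flagged coding or non-coding.
* **Per-CGI methylation levels** from per-site bisulfite call counts,
  with three estimator variants (pooled strand-averaged, pooled, and
  per-site mean with a minimum-coverage filter), a ≥ 5-call exclusion
  rule, a 5hmC stream, and inclusive HM (≥ 80%) / LM (≤ 20%) labels.
* **Six context-dependent substitution rates** per CGI from a
  human/chimp/ancestor alignment (MAF):

  | rate | numerator (both lineages) | denominator |
  |---|---|---|
  | CpG→TpG/CpA | derived TpG or CpA | 2 × ancestral CpG |
  | TpG/CpA→CpG | derived CpG | 2 × ancestral TpG/CpA |
  | CpG→GpG/ApG/CpC/CpT | derived GpG/ApG/CpC/CpT | 2 × ancestral CpG |
  | GpG/ApG/CpC/CpT→CpG | derived CpG | 2 × ancestral GpG/ApG/CpC/CpT |
  | A/T→G/C | derived non-CpG G/C | 2 × ancestral A/T |
  | G/C→A/T | derived A/T | 2 × ancestral non-CpG-context G/C |

  CGIs covered on less than 50% of their length are excluded.
* **A one-split CART stump** (Gini impurity) that learns the
  CpG→TpG/CpA rate threshold separating sperm-HM from sperm-LM CGIs.
* **Summary tables**: HM/LM counts per genomic position, cross-sample
  label cross-tabs, grouped mean ± SEM rate comparisons, and
  below-threshold partition reports.
* **A synthetic-data generator** that emits every input format the
  pipeline consumes (BED, knownGene-style TSV, site-count TSV, MAF)
  with known ground truth, so every stage is testable by parameter
  recovery without any external download.

## Worked example

Simulate a cohort and run the whole pipeline:

```sh
cgievol simulate --seed 7 --n-per-cell 3 --out sim/
cat > config.yaml <<EOF
cgi_bed: sim/cgis.bed
genes_tsv: sim/genes.tsv
maf: sim/alignment.maf
samples:
  - {name: H1,    sites: sim/sites_H1.tsv}
  - {name: sperm, sites: sim/sites_sperm.tsv}
outdir: out/
seed: 7
EOF
cgievol run-all --config config.yaml
```

`out/manifest.json` then records, for that simulation:

```json
"stages": {
 "regions":   {"cgis": 21, "genes": 18},
 "methylome": {"rows": 42, "excluded": 0},
 "subrates":  {"blocks": 1, "rejected_blocks": 0, "cgis_passing_coverage": 21},
 "stump":     {"n_labeled": 21, "threshold": 0.011308840413318026, "degenerate": false},
 "summaries": {"profiles": 21, "tables": 5}
}
```

All 21 simulated CGIs are classified (their planted categories are
recovered exactly), none fail the 5-call or 50%-coverage filters at the
default simulation depth, and the stump separates the sperm-HM from the
sperm-LM islands at a CpG→TpG/CpA rate threshold of ≈ 0.011 — between
the two planted per-branch deamination probabilities (0.005 and 0.04),
as it should be.  `out/` also contains the per-stage tables
(`classification.tsv`, `methylation.tsv`, `rates.tsv`, `stump.json`,
`profiles.tsv`, the position/crosstab/partition/group-rate tables).

The same steps are available as library calls (`cgievol.classify_all`,
`cgievol.cgi_methylation_table`, `cgievol.cgi_rate_table`,
`cgievol.fit_stump`, `cgievol.run_pipeline`, ...); see the module
docstrings and `docs/methods.md` for the precise definitions.

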