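# scdimorph

Sex-stratified single-cell transcriptomics analysis of a 2×2
genotype (TG/WT) × gender (M/F) design, as a reusable pipeline:

1. **synthetic_data** — Poisson count simulator with planted gender-neutral /
   -specific / -dimorphic log-fold-change effects, library-size variation,
   mitochondrial fractions, plus a signed regulatory-network generator whose
   Boolean dynamics realise a planted disease state (with ground-truth
   perturbation scores).
2. **preprocess** — QC filtering (feature-count and mitochondrial-fraction
   cutoffs), CLR normalization, variable-gene selection, PCA, shared-nearest-
   neighbor graph clustering (Leiden over a resolution grid) with
   silhouette-based model selection, and marker-based cluster annotation.
3. **diffexpr** — per-stratum Poisson-GLM likelihood-ratio tests (TG vs WT,
   exact closed form with exposure offsets), Bonferroni adjustment, and the
   gender-pattern classification (neutral / male_specific / female_specific /
   dimorphic / unclassified), percent-expressing statistics, and
   cross-dataset DEG overlap with direction concordance.
4. **enrichment** — hypergeometric over-representation analysis of classified
   DEG lists against GMT collections (gene ratio, BH q-values).
5. **grn_inference** — Booleanization of DE results into phenotype states and
   genetic-algorithm selection of genotype-specific consistent subnetworks
   from a prior-knowledge edge list, inferring unknown edge signs.
6. **perturbation** — in-silico single-regulator clamping with synchronous
   signed propagation; regulators ranked by the number of downstream genes
   reverted toward the control state (with an independent brute-force oracle).
7. **workflow_cli** — a `click` CLI orchestrating the stages with YAML
   config, per-stage outputs (TSV/JSON), and a provenance manifest.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the eight property-based acceptance
criteria (perturbation-oracle equivalence, GA optimality vs exhaustive
search, end-to-end regulator recovery, gender-class recovery, closed-form
LRT agreement, ORA exactness, worked-example classification, clustering
recovery). The full suite runs in ~1.5 minutes on one CPU.

## CLI

```bash
# generate the default synthetic bundle (MTX + metadata + GMT + network)
scdimorph simulate --data-dir data --seed 1

# full pipeline (preprocess -> de -> enrich -> grn -> perturb -> report)
scdimorph run --data-dir data --out-dir results --seed 1

# or stage by stage
scdimorph preprocess --data-dir data --out-dir results
scdimorph de --data-dir data --out-dir results
scdimorph enrich --data-dir data --out-dir results
scdimorph grn --data-dir data --out-dir results --cell-type ALL --gender M
scdimorph perturb --data-dir data --out-dir results
scdimorph report --out-dir results
```

All options can also be set in a YAML config (`--config cfg.yaml`); CLI
flags override it. Defaults reproduce the published thresholds (features in
[200, 2500], mito ≤ 5%, top 2500 variable genes, 10 PCs, q<0.05 significant
and q>0.5 null buffer).

### Input formats

- counts: Matrix Market `matrix.mtx` + `features.tsv` + `barcodes.tsv`
- per-cell metadata: `metadata.tsv` (barcode, genotype ∈ {TG, WT},
  gender ∈ {M, F}, cell_type)
- marker / pathway gene sets: GMT (`markers.gmt`, `pathways.gmt`)
- prior network: `network.tsv` (source, target,
  effect ∈ {activation, inhibition, unknown}, category)

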