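# cardionet

A tested, reusable pipeline for two-condition time-course transcriptome
analysis: probe-level normalization, per-timepoint differential-expression
(DE) calling by a mean ± 2·SD fold-change envelope, cross-condition
correlation transition profiling, TF co-expression module detection by
iterated bridge bisection, miRNA → TF suppression inference, construction
of a signed TF–miRNA–gene regulatory network with per-timepoint hub
ranking, and hypergeometric over-representation analysis with
Benjamini–Hochberg FDR control.

The package ships a synthetic-data generator that reproduces the
statistical structure the analysis assumes — two conditions (`sham`, `TAB`)
× five timepoints (`d3`–`d28`), log-normal intensity background, planted DE
effects, planted TF modules with distinct temporal patterns, and
interaction tables consistent with the plants — together with serialized
ground truth, so the whole pipeline runs and is validated with no external
data.

## Command line

```sh
# generate a synthetic dataset (expression TSVs, gene lists, interaction
# tables, GMT annotations, ground-truth JSON)
cardionet simulate --seed 1 --out data/

# run the full pipeline end to end on a fresh simulation
cardionet run-all --simulate --seed 1 --out runs/demo

# or on files, via a YAML config listing input paths and thresholds
cardionet run-all --config pipeline.yaml --out runs/real

# individual stages
cardionet preprocess data/genes_raw.tsv --out data/genes.tsv
cardionet de data/genes.tsv data/mirnas.tsv data/tf_genes.txt --out de.tsv
cardionet transition data/genes.tsv data/mirnas.tsv data/tf_genes.txt --out tr.json
cardionet modules data/genes.tsv data/mirnas.tsv data/tf_genes.txt --out mods.tsv
cardionet suppress data/genes.tsv data/mirnas.tsv data/tf_genes.txt \
    data/mirna_targets.tsv --out events.tsv
cardionet enrich query.txt sets.gmt background.txt --out enrichment.tsv
```

`run-all` writes one TSV/JSON per stage plus `manifest.json` recording the
configuration echo, library versions, SHA-256 hashes of every output (runs
are bit-reproducible for a fixed seed), and — when ground truth is
available — plant-recovery metrics (DE sensitivity, module ARI,
suppression recall).

## File formats

* Expression: headered TSV, first column `feature`, sample columns named
  `<condition>_<timepoint>` (e.g. `TAB_d5`); one file for genes (including
  TF genes), one for miRNAs.
* Feature lists: one symbol per line (`tf_genes.txt`, `cv_genes.txt`).
* Interaction tables: two-column TSV `regulator<TAB>target`.
* Annotation sets: GMT (term, description, members).
* Networks: edge-list TSV `source target type sign pcc`; partitions as
  `node<TAB>module` (module 0 is the residual of isolated nodes and small
  components).

## Package layout

| module | contents |
| --- | --- |
| `cardionet.simulate` | synthetic datasets + ground truth |
| `cardionet.preprocess` | median scaling, probe filter, quantile normalization, probe→gene collapse, fold changes |
| `cardionet.de` | mean ± k·SD DE calling, first-emergence (New+/Old+) classification |
| `cardionet.transition` | filtered cross-condition PCC series and transition minimum |
| `cardionet.modules` | PCC ≥ 0.9 TF network, bridge finding, iterated bridge bisection |
| `cardionet.suppression` | three-condition miRNA → TF suppression rule |
| `cardionet.regnet` | typed signed edges, network assembly/validation, hub ranking, CV-gene enrichment |
| `cardionet.enrich` | hypergeometric ORA with BH FDR over GMT sets |
| `cardionet.pipeline`, `cardionet.cli`, `cardionet.config`, `cardionet.io` | orchestration, CLI, config, format adapters |
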