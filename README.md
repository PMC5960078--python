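# brmmode

Classification of Drosophila SWI/SNF (BRM) target genes into
**ATPase-dependent** and **ATPase-independent** regulatory classes.

BRM is the ATPase subunit of the fly SWI/SNF chromatin-remodeling complex.
A sizeable fraction of the genes it regulates turn out not to need its
catalytic activity: when endogenous BRM is depleted and either wild-type BRM
or the catalytically dead K804R mutant is re-expressed, many target genes
respond the same way to both. `brmmode` is a reusable implementation of the
genomic analysis that makes that call, for computational biologists working
with ChIP coverage, RNA-seq counts and MNase occupancy data — together with
a synthetic-study generator with planted ground truth, so the whole pipeline
is testable without any sequencing data.

## What it computes

* **Binding**: per-gene BRM occupancy score
  `(mean IP + c) / (mean Input + c)` over the gene body ± 200 bp;
  bound ⇔ score ≥ 1.1. Genes are also classed short (< 1.5 kb) /
  medium / long (> 15 kb).
* **Differential expression**: empirical-Bayes moderated t on log2-CPM.
  Pooled variances s²_g are shrunk toward an inverse-gamma prior
  (s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), prior moment-matched by trigamma
  inversion); t̃ is referred to a t distribution with d₀ + d df and BH
  q-values control FDR (q < 0.05). Verified against limma's `eBayes`.
* **Classification**: target ⇔ bound ∧ DE under wild-type rescue;
  ATPase-independent ⇔ target ∧ DE under K804R rescue with the same sign;
  ATPase-dependent ⇔ the rest. A depletion-only contrast serves as control.
* **Metagene profiles**: scaled gene bodies (100 bins) with fixed 1-kb
  flanks (50 bins each), 0.5% expression robustness filter, and two-sample
  Kolmogorov–Smirnov group comparisons.
* **Promoter hexamers**: exhaustive 4096-hexamer sense/antisense counts in
  the −50/−10 promoter window, log2 strand-bias ratios, TATAAA frequency and
  an exact binomial test against the 19% genome baseline.
* **Nucleosome dynamics**: per-gene Δ occupancy (depleted − control) on the
  metagene axis and a seeded 2-cluster k-means that isolates the subset with
  the strongest gene-body nucleosome gain (Cluster 1).

See `docs/methods.md` for the full model description and design choices.

## Worked example

The published classification arithmetic on the fixed count fixture
(13,294 genes with the study's marginal counts):

```python
>>> from brmmode import make_paper_fixture, classify_targets
>>> table, _ = make_paper_fixture()
>>> res = classify_targets(table["bound"], table["de_wt"],
...                        table["de_mut"], table["de_depl"])
>>> res.summary
{'n_genes': 13294, 'n_bound': 2521, 'n_de_wt': 2112, 'n_target': 541,
 'n_target_down': 245, 'n_target_up': 296, 'n_overlap_mut': 270,
 'n_concordant': 267, 'n_independent': 267, 'n_dependent': 274,
 'pct_independent': 49.35, 'n_depl_in_independent': 24}
```

Of 2112 genes responding to wild-type rescue, 541 are BRM-bound — the
confident targets (245 repressed, 296 activated by BRM). 270 of those also
respond to the dead mutant, 267 of them in the same direction: the
ATPase-independent class (49.35% of targets); the other 274 are
ATPase-dependent. Only 24 of the 267 respond to depletion alone, so the
mutant's effect is not explained by residual BRM loss.

The same logic end-to-end from files, on a synthetic study:

```sh
$ brm-mode simulate --seed 4 --out study
wrote 11 files to study
$ brm-mode bind --ip study/chip_ip.bedGraph --input study/chip_input.bedGraph \
    --genes study/genes.gff3 --chrom-sizes study/genome.chrom.sizes --out binding.tsv
160 of 400 genes bound (threshold 1.1)
$ brm-mode de --counts study/counts.tsv --samples study/samples.tsv \
    --contrast dsBRM_WT:control --out de_wt.tsv
142 of 400 genes significant at q < 0.05
$ brm-mode classify --binding binding.tsv --de-wt de_wt.tsv \
    --de-mut de_mut.tsv --de-depl de_depl.tsv \
    --out classes.tsv --summary summary.json
{ ... "n_target": 96, "n_independent": 28, "n_dependent": 68,
  "pct_independent": 29.17, "n_depl_in_independent": 4 }
```

(`de_mut.tsv` / `de_depl.tsv` come from the same `brm-mode de` command with
contrasts `dsBRM_K804R:control` and `dsBRM:control`.) Further subcommands:
`brm-mode hexamer`, `brm-mode metagene`, `brm-mode nucleosome` — each prints
a one-line JSON summary and writes a TSV.

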