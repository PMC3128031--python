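# ssrkit

Supervised variety identification from SSR (microsatellite) fingerprints.
`ssrkit` encodes genotype polymorphism in the Nei-Li similarity — a
positive-definite kernel on allele sets — trains kernel discriminant
classifiers (KLDA, KPCLDA) on the resulting Gram matrices, and selects
minimal marker "kits" with a greedy filter driven by uncertainty-coefficient
Z-scores (plus MIFS and mRMR baselines). A synthetic genotype generator
makes the whole pipeline testable without any external data.

## Data format

Tab-separated (comma auto-detected) tables, one row per sample, first column
the sample id, optional class-label column (default name `group`), marker
names in the header. Cells are slash-separated amplicon sizes, `-` (or empty
/ `NA`) for a missing call:

```
sample	group	SSR1	SSR2	SSR3
S1	red	177/181	191/193	172
S2	red	177/181	-	172/174
S3	blue	175/177	193	168/172
```

## Library quick tour

```python
from ssrkit import (
    read_genotype_table, gram_matrix, cross_gram,
    fit_klda, fit_kpclda, predict,
    SelectionConfig, greedy_select,
    cross_validate, grid_search, exhaustive_subset_search,
    SynthSpec, generate,
)

table = generate(SynthSpec(n_groups=5, samples_per_group=20, n_markers=12, seed=0))
kit = greedy_select(table, config=SelectionConfig(kit_size=5, alpha=1.0))
gram = gram_matrix(table, kit.selected_markers)
model = fit_klda(gram, table.labels)
report = cross_validate(
    table, selector_config=SelectionConfig(kit_size=5, alpha=1.0),
    classifier="KLDA", k=10, seed=0,
)
print(kit.selected_markers, report.mean_error)
```

Feature selection always runs inside each cross-validation fold's training
split; a deliberately biased variant is available only through the explicit
`leaky=True` flag.

## CLI

One entry point with subcommands; every output gets a
`<out>.manifest.json` recording the configuration, seed and version.

```sh
ssrkit simulate --preset landRace --seed 0 --out table.tsv
ssrkit select --input table.tsv --kit-size 5 --alpha 1 --out kit.tsv
ssrkit kernel --input table.tsv --out dist.phy
ssrkit fit --input table.tsv --classifier KPCLDA --out model.json
ssrkit predict --model model.json --train-input table.tsv --input new.tsv --out pred.tsv
ssrkit crossval --input table.tsv --selector FS --kit-size 5 --classifier KLDA --out cv.json
ssrkit gridsearch --input table.tsv --grid 0,0.75,1,1.25 --out grid.json
ssrkit exhaustive --input table.tsv --subset-size 5 --out exh.json
ssrkit rank --kit-error 0.03 --errors-file exh.json
```

## Notes on the method

- The Nei-Li distance pools symmetric differences over markers
  (`sum |A^B| / sum (|A|+|B|)`); its complement is the Dice coefficient on
  marker-tagged allele sets and is positive definite, so Gram matrices feed
  directly into kernel methods and unseen alleles in new samples need no
  re-coding.
- Missing calls contribute empty allele sets to the pooled sums, which
  preserves positive semi-definiteness exactly (pairwise marker exclusion
  does not).
- Marker power is `U(Group|Marker)`, redundancy the symmetric uncertainty
  between markers; both carry delta-method asymptotic variances, and the
  greedy selector keeps a marker when its power Z-score beats `alpha` times
  the strongest redundancy Z-score against the kit so far. `alpha = 0`
  reduces to top-N by power.
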