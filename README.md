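# heterokern

Prediction of heterodimeric protein complexes from a weighted
protein–protein interaction (PPI) network and per-protein annotations.
Protein pairs are mapped to a 7-dimensional network/domain feature vector,
protein-level kernels (Min and its two normalizations, MinMax and
scale-normalized Min) are lifted to pair-level kernels (metric-learning
lift, tensor-product lift, their sum, and a 0/1 domain-composition
baseline), and the combined kernel drives a class-weighted C-SVC evaluated
by stratified 10-fold cross-validation with precision / recall / F-measure.

## Layout

| module | contents |
|---|---|
| `heterokern.data_model_io` | core types, TSV readers/writers, positive/negative example construction |
| `heterokern.feature_maps` | pair feature vector `psi`, profile lookup `phi` |
| `heterokern.kernels` | Min / MinMax / scale-normalized kernels, pairwise lifts, combined kernel, vectorized Gram assembly |
| `heterokern.svm_eval` | class-weighted C-SVC (libsvm via scikit-learn, precomputed Gram), CV, grid search |
| `heterokern.synthetic_data` | seeded generator of networks/catalogs/profiles with planted heterodimers |
| `heterokern.cli` | `heterokern` command: `simulate`, `build-dataset`, `gram`, `cv`, `grid` |

## Input formats

Tab-delimited UTF-8, `#` comment lines ignored:

- **network** — `protein_a TAB protein_b TAB weight` (positive weights;
  duplicate edges keep the max, self-edges are dropped with a warning).
  The `wi-phi` dialect tolerates a header and extra columns (last numeric
  column is the weight).
- **complex catalog** — `complex_id TAB protein`, one row per membership.
- **domain annotation** — `protein TAB domain`; repeated rows encode
  multiplicity.
- **binary profiles** (phylogenetic, localization) — header
  `protein TAB label1 ...`, then 0/1 rows.

A pair of proteins is a *positive* example when it is a network edge and a
size-2 complex; a *negative* when it is an edge, not a size-2 complex, and
its proteins co-occur in a complex of size ≥ 3.

## CLI

```sh
# generate a synthetic bundle (network, domains, profiles, complexes, truth)
heterokern simulate --seed 7 -o out/

# label the edges
heterokern build-dataset --network out/network.tsv --complexes out/complexes.tsv \
    -o out/pairs.tsv

# cross-validate one configuration
heterokern cv --network out/network.tsv --domains out/domains.tsv \
    --pairs out/pairs.tsv --kernel scale-normalized-min --pairwise mlpk \
    --alpha 0.3 --c-pos 4.5 --c-neg 1.0 -o out/cv/

# the alpha / C+ / C- grid
heterokern grid --network out/network.tsv --domains out/domains.tsv \
    --pairs out/pairs.tsv --kernel scale-normalized-min --pairwise mlpk \
    --alpha 0:0.1:1.0 --c-pos 3.5,4.0,4.5 --c-neg 1.0 -o out/grid/
```

Every run writes a `manifest.json` with the resolved configuration before
computing; all randomness comes from `--seed`.

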