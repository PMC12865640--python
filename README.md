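# spaxtalk

Spatial cell–cell crosstalk analysis for CosMx-style single-cell spatial
transcriptomics: directional proximity scoring between cell types,
spatially weighted one-to-one ligand–receptor (LR) scoring with
permutation significance, nearest-landmark and radius-neighbor distance
statistics, and neighborhood (niche) profiling — plus a synthetic-data
generator with planted ground truth so the whole pipeline is testable
without tissue data.

The package targets analyses of the kind used to dissect inflammatory
signaling in diseased liver — e.g. identifying macrophage→LSEC IL1B–IL1R1
signaling as a dominant interaction in MASH, localized to periportal zones
near cholangiocytes — but all statistics are generic over cell types,
genes, and tissues.

## The statistics

With per-cell coordinates (µm), FOV ids and type labels, and Gaussian
kernel weights `w_ij = exp(−d_ij²/(2b²))` between same-FOV cells
(`b` = 20 µm default, self and cross-FOV weights 0):

- **Directional proximity** `score(S→T) = mean_{i∈S} Σ_{j∈T} w_ij`, with
  per-source-cell weight normalization by default so each row is a mean
  kernel-smoothed neighborhood composition (rows sum to 1). Asymmetric by
  construction: the average runs over source cells.
- **Spatial LR score** for pair (L, R) and direction S→T:
  `Σ_ij x_iL·x_jR·w_ij / Σ_ij w_ij` over same-FOV source/target pairs,
  with x library-normalized expression (counts-per-10k). Self-self type
  directions are excluded (intercellular, not autocrine, signaling).
  Significance by within-FOV label permutation:
  `perm_p = (1 + #{null ≥ observed})/(n_perm + 1)`.
- **Landmark distance / radius counts**: per-cell nearest distance to a
  landmark type (e.g. cholangiocytes as portal-tract proxies) and counts
  of a neighbor type within a radius (default 20 µm), always FOV-restricted.
- **Niches**: k-NN neighborhood composition vectors clustered by seeded
  k-means, profiled by type proportions, mean landmark distance and panel
  gene expression.

See `docs/methods.md` for definitions, defaults, and the synthetic-data
model.

## Worked example

Generate the default synthetic dataset — 2 FOVs × 300 cells, six liver-like
cell types, a 120-gene panel, one planted IL1B→IL1R1 interaction from
macrophages to periportal ECs (effect 5 within 30 µm) among 50 decoy
pairs — then score every pair in every direction:

```python
import spaxtalk as sx

cfg = sx.default_config(seed=7)
cells, expr, pairs, truth = sx.generate_dataset(cfg)

norm = sx.normalize_expression(expr)
res = sx.score_all(norm, cells, pairs, bandwidth_um=20)
top = sx.rank_pairs(res, "Macrophages", "ECs_periportal", top_n=5)
print(top[["pair_id", "score"]].to_string(index=False))

z, p = sx.permutation_null(norm, cells, ("IL1B", "IL1R1"),
                           "Macrophages", "ECs_periportal",
                           n_perm=199, seed=7)
print(f"perm_z={z:.1f} perm_p={p:.3f}")

d_pp = sx.nearest_landmark_distance(cells, "ECs_periportal", "Cholangiocytes")
d_pc = sx.nearest_landmark_distance(cells, "ECs_pericentral", "Cholangiocytes")
print(f"mean nearest-cholangiocyte distance: periportal ECs {d_pp.mean:.0f} um, "
      f"pericentral ECs {d_pc.mean:.0f} um")
```

Output:

```
          pair_id         score
       IL1B_IL1R1 136874.709013
GENE0063_GENE0065  10503.391627
GENE0031_GENE0010   9501.905792
GENE0090_GENE0023   9098.006548
GENE0006_GENE0054   8201.547188
perm_z=32.1 perm_p=0.005
mean nearest-cholangiocyte distance: periportal ECs 87 um, pericentral ECs 183 um
```

The planted pair tops the ranking in its planted direction by more than an
order of magnitude over the best decoy (scores are on the CP10k² scale of
ligand×receptor products); its permutation p is the smallest achievable at
199 permutations; and the periportal EC type sits about twice as close to
cholangiocytes as the pericentral type, reproducing the zonation the
generator plants.

The same stages are available from the shell:

```bash
spaxtalk simulate --out sim/ --seed 7
spaxtalk lr-score --cells sim/cells.csv --expr sim/matrix.mtx \
    --pairs sim/pairs.tsv --source Macrophages --target ECs_periportal \
    --perm 199 --seed 7 --out lr_scores.tsv
spaxtalk run --config run.yaml     # full pipeline with a run manifest
```

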