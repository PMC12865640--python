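# Methods

`spaxtalk` quantifies directed cell–cell crosstalk in single-cell spatial
transcriptomic data of the CosMx type: per-cell x/y coordinates in
micrometers, a field-of-view (FOV) id, a cell-type label, and a cells ×
genes count matrix from a targeted (~1000-plex) panel. The motivating
biology is macrophage→LSEC IL1B–IL1R1 signaling in MASH liver, where
inflammatory niches organize around periportal structures, but every
statistic is generic over cell types and gene pairs.

## Spatial model and statistics

**FOV restriction.** FOVs are separate imaging tiles; stitching artifacts
make cross-tile distances unreliable. Every statistic therefore treats
cells in different FOVs as infinitely far apart (kernel weight 0, no
neighbor relations). All coordinates live in one global frame so that
within-FOV distances are plain Euclidean distances in micrometers.

**Directional proximity score.** For source cell *i*, Gaussian kernel
weights to every other same-FOV cell *j*:

    w_ij = exp(−d_ij² / (2 b²)),   w_ii = 0

with bandwidth *b* = 20 µm by default — the one spatial scale that recurs
throughout this kind of analysis (a cell diameter or two; also the radius
used for neighbor counting). With per-cell normalization (the default)
each cell's weights are divided by their sum, making them a
kernel-smoothed neighborhood composition; the proximity score

    score(S→T) = mean_{i ∈ S} Σ_{j ∈ T} w_ij

then lies in [0, 1] per row, rows sum to 1, and the matrix is directional
because the average runs over source cells: a rare type surrounded by an
abundant one scores high toward it, while the reverse direction is diluted.
Unnormalized mode (raw kernel sums) is exposed for users who want absolute
rather than compositional adjacency; in that mode uniformly scaling all
distances up can only decrease scores.

The kernel is evaluated densely per FOV, with no truncation radius. At
CosMx FOV sizes (hundreds to a few thousand cells) the dense computation is
cheap, and it keeps the implementation exactly equal — to floating-point
precision — to the O(n²) brute-force definition, which the test suite
verifies on random instances. Source cells whose total weight underflows
to zero (isolated cells) are excluded from their type's average and logged;
a type with only such cells yields a NaN row.

**Landmark distances and radius counts.** The nearest-landmark distance is
each query cell's Euclidean distance to the nearest landmark-type cell in
the same FOV (cholangiocytes proxy portal tracts in liver work); query
cells in FOVs without landmarks are excluded from summaries and logged.
Radius-neighbor counting reports, per center cell, the number of
neighbor-type cells within 20 µm (default), excluding the center cell
itself. Both use k-d trees internally but are contractually identical to
the double-loop definitions.

## Spatially weighted ligand–receptor scores

For an ordered type direction S→T and a one-to-one ligand–receptor pair
(L, R):

    score(S→T, L→R) = Σ_i Σ_j x_iL · x_jR · w_ij  /  Σ_i Σ_j w_ij

summing over same-FOV source/target pairs, with x the library-normalized
expression (counts-per-10k; log transform available but off by default —
products of logged values have no natural interpretation as interaction
mass). Normalizing by the total kernel weight makes scores comparable
across directions with different cell abundances: the score is the
kernel-weighted average ligand×receptor product over spatially adjacent
cell pairs, so it is bilinear in expression and invariant to adding cells
of uninvolved types. Self-self type directions (S = T) are excluded
throughout — the target is intercellular, not autocrine, signaling. A pair
whose genes are both on the panel but identical (L = R) is allowed; the
type-level exclusion still applies.

Pair databases are CellChat-style one-to-one tables filtered to the panel
(both genes present). Ranking within a direction is by descending score
with lexicographic pair-id tie-breaks for determinism.

**Permutation significance.** The null shuffles cell-type labels within
each FOV, keeping coordinates and expression fixed, so FOV composition and
the spatial point pattern are preserved while the label–position
association is broken. With n_perm permutations,

    perm_p = (1 + #{null ≥ observed}) / (n_perm + 1)

(the add-one estimator; valid and never zero), and perm_z is the observed
score standardized by the null mean and SD. Observed and null scores are
computed by the same code path so the test is exactly exchangeable. Null
values tying the observed score at floating-point resolution are counted
as ≥ (relative tolerance 1e-12); a degenerate null (SD ≈ 0) yields
perm_z = NaN while perm_p remains valid.

## Niche analysis

Each cell's neighborhood is summarized as the cell-type frequency vector of
its k nearest same-FOV neighbors (self excluded; k truncated with a warning
in FOVs smaller than k+1 cells). These composition vectors are clustered
with k-means (k-means++ init, 10 restarts, fixed seed). Because k-means++
sampling depends on row order, the model is fitted on a canonical
lexicographically-sorted copy of the composition matrix and labels are then
assigned by nearest centroid, making the partition invariant to cell-row
permutation. Clusters are renamed `niche_1, niche_2, …` by descending size;
empty clusters are dropped rather than re-seeded. Defaults are k = 30
neighbors and 6 niches — the granularity at which periportal
inflammatory/fibrotic niches separate from parenchymal ones in liver
sections — but both are free parameters recorded in the run manifest, since
the commercial pipelines this step replaces do not document their values.

Per-niche profiles report member cell-type proportions, mean nearest-
landmark distance, and mean normalized expression of a gene panel
(default: CCL2, CXCL10, ITGAM, CCR2, COL1A1, IL1B, IL1R1 — the
inflammation/fibrosis transcripts of interest in the MASH setting).

## Signature scores and derived counts

The gene-set score of a cell is the plain sum of its normalized expression
over the set's genes present on the panel (missing genes are skipped and
logged). No z-scaling or control-gene subtraction is applied by default — a
"total expression" score in the literal sense — though a z-scored variant
exists behind a flag. Group comparisons use the two-sided Mann–Whitney
rank-sum test. `momf_count` converts flow-cytometry frequencies to an
absolute monocyte-derived-macrophage count:
total live NPCs × (%CD45⁺ of live) × (%MoMF of CD45⁺), rounded to a cell.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream claim is validated.

*Geometry.* FOVs tile a near-square global grid (500 µm tiles). One
landmark anchor per FOV is drawn at a seeded interior point; landmark-type
cells scatter around it with σ = 25 µm (a portal-tract footprint). In the
`radial_gradient` layout the designated periportal type is placed with
density ∝ exp(−d/75 µm) from the anchor (rejection sampling) and the true
zone label is periportal within 150 µm of the anchor, distal beyond; all
other types are uniform. In the `two_block` layout each FOV splits at its
vertical midline into two blocks whose non-landmark type compositions are
drawn from disjoint dominant type groups with a 10% cross-leak; the anchor
sits in block 1.

*Counts.* Per-cell library factors are log-normal with unit mean
(σ = 0.35), gene baselines are a flat 2.5 counts/gene over a 120-gene
default panel, and counts are Poisson given rate = library × baseline —
i.e. a Poisson-lognormal (negative-binomial-like) model. The defaults put
the median per-cell total near 300 counts, the depth typical of
1000-plex-scale chemistry restricted to a panel this size.

*Planted interactions.* A planted (L, R, S→T, effect, range) multiplies the
ligand rate in source cells lying within `range` of a target-type cell, and
the receptor rate in target cells within `range` of a source-type cell.
Acting on rates (not post-hoc on counts) means normalization interacts with
the effect realistically. Effect 1 reproduces the null exactly: the count
matrix is bit-identical to a run with no planted interaction. The default
condition plants IL1B→IL1R1 from macrophages to periportal ECs with effect
5 over 30 µm among 50 decoy pairs of background genes.

*What it does not emulate.* No segmentation errors, no sub-cellular
transcript positions, no cell-type-specific marker programs beyond the
planted genes, no spatial autocorrelation of library size, no doublets.
Passing tests on this generator demonstrates that the statistics recover
planted spatial co-expression structure under realistic sparsity and
depth variation — not that they are robust to segmentation or annotation
error in real tissue.

## Validation conditions and numerical choices

Problem sizes used by the test suite and the acceptance script are chosen
as the smallest at which each claim is meaningful: oracle equivalence on
random instances of ≤ 500 cells; planted-pair recovery on 2 FOVs × 300
cells with 50 decoys over 20 replicate datasets; permutation calibration on
400 null datasets (2 FOVs × 150 cells, n_perm = 99) and power on 20
replicates (n_perm = 199); niche recovery on 2 FOVs × 900 cells. The niche
phantom uses k = 15 neighbors: the k-NN neighborhood radius must be small
relative to the zone geometry for *any* composition-based method to resolve
the zone boundary, and at 900 cells per 500 µm FOV (≈3,600 cells/mm², a
realistic in-situ density) k = 15 gives a ≈25 µm neighborhood radius
against 250 µm blocks.

Other numerical choices: distances are exact (no grid binning); k-NN ties
at equal distance follow the k-d tree's deterministic ordering; zero-count
cells stay as zero rows through normalization and contribute nothing to
any score; NaN marks undefined quantities (no same-FOV partner, isolated
sources) and is excluded, with a log message, from all summaries.

## Known limitations

- The proximity and LR-score formulas are this package's canonical
  definitions of informally-described quantities; other reasonable kernels
  (uniform disc, exponential) would rank pairs similarly but are not
  implemented.
- Only one-to-one LR pairs are supported — no multi-subunit complexes, no
  downstream-target weighting of the CellChat/NicheNet kind.
- Permutation tests shuffle labels within FOV; they test label–position
  association, not expression spatial autocorrelation per se.
- 2-D coordinates only; niche clustering has no spatial-contiguity
  constraint.
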