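# spotanno

Probabilistic cell/domain-type annotation for spatially resolved
transcriptomics.

Spatial transcriptomics assays (10x Visium, ST, Slide-seq, seqFISH, ...)
measure expression at thousands of barcoded locations ("spots") whose tissue
identity — a cortical layer, a hippocampal subfield, a cell type — is
unknown. Annotating spots by hand from marker genes is slow and
irreproducible, and annotation tools built for dissociated single-cell data
ignore two strong signals: the thousands of genes that are *not* markers,
and the fact that neighboring spots usually share a type. `spotanno` uses
both, and flags spots matching no known profile as `unknown`. It is aimed at
computational biologists who have an expression matrix, spot coordinates and
a marker-gene list per type, and want posterior type probabilities, hard
labels and low-dimensional embeddings per spot.

## Model

For spot *i* with latent type *y<sub>i</sub>* ∈ {1, …, K}:

- **Marker mixture.** The centered, normalized marker-gene vector obeys
  *x*<sub>1i</sub> | *y*<sub>i</sub>=k ~ N(μ<sub>k</sub>, Σ) with
  μ<sub>jk</sub> = α<sub>j</sub> + ρ<sub>jk</sub> β<sub>jk</sub>,
  β<sub>jk</sub> ≥ 0 and Σ diagonal. The binary matrix ρ encodes which genes
  mark which type: a marker may be expressed everywhere, but is *elevated*
  (by β<sub>jk</sub>) in the types it marks.
- **Factor model for non-markers.** The p-dimensional non-marker vector is
  *x*<sub>2i</sub> = L*z*<sub>i</sub> + *e*<sub>i</sub> with a shared p×q
  loading L, *z*<sub>i</sub> | *y*<sub>i</sub>=k ~ N(*m*<sub>k</sub>, V) and
  diagonal residual Λ. The type-specific factor means *m*<sub>k</sub> let
  thousands of non-marker genes separate the types through a q-dimensional
  embedding (default q = 15).
- **Potts spatial prior.** Labels follow
  p(**y**) ∝ exp{−ξ Σ<sub>i∼i′</sub> [1 − I(y<sub>i</sub>=y<sub>i′</sub>)]}
  over the spot neighbor graph, rewarding smooth label fields; ξ ≥ 0 is
  estimated from the data by maximum pseudo-likelihood.
- **Unknown component.** An optional extra mixture component with no marker
  elevation (β ≡ 0) and its own factor mean absorbs spots that match no
  provided type.

Fitting is by ICM-EM: iterated-conditional-modes sweeps update hard labels
under the Potts coupling, a responsibility update mixes marker, factor and
local Potts terms, closed-form M-steps update both blocks (non-negative
projection for β, Woodbury-form factor updates that never build the p×p
covariance), and ξ is refreshed on a grid. Outputs are the n×(K+1)
responsibility matrix, hard labels (with `unknown`), the n×q posterior
embeddings and the fit trace.

## Worked example

`examples/01_annotate_simulated_tissue.py` simulates a 20×20 lattice section
with 7 spatially coherent domain types (35 marker genes, 200 non-marker
genes), fits the model and scores it against the simulated truth:

```text
spots: 400, markers: 35, non-markers: 200, types: 7
Kappa = 0.822  mF1 = 0.861  ACC = 0.848  ARI = 0.711
estimated Potts interaction xi_hat = 1.10 (simulated at 1.0)
spots labeled unknown: 16
```

Kappa/mF1/ACC near 1 mean the fitted labels reproduce the hidden domain
map; the estimated ξ recovers the smoothness the field was simulated with.
The other examples show novel-type detection when marker lists are
incomplete (`02`), robustness to randomly corrupted marker matrices (`03`),
and what the factor block and spatial prior buy over a marker-only GMM
baseline, plus clustering on the estimated embeddings (`04`).

The same pipeline runs from the shell:

```bash
spotanno simulate --scenario full_types --outdir sim --seed 3
spotanno annotate --expression sim/full_types/expression.csv \
    --coords sim/full_types/coords.csv --markers sim/full_types/markers.csv \
    --neighbor-mode st_square --outdir out --seed 7
spotanno evaluate --pred out/labels.csv --truth sim/full_types/truth.csv
```

Accepted inputs: dense CSV/TSV or MatrixMarket triplet expression, a
`spot_id,x,y` coordinate CSV, and markers as CSV (`type,gene`) or JSON
(`{type: [genes]}`). Neighbor graphs: `visium_hex`, `st_square`, `knn`,
`radius`.

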