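# cellmil

Weakly supervised discovery of condition-associated cell subpopulations
from single-cell RNA-seq cohorts, using attention-based multiple-instance
learning (MIL).

## The problem

Cohort-scale scRNA-seq experiments label *samples* (patient vs. healthy,
inflamed vs. normal), not cells. Yet the biology of interest is usually
carried by a minority of cells within the affected samples. `cellmil`
treats each sample as a *bag* of cell instances with a single binary
label and learns, end to end:

- a **sample classifier** that predicts the condition from the bag of
  cells, and
- a **per-cell attention score** `a_ij ∈ [0,1]` (softmax-normalized
  within each bag) that quantifies how much each cell contributed —
  a cell-level relevance readout obtained *without any cell labels*.

## The model

Training has two stages. Stage 1 pretrains an autoencoder on raw counts
with a negative-binomial reconstruction loss

    L_NB = (1/N) Σ_j Σ_i Σ_g −log NB(x_ijg | x̂_ijg, θ_ijg),

giving a latent representation `z_ij = f_enc(x_ij)`. Stage 2 trains two
branches that share the encoder, alternating one update each:

- **Sample branch** — gated-tanh attention
  `a_ij = softmax_i(wᵀ tanh(V z_ij))`, bag embedding `v_j = Σ_i a_ij z_ij`,
  sigmoid classifier, binary cross-entropy against the sample labels.
- **Cell branch** — attention scores of positive bags become per-cell
  pseudo-labels τ (zero in negative bags); a cell classifier predicts
  τ̂ from z under a class-weighted BCE (negative-class weight λ), plus
  an orthogonal projection loss (weight γ) that tightens the
  high-attention group and pushes it orthogonal to the rest, with the
  high/low grouping from a 2-component Gaussian mixture on the scores.

Ablation variants are one switch away: `dual_no_opl` (γ=0) and `abmil`
(sample branch only).

Downstream, attention scores stratify positive-sample cells into
condition-associated vs. condition-independent subgroups (GMM), with
KS/overlap separation metrics, attention-guided Leiden clustering,
Wilcoxon DEG ranking, and integrated-gradients gene attributions of the
attention logit (DIGs, compared to DEGs by Fisher exact test).

## Worked example

```python
import numpy as np
from cellmil import SimulationSpec, simulate_dataset, CellMIL

# a synthetic cohort: 14 control + 14 case samples, 200 cells each,
# 20% of case cells carry a 25-gene log2FC=2 signature
spec = SimulationSpec(n_genes=500, n_de_genes_per_signature=25,
                      cells_per_sample=200, perturb_fractions=(0.2,),
                      de_log2fc=2.0, seed=303)
ds = simulate_dataset(spec)

res = CellMIL(ds, "simulation").fit(seed=303)
print(res.summary())
```

```
Dual-branch attention MIL results
==============================================
variant:            dual
encoder widths:     (256, 128, 64)
attention hidden:   128
head hidden:        (64, 64)
lambda / gamma:     0.1 / 1.0
seed:               303
best stage-2 epoch: 158
----------------------------------------------
partition      AUROC    F1-macro    cell AUROC
train          1.000       1.000         0.742
val            1.000       1.000         0.791
test           1.000       1.000         0.805
==============================================
```

The test row is the one that matters: the model separates unseen case
from control samples perfectly (AUROC 1.0), and its attention scores
rank the planted perturbed cells above background cells with AUROC
≈ 0.81 — cells the model was never told about. `res.attention_table`
holds the per-cell scores; `cellmil.stratify.stratify_cells` turns them
into condition-associated / -independent subgroups.

The same pipeline is scriptable from the shell:

```bash
cellmil simulate --out data/ --seed 3
cellmil train --data data/ --out run/ --profile simulation --seed 3
cellmil stratify --data data/ --model run/run_model.npz --out strat/
cellmil interpret --data data/ --model run/run_model.npz \
        --subgroups strat/subgroups.tsv --out interp/
```

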