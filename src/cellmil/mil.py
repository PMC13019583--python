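"""Model/Results interface to the dual-branch attention-MIL framework.

:class:`CellMIL` is built from a :class:`~cellmil.simdata.BagDataset`
(or an AnnData with sample membership and sample labels in ``obs``); its
:meth:`~CellMIL.fit` runs the two training stages and returns a
:class:`CellMILResults` carrying the fitted networks, loss traces,
per-cell attention table and evaluation metrics, with a ``summary()``
table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelState
from .simdata import BagDataset, CountMatrix, split_dataset
from .training import (
    FitResult,
    MetricsReport,
    TrainConfig,
    evaluate,
    fit_pipeline,
    profile,
)


class CellMIL:
    """Weakly supervised MIL classifier of sample bags of cells.

    Parameters
    ----------
    dataset
        Bag-structured counts with sample labels and a train/val/test
        partition (an unpartitioned dataset is split 50/25/25).
    config
        A :class:`~cellmil.training.TrainConfig` or a profile name
        (``"default"`` or ``"simulation"``).
    """

    def __init__(self, dataset: BagDataset, config: TrainConfig | str = "default"):
        if isinstance(config, str):
            config = profile(config)
        if not dataset.partition:
            dataset = split_dataset(dataset, (0.5, 0.25, 0.25), seed=0)
        self.data = dataset
        self.config = config

    @classmethod
    def from_anndata(cls, adata, sample_key: str = "sample_id",
                     label_key: str = "sample_label",
                     config: TrainConfig | str = "default",
                     split_seed: int = 0) -> "CellMIL":
        """Build from an AnnData of raw counts.

        ``obs[sample_key]`` assigns each cell to a sample;
        ``obs[label_key]`` holds the binary condition label (constant
        within each sample).
        """
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        sample = np.asarray(adata.obs[sample_key]).astype(str)
        labels = np.asarray(adata.obs[label_key]).astype(int)
        bag_labels = {}
        for s in np.unique(sample):
            lab = np.unique(labels[sample == s])
            if len(lab) != 1:
                raise ValueError(f"sample {s!r} has inconsistent labels")
            bag_labels[s] = int(lab[0])
        cm = CountMatrix(
            counts=np.asarray(X),
            cell_ids=np.asarray(adata.obs_names),
            gene_ids=np.asarray(adata.var_names),
            sample_of_cell=sample,
            truth_label_of_cell=(np.asarray(adata.obs["truth_label"])
                                 if "truth_label" in adata.obs else None),
        )
        ds = BagDataset(cells=cm, bag_labels=bag_labels)
        ds = split_dataset(ds, (0.5, 0.25, 0.25), seed=split_seed)
        return cls(ds, config)

    def fit(self, seed: int = 0, pretrained: ModelState | None = None,
            verbose: bool = False) -> "CellMILResults":
        """Run stage-1 pretraining and stage-2 alternating optimization."""
        fit = fit_pipeline(self.data, self.config, seed=seed,
                           pretrained=pretrained, verbose=verbose)
        metrics = {}
        for part in ("train", "val", "test"):
            if self.data.samples_in(part):
                try:
                    metrics[part] = evaluate(fit.state, self.data, part)
                except ValueError:
                    pass
        return CellMILResults(model=self, fit=fit, metrics=metrics)


@dataclass
class CellMILResults:
    """Fitted dual-branch MIL model with diagnostics."""

    model: CellMIL
    fit: FitResult
    metrics: dict[str, MetricsReport] = field(default_factory=dict)

    @property
    def state(self) -> ModelState:
        return self.fit.state

    @property
    def attention_table(self) -> pd.DataFrame:
        """Per-cell attention/tau_hat over all evaluated partitions."""
        frames = []
        for part, rep in self.metrics.items():
            df = rep.attention.copy()
            df["partition"] = part
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def latent(self, counts) -> np.ndarray:
        """Latent embedding of raw count vectors."""
        return self.state.encode(np.asarray(counts, dtype=np.float32))

    def predict_bag(self, counts) -> float:
        """Condition probability for one bag of cells."""
        _, _, p = self.state.bag_forward(np.asarray(counts, dtype=np.float32))
        return p

    def attention_for(self, counts) -> np.ndarray:
        """Bag-normalized attention scores for one bag of cells."""
        a, _, _ = self.state.bag_forward(np.asarray(counts, dtype=np.float32))
        return a

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Dual-branch attention MIL results",
            "=" * 46,
            f"variant:            {cfg.variant}",
            f"encoder widths:     {cfg.encoder_widths}",
            f"attention hidden:   {cfg.attention_hidden}",
            f"head hidden:        {cfg.head_hidden}",
            f"lambda / gamma:     {cfg.stage2.lam} / {cfg.effective_gamma()}",
            f"seed:               {self.fit.seed}",
            f"best stage-2 epoch: {self.fit.best_epoch}",
            "-" * 46,
            f"{'partition':<10}{'AUROC':>10}{'F1-macro':>12}{'cell AUROC':>14}",
        ]
        for part in ("train", "val", "test"):
            rep = self.metrics.get(part)
            if rep is None:
                continue
            ca = "--" if rep.cell_auroc is None else f"{rep.cell_auroc:.3f}"
            lines.append(
                f"{part:<10}{rep.sample_auroc:>10.3f}"
                f"{rep.f1_macro:>12.3f}{ca:>14}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_attention(self, partition: str = "test", ax=None):
        """Histogram of attention scores, split by truth label when known.

        Returns the matplotlib axes; useful as a quick visual check of
        how well the attention separates the condition-associated cells.
        """
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        rep = self.metrics[partition]
        att = rep.attention
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        has_truth = (att["truth_label"] != "").any()
        if has_truth:
            groups = [("background", att["truth_label"] == "control"),
                      ("perturbed", att["truth_label"] != "control")]
        else:
            groups = [("negative bags", att["bag_label"] == 0),
                      ("positive bags", att["bag_label"] == 1)]
        for name, mask in groups:
            vals = att.loc[mask, "attention"]
            if len(vals):
                ax.hist(vals, bins=50, alpha=0.6, label=name, density=True)
        ax.set_xlabel("attention score")
        ax.set_ylabel("density")
        ax.set_title(f"attention distribution ({partition})")
        ax.legend(frameon=False)
        return ax

    def save(self, prefix: str) -> None:
        self.state.save(str(prefix) + "_model.npz")
        self.attention_table.to_csv(str(prefix) + "_attention.tsv",
                                    sep="\t", index=False)
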