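"""Downstream stratification of cells by attention score.

Positive-sample cells are split by a 2-component Gaussian mixture on
their attention scores into a condition-associated (higher-mean
component) and a condition-independent subgroup; negative-sample cells
form the control baseline.  Companion analyses: distribution-separation
metrics (KS statistic and overlap coefficient), attention-guided graph
clustering, Wilcoxon rank-sum differential expression with Bonferroni
correction, and concordance of estimated against planted fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .model import gmm_split_scores

SUBGROUPS = ("condition_associated", "condition_independent", "control")


@dataclass
class StratificationResult:
    """Per-cell subgroup labels plus the fitted mixture."""

    subgroup: np.ndarray            # one of SUBGROUPS per cell
    means: np.ndarray               # component means, [low, high]
    variances: np.ndarray
    weights: np.ndarray
    threshold: float                # equal-posterior score between the means

    def frame(self, cell_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({"subgroup": self.subgroup})
        if cell_ids is not None:
            df.insert(0, "cell_id", np.asarray(cell_ids))
        return df


def stratify_cells(attention: np.ndarray, bag_label_of_cell: np.ndarray,
                   seed: int = 0) -> StratificationResult:
    """GMM stratification of positive-sample cells by attention score.

    ``bag_label_of_cell`` holds each cell's sample-level label (0/1).
    Control cells (label 0) are never stratified, whatever their score.
    """
    attention = np.asarray(attention, dtype=float)
    bag_label_of_cell = np.asarray(bag_label_of_cell).astype(int)
    if attention.shape != bag_label_of_cell.shape:
        raise ValueError("attention and bag labels must align")
    pos = bag_label_of_cell == 1
    if pos.sum() < 4:
        raise ValueError("need at least 4 positive-sample cells")

    scores = attention[pos]
    subgroup = np.full(attention.shape, "control", dtype=object)
    if np.std(scores) < 1e-12:
        high = gmm_split_scores(scores, seed=seed)  # median-split fallback
        means = np.array([scores.mean(), scores.mean()])
        variances = np.zeros(2)
        weights = np.array([0.5, 0.5])
        threshold = float(scores.mean())
    else:
        gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        labels = gmm.fit_predict(scores.reshape(-1, 1))
        order = np.argsort(gmm.means_.ravel())
        high = labels == order[1]
        means = gmm.means_.ravel()[order]
        variances = gmm.covariances_.ravel()[order]
        weights = gmm.weights_.ravel()[order]
        threshold = _equal_posterior_threshold(gmm, means)
    subgroup[np.flatnonzero(pos)[high]] = "condition_associated"
    subgroup[np.flatnonzero(pos)[~high]] = "condition_independent"
    return StratificationResult(
        subgroup=subgroup.astype(str), means=means, variances=variances,
        weights=weights, threshold=threshold,
    )


def _equal_posterior_threshold(gmm: GaussianMixture,
                               sorted_means: np.ndarray) -> float:
    """Score between the component means where the posteriors cross."""
    grid = np.linspace(sorted_means[0], sorted_means[1], 2001)
    post = gmm.predict_proba(grid.reshape(-1, 1))
    high_comp = int(np.argmax(gmm.means_.ravel()))
    diff = post[:, high_comp] - 0.5
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if len(sign_change) == 0:
        return float(sorted_means.mean())
    i = sign_change[0]
    return float(grid[i] - diff[i] * (grid[i + 1] - grid[i])
                 / (diff[i + 1] - diff[i]))


# ---------------------------------------------------------------------------
# separation metrics
# ---------------------------------------------------------------------------
def ks_and_overlap(scores_a: np.ndarray, scores_b: np.ndarray,
                   n_bins: int = 512) -> dict[str, float]:
    """Two-sample KS statistic and histogram overlap coefficient.

    The overlap coefficient integrates ``min(f_a, f_b)`` over densities
    estimated on a shared-range histogram with ``n_bins`` bins.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    ks = float(stats.ks_2samp(a, b, method="asymp").statistic)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return {"ks": ks, "overlap": 1.0}
    edges = np.linspace(lo, hi, n_bins + 1)
    fa, _ = np.histogram(a, bins=edges, density=True)
    fb, _ = np.histogram(b, bins=edges, density=True)
    width = edges[1] - edges[0]
    return {"ks": ks, "overlap": float(np.minimum(fa, fb).sum() * width)}


# ---------------------------------------------------------------------------
# guided clustering
# ---------------------------------------------------------------------------
def guided_cluster(embedding: np.ndarray, mode: str = "guided",
                   strat: StratificationResult | None = None,
                   bag_label_of_cell: np.ndarray | None = None,
                   truth_labels: np.ndarray | None = None,
                   resolutions=(1.0,), n_neighbors: int = 15,
                   seed: int = 0) -> pd.DataFrame:
    """Leiden clustering of cells under three selection strategies.

    ``guided`` clusters only condition-associated cells (needs ``strat``),
    ``case_only`` all positive-sample cells (needs ``bag_label_of_cell``),
    ``standard`` all cells.  Returns one row per resolution with cluster
    labels and, when ``truth_labels`` is given, ARI/AMI against truth on
    the clustered subset.
    """
    import scanpy as sc
    import anndata as ad

    embedding = np.asarray(embedding, dtype=np.float32)
    if mode == "guided":
        if strat is None:
            raise ValueError("guided mode requires a StratificationResult")
        keep = np.flatnonzero(strat.subgroup == "condition_associated")
    elif mode == "case_only":
        if bag_label_of_cell is None:
            raise ValueError("case_only mode requires bag labels")
        keep = np.flatnonzero(np.asarray(bag_label_of_cell).astype(int) == 1)
    elif mode == "standard":
        keep = np.arange(embedding.shape[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(keep) < 10:
        raise ValueError("fewer than 10 cells selected for clustering")

    adata = ad.AnnData(X=embedding[keep])
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, len(keep) - 1),
                    use_rep="X", random_state=seed)
    rows = []
    for res in resolutions:
        key = f"leiden_{res}"
        sc.tl.leiden(adata, resolution=float(res), key_added=key,
                     random_state=seed, flavor="leidenalg")
        labels = adata.obs[key].to_numpy().astype(str)
        row = {"mode": mode, "resolution": float(res),
               "n_clusters": len(np.unique(labels)),
               "cell_index": keep, "labels": labels}
        if truth_labels is not None:
            truth = np.asarray(truth_labels)[keep].astype(str)
            row["ari"] = float(adjusted_rand_score(truth, labels))
            row["ami"] = float(adjusted_mutual_info_score(truth, labels))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------
def _log_normalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)


def rank_genes(counts: np.ndarray, in_group: np.ndarray,
               gene_ids=None, padj_threshold: float = 0.01,
               lfc_threshold: float = 0.25,
               min_detection: float = 0.0) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression, group vs rest.

    Expression is library-size log-normalized; p-values are Bonferroni
    corrected; the fold-change is
    ``log2[(mean(expm1(x1)) + 1) / (mean(expm1(x2)) + 1)]``.
    A gene passes when ``padj < padj_threshold``, ``|log2FC| >
    lfc_threshold`` and, when ``min_detection > 0``, the gene is detected
    in more than that fraction of cells in either group.
    """
    counts = np.asarray(counts)
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    logn = _log_normalize(counts)
    x1, x2 = logn[in_group], logn[~in_group]
    stat, p = stats.ranksums(x1, x2, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    padj = np.minimum(p * counts.shape[1], 1.0)
    m1 = np.expm1(x1).mean(axis=0)
    m2 = np.expm1(x2).mean(axis=0)
    lfc = np.log2((m1 + 1.0) / (m2 + 1.0))
    det1 = (counts[in_group] > 0).mean(axis=0)
    det2 = (counts[~in_group] > 0).mean(axis=0)
    flag = (padj < padj_threshold) & (np.abs(lfc) > lfc_threshold)
    if min_detection > 0:
        flag &= np.maximum(det1, det2) > min_detection
    return pd.DataFrame({
        "gene_id": (np.asarray(gene_ids) if gene_ids is not None
                    else np.arange(counts.shape[1])),
        "log2fc": lfc,
        "statistic": stat,
        "pval": p,
        "padj": padj,
        "detection_group": det1,
        "detection_rest": det2,
        "significant": flag,
    })


def deg_truth_concordance(estimated_lfc: np.ndarray,
                          truth_lfc: np.ndarray) -> float:
    """r^2 (squared Pearson correlation) of estimated vs planted log2FC."""
    est = np.asarray(estimated_lfc, dtype=float)
    tru = np.asarray(truth_lfc, dtype=float)
    if est.size != tru.size or est.size < 3:
        raise ValueError("need >= 3 paired fold-changes")
    if np.std(est) == 0 or np.std(tru) == 0:
        raise ValueError("zero-variance fold-change vector")
    r = stats.pearsonr(est, tru).statistic
    return float(r**2)
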