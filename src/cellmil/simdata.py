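"""Synthetic bag-structured single-cell count data with planted signals.

Emulates the simulation design used to validate the MIL model: a pool of
negative-binomial count profiles in which a minority "perturbed"
population carries a planted differential-expression signature, assembled
into control samples (background cells only) and case samples (a mixture
of background and perturbed cells), with a stratified sample-level
train/validation/test split and optional training-label noise.

All operations are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TRUTH_LABELS = ("control", "perturbA", "perturbB")
PARTITIONS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class SimulationSpec:
    """Generative law and bag design for one simulated dataset.

    Per-gene baseline means are log-normal (``mean_log_mu/sigma``, natural
    log scale); per-gene NB dispersions are log-normal
    (``disp_log_mu/sigma``); DE genes of perturbed cells have their mean
    multiplied by ``2 ** de_log2fc``; per-cell library-size factors are
    log-normal with coefficient of variation ``library_size_cv`` and unit
    mean (all factors exactly 1 when the CV is 0).
    """

    n_genes: int = 500
    n_de_genes_per_signature: int = 25
    mean_log_mu: float = -1.0
    mean_log_sigma: float = 1.0
    disp_log_mu: float = 0.7
    disp_log_sigma: float = 0.3
    de_log2fc: float = 2.0
    library_size_cv: float = 0.0
    n_control_samples: int = 14
    n_case_samples: int = 14
    cells_per_sample: int = 400
    perturb_fractions: tuple[float, ...] = (0.2,)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.cells_per_sample <= 0:
            raise ValueError("n_genes and cells_per_sample must be positive")
        n_sig = len(self.perturb_fractions)
        if n_sig not in (1, 2):
            raise ValueError("1 or 2 perturbation signatures supported")
        if any(f < 0 or f > 1 for f in self.perturb_fractions):
            raise ValueError("perturb fractions must lie in [0, 1]")
        if sum(self.perturb_fractions) >= 1:
            raise ValueError(
                "perturb fractions must sum to < 1: case bags must retain "
                "background control cells"
            )
        if n_sig * self.n_de_genes_per_signature > self.n_genes:
            raise ValueError("more DE genes requested than genes available")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be >= 0")

    @property
    def n_signatures(self) -> int:
        return len(self.perturb_fractions)

    def perturbed_per_bag(self) -> list[int]:
        """Cells of each signature per case bag (round half up)."""
        return [
            int(np.floor(f * self.cells_per_sample + 0.5))
            for f in self.perturb_fractions
        ]


@dataclass
class CountMatrix:
    """Cells x genes raw integer counts with identifiers and metadata."""

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    sample_of_cell: np.ndarray | None = None
    truth_label_of_cell: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.round(c)) or np.any(c < 0):
                raise ValueError("counts must be nonnegative integers")
            c = c.astype(np.int64)
        self.counts = c
        if len(self.cell_ids) != c.shape[0] or len(self.gene_ids) != c.shape[1]:
            raise ValueError("identifier lengths do not match count matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx) -> "CountMatrix":
        take = lambda a: None if a is None else np.asarray(a)[idx]
        return CountMatrix(
            self.counts[idx], np.asarray(self.cell_ids)[idx], self.gene_ids,
            take(self.sample_of_cell), take(self.truth_label_of_cell),
        )

    def subset_genes(self, idx) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, idx], self.cell_ids, np.asarray(self.gene_ids)[idx],
            self.sample_of_cell, self.truth_label_of_cell,
        )

    def to_anndata(self):
        """Export as an AnnData with obs columns sample_id / truth_label."""
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        if self.sample_of_cell is not None:
            obs["sample_id"] = np.asarray(self.sample_of_cell)
        if self.truth_label_of_cell is not None:
            obs["truth_label"] = np.asarray(self.truth_label_of_cell)
        var = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        return ad.AnnData(X=self.counts.astype(np.float32), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata) -> "CountMatrix":
        X = adata.X
        if not isinstance(X, np.ndarray):
            X = X.toarray()
        return cls(
            counts=np.asarray(X),
            cell_ids=np.asarray(adata.obs_names),
            gene_ids=np.asarray(adata.var_names),
            sample_of_cell=(np.asarray(adata.obs["sample_id"])
                            if "sample_id" in adata.obs else None),
            truth_label_of_cell=(np.asarray(adata.obs["truth_label"])
                                 if "truth_label" in adata.obs else None),
        )


@dataclass
class BagDataset:
    """Cells grouped into labeled sample bags with a sample-level split.

    ``noisy_labels`` — labels after training-label noise injection — are
    used only for training; evaluation always uses ``bag_labels``.
    """

    cells: CountMatrix
    bag_labels: dict[str, int]
    partition: dict[str, str] = field(default_factory=dict)
    noisy_labels: dict[str, int] | None = None

    def __post_init__(self):
        samples = set(np.unique(self.cells.sample_of_cell))
        if samples != set(self.bag_labels):
            raise ValueError("bag_labels must cover exactly the samples present")
        if self.partition:
            if set(self.partition) != samples:
                raise ValueError("partition must cover exactly the samples")
            bad = set(self.partition.values()) - set(PARTITIONS)
            if bad:
                raise ValueError(f"unknown partition names: {bad}")
        if self.noisy_labels is not None:
            for s, lab in self.noisy_labels.items():
                if lab != self.bag_labels[s] and self.partition.get(s) != "train":
                    raise ValueError(
                        "label noise may only touch train-partition samples"
                    )

    @property
    def samples(self) -> list[str]:
        return sorted(self.bag_labels)

    def samples_in(self, part: str) -> list[str]:
        return [s for s in self.samples if self.partition.get(s) == part]

    def training_label(self, sample: str) -> int:
        if self.noisy_labels is not None:
            return self.noisy_labels[sample]
        return self.bag_labels[sample]

    def bag_cell_indices(self, sample: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.cells.sample_of_cell) == sample)

    def cells_in(self, part: str) -> np.ndarray:
        """Row indices of all cells whose sample is in ``part``."""
        keep = {s for s in self.samples_in(part)}
        return np.flatnonzero(
            np.isin(np.asarray(self.cells.sample_of_cell), sorted(keep))
        )

    def metadata_frame(self) -> pd.DataFrame:
        """Per-cell metadata (cell_id, sample_id, bag_label, partition, truth)."""
        sample = np.asarray(self.cells.sample_of_cell)
        return pd.DataFrame({
            "cell_id": self.cells.cell_ids,
            "sample_id": sample,
            "bag_label": [self.bag_labels[s] for s in sample],
            "partition": [self.partition.get(s, "") for s in sample],
            "truth_label": (self.cells.truth_label_of_cell
                            if self.cells.truth_label_of_cell is not None
                            else [""] * len(sample)),
        })


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------
def _signature_lfc(spec: SimulationSpec, rng: np.random.Generator,
                   mu_g: np.ndarray) -> np.ndarray:
    """(n_signatures, n_genes) log2 fold-changes, disjoint DE gene blocks.

    DE genes are drawn from the detectably expressed half of the genes
    (baseline mean at or above the median), mirroring how perturbation
    signatures live in highly-variable-gene space rather than among
    near-zero-count genes.
    """
    lfc = np.zeros((spec.n_signatures, spec.n_genes))
    eligible = np.flatnonzero(mu_g >= np.median(mu_g))
    n_needed = spec.n_signatures * spec.n_de_genes_per_signature
    if n_needed > len(eligible):
        eligible = np.arange(spec.n_genes)
    de_genes = rng.choice(eligible, size=n_needed, replace=False)
    for s in range(spec.n_signatures):
        block = de_genes[s * spec.n_de_genes_per_signature:
                         (s + 1) * spec.n_de_genes_per_signature]
        lfc[s, block] = spec.de_log2fc
    return lfc


def _draw_counts(rng, n_cells, mu_g, theta_g, lfc_row, size_factors):
    mean = size_factors[:, None] * mu_g[None, :] * 2.0 ** lfc_row[None, :]
    p = theta_g[None, :] / (theta_g[None, :] + mean)
    return rng.negative_binomial(theta_g[None, :], p, size=(n_cells, len(mu_g)))


def generate_cell_pool(spec: SimulationSpec,
                       n_control: int | None = None,
                       n_perturbed: int | None = None) -> CountMatrix:
    """Draw the pool of control and perturbed NB count profiles.

    Pool sizes default to exactly what :func:`assemble_bags` consumes for
    ``spec``; pass ``n_control`` / ``n_perturbed`` (per signature) to
    override, e.g. for moment checks on large pools.
    """
    rng = np.random.default_rng(spec.seed)
    mu_g = rng.lognormal(spec.mean_log_mu, spec.mean_log_sigma, spec.n_genes)
    theta_g = rng.lognormal(spec.disp_log_mu, spec.disp_log_sigma, spec.n_genes)
    lfc = _signature_lfc(spec, rng, mu_g)

    per_bag = spec.perturbed_per_bag()
    if n_perturbed is None:
        n_pert = [spec.n_case_samples * k for k in per_bag]
    else:
        n_pert = [n_perturbed] * spec.n_signatures
    if n_control is None:
        n_control = (
            spec.n_control_samples * spec.cells_per_sample
            + spec.n_case_samples * (spec.cells_per_sample - sum(per_bag))
        )

    def factors(n):
        cv = spec.library_size_cv
        if cv == 0:
            return np.ones(n)
        sigma2 = np.log1p(cv**2)
        return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), n)

    blocks, labels = [], []
    blocks.append(_draw_counts(rng, n_control, mu_g, theta_g,
                               np.zeros(spec.n_genes), factors(n_control)))
    labels += ["control"] * n_control
    for s in range(spec.n_signatures):
        blocks.append(_draw_counts(rng, n_pert[s], mu_g, theta_g, lfc[s],
                                   factors(n_pert[s])))
        labels += [TRUTH_LABELS[1 + s]] * n_pert[s]

    counts = np.vstack(blocks).astype(np.int64)
    n = counts.shape[0]
    return CountMatrix(
        counts=counts,
        cell_ids=np.array([f"cell_{i:06d}" for i in range(n)]),
        gene_ids=np.array([f"gene_{g:05d}" for g in range(spec.n_genes)]),
        sample_of_cell=None,
        truth_label_of_cell=np.array(labels),
    )


def true_log2fc(spec: SimulationSpec) -> np.ndarray:
    """Planted per-gene log2 fold-changes, (n_signatures, n_genes).

    Re-derives the same DE gene draw as :func:`generate_cell_pool` for
    ``spec.seed`` (the gene-level laws are consumed from the stream first).
    """
    rng = np.random.default_rng(spec.seed)
    mu_g = rng.lognormal(spec.mean_log_mu, spec.mean_log_sigma, spec.n_genes)
    rng.lognormal(spec.disp_log_mu, spec.disp_log_sigma, spec.n_genes)
    return _signature_lfc(spec, rng, mu_g)


def assemble_bags(pool: CountMatrix, spec: SimulationSpec,
                  seed: int | None = None) -> BagDataset:
    """Assemble the pool into control and case bags without replacement.

    Control bags contain only control cells; each case bag contains
    ``round(fraction * cells_per_sample)`` cells of each perturbation
    signature and control cells for the remainder.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truth = np.asarray(pool.truth_label_of_cell)
    per_bag = spec.perturbed_per_bag()
    n_bg_case = spec.cells_per_sample - sum(per_bag)

    need = {"control": (spec.n_control_samples * spec.cells_per_sample
                        + spec.n_case_samples * n_bg_case)}
    for s in range(spec.n_signatures):
        need[TRUTH_LABELS[1 + s]] = spec.n_case_samples * per_bag[s]

    queues = {}
    for lab, n_need in need.items():
        avail = np.flatnonzero(truth == lab)
        if len(avail) < n_need:
            raise ValueError(
                f"insufficient pool cells with truth label {lab!r}: "
                f"need {n_need}, have {len(avail)}"
            )
        queues[lab] = list(rng.permutation(avail))

    sample_of_cell = np.full(pool.n_cells, "", dtype=object)
    bag_labels: dict[str, int] = {}
    used: list[int] = []

    for j in range(spec.n_control_samples):
        name = f"control_{j:02d}"
        take = [queues["control"].pop() for _ in range(spec.cells_per_sample)]
        sample_of_cell[take] = name
        bag_labels[name] = 0
        used += take
    for j in range(spec.n_case_samples):
        name = f"case_{j:02d}"
        take = [queues["control"].pop() for _ in range(n_bg_case)]
        for s in range(spec.n_signatures):
            lab = TRUTH_LABELS[1 + s]
            take += [queues[lab].pop() for _ in range(per_bag[s])]
        sample_of_cell[take] = name
        bag_labels[name] = 1
        used += take

    used = np.sort(np.asarray(used))
    cells = pool.subset_cells(used)
    cells.sample_of_cell = sample_of_cell[used].astype(str)
    return BagDataset(cells=cells, bag_labels=bag_labels)


def split_dataset(ds: BagDataset, fractions=(0.5, 0.25, 0.25),
                  seed: int = 0) -> BagDataset:
    """Class-stratified sample-level train/val/test split.

    Global partition sizes follow largest-remainder rounding of
    ``fractions``; within that, each class is spread across partitions so
    per-partition class balance stays within one sample of the global
    balance.  Cells always follow their sample.
    """
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    samples = ds.samples
    n = len(samples)
    # global partition sizes: largest remainder
    raw = np.array(fractions) * n
    sizes = np.floor(raw).astype(int)
    order = np.argsort(-(raw - sizes), kind="stable")
    for i in order[: n - sizes.sum()]:
        sizes[i] += 1

    labels = np.array([ds.bag_labels[s] for s in samples])
    classes = np.unique(labels)
    # per-class allocation constrained to the global column sizes
    alloc = np.zeros((len(classes), 3), dtype=int)
    frac_part = np.zeros((len(classes), 3))
    for ci, c in enumerate(classes):
        n_c = int((labels == c).sum())
        raw_c = np.array(sizes) * n_c / n
        alloc[ci] = np.floor(raw_c).astype(int)
        frac_part[ci] = raw_c - alloc[ci]
    col_deficit = sizes - alloc.sum(axis=0)
    row_deficit = np.array([(labels == c).sum() for c in classes]) - alloc.sum(axis=1)
    cells_order = sorted(
        ((ci, p) for ci in range(len(classes)) for p in range(3)),
        key=lambda t: (-frac_part[t[0], t[1]], t[0], t[1]),
    )
    for ci, p in cells_order:
        if row_deficit[ci] > 0 and col_deficit[p] > 0:
            alloc[ci, p] += 1
            row_deficit[ci] -= 1
            col_deficit[p] -= 1

    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    for ci, c in enumerate(classes):
        members = [s for s in samples if ds.bag_labels[s] == c]
        members = list(rng.permutation(members))
        pos = 0
        for p, name in enumerate(PARTITIONS):
            for s in members[pos: pos + alloc[ci, p]]:
                partition[s] = name
            pos += alloc[ci, p]

    for name in PARTITIONS:
        part_labels = {ds.bag_labels[s] for s, p in partition.items() if p == name}
        if len(part_labels) < 2:
            raise ValueError(
                f"partition {name!r} lacks one of the classes; "
                "evaluation metrics would be undefined"
            )
    return replace(ds, partition=partition)


def inject_label_noise(ds: BagDataset, k: int, seed: int = 0) -> BagDataset:
    """Flip the training labels of ``k`` randomly chosen train samples."""
    train = ds.samples_in("train")
    if not 0 <= k <= len(train):
        raise ValueError(f"k must be in [0, {len(train)}]")
    rng = np.random.default_rng(seed)
    flip = set(rng.choice(train, size=k, replace=False)) if k else set()
    noisy = {
        s: (1 - ds.bag_labels[s] if s in flip else ds.bag_labels[s])
        for s in ds.samples
    }
    return replace(ds, noisy_labels=noisy)


def select_hvgs(cm: CountMatrix, n: int) -> CountMatrix:
    """Keep the ``n`` most variable genes.

    Variability statistic: variance of log1p(CPM-normalized counts); ties
    broken by gene index.  Cell order and the original relative gene
    order are preserved.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n > cm.n_genes:
        raise ValueError("cannot select more genes than present")
    if n == cm.n_genes:
        return cm
    lib = cm.counts.sum(axis=1, keepdims=True).astype(float)
    lib[lib == 0] = 1.0
    logcpm = np.log1p(cm.counts / lib * 1e6)
    var = logcpm.var(axis=0)
    ranked = np.lexsort((np.arange(cm.n_genes), -var))
    keep = np.sort(ranked[:n])
    return cm.subset_genes(keep)


def simulate_dataset(spec: SimulationSpec,
                     split_fractions=(0.5, 0.25, 0.25),
                     n_label_noise: int = 0,
                     n_hvgs: int | None = None) -> BagDataset:
    """One-call pipeline: pool -> bags -> split -> optional noise/HVGs.

    Sub-seeds for the split and the noise draw derive from ``spec.seed``.
    """
    pool = generate_cell_pool(spec)
    if n_hvgs is not None and n_hvgs < spec.n_genes:
        pool = select_hvgs(pool, n_hvgs)
    ds = assemble_bags(pool, spec)
    ds = split_dataset(ds, split_fractions, seed=spec.seed + 1)
    if n_label_noise:
        ds = inject_label_noise(ds, n_label_noise, seed=spec.seed + 2)
    return ds
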