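"""Readers and writers for count matrices and run artifacts.

On disk, Matrix Market files follow the community convention of genes as
rows and cells as columns (with ``barcodes.tsv`` / ``features.tsv``
sidecars); in memory, cells are always rows.  Cell-to-sample membership
and sample labels travel in a metadata TSV with columns ``cell_id``,
``sample_id``, ``sample_label`` (plus optional ``partition`` and
``truth_label``).
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simdata import BagDataset, CountMatrix

META_COLUMNS = ("cell_id", "sample_id", "sample_label")


def _check_integral(X: np.ndarray) -> np.ndarray:
    bad = np.argwhere(X != np.round(X))
    if len(bad):
        entries = ", ".join(f"({i},{j})={X[i, j]!r}" for i, j in bad[:5])
        raise ValueError(f"non-integer count entries: {entries}")
    if np.any(X < 0):
        raise ValueError("negative count entries present")
    return X.astype(np.int64)


def read_counts(path: str, fmt: str | None = None,
                metadata: str | None = None) -> CountMatrix:
    """Read a cells x genes count matrix with optional sample metadata.

    ``fmt`` is one of ``mtx``, ``tsv``, ``h5ad`` (inferred from the file
    suffix when omitted).  For MTX, ``path`` is the ``.mtx`` file and the
    ``barcodes.tsv`` / ``features.tsv`` sidecars must sit next to it.
    """
    if fmt is None:
        suffix = os.path.splitext(str(path))[1].lstrip(".")
        fmt = {"mtx": "mtx", "tsv": "tsv", "txt": "tsv",
               "h5ad": "h5ad"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}")

    if fmt == "mtx":
        try:
            mat = spio.mmread(str(path))
        except Exception as exc:
            raise ValueError(f"malformed Matrix Market file {path!r}: {exc}")
        d = os.path.dirname(str(path))
        barcodes = pd.read_csv(os.path.join(d, "barcodes.tsv"), sep="\t",
                               header=None)[0].to_numpy(dtype=str)
        features = pd.read_csv(os.path.join(d, "features.tsv"), sep="\t",
                               header=None)[0].to_numpy(dtype=str)
        X = np.asarray(mat.todense()).T  # genes-as-rows on disk
        if X.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {X.shape} does not match sidecars "
                f"({len(barcodes)} barcodes, {len(features)} features)"
            )
        cm = CountMatrix(_check_integral(X), barcodes, features)
    elif fmt == "tsv":
        df = pd.read_csv(str(path), sep="\t", index_col=0)
        cm = CountMatrix(_check_integral(df.to_numpy()),
                         df.index.to_numpy(dtype=str),
                         df.columns.to_numpy(dtype=str))
    elif fmt == "h5ad":
        import anndata as ad
        adata = ad.read_h5ad(str(path))
        X = adata.X
        if sparse.issparse(X):
            X = np.asarray(X.todense())
        cm = CountMatrix(_check_integral(np.asarray(X)),
                         np.asarray(adata.obs_names),
                         np.asarray(adata.var_names))
        if "sample_id" in adata.obs:
            cm.sample_of_cell = np.asarray(adata.obs["sample_id"]).astype(str)
        if "truth_label" in adata.obs:
            cm.truth_label_of_cell = np.asarray(
                adata.obs["truth_label"]).astype(str)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if metadata is not None:
        cm = join_metadata(cm, pd.read_csv(str(metadata), sep="\t"))
    return cm


def join_metadata(cm: CountMatrix, meta: pd.DataFrame) -> CountMatrix:
    """Attach sample membership (and truth labels) from a metadata table."""
    missing = [c for c in ("cell_id", "sample_id") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks columns: {missing}")
    meta = meta.set_index("cell_id")
    orphans = [c for c in cm.cell_ids if c not in meta.index]
    if orphans:
        raise ValueError(
            f"{len(orphans)} cells lack sample metadata, e.g. {orphans[:3]}"
        )
    aligned = meta.loc[np.asarray(cm.cell_ids)]
    cm.sample_of_cell = aligned["sample_id"].to_numpy(dtype=str)
    if "truth_label" in aligned:
        cm.truth_label_of_cell = aligned["truth_label"].to_numpy(dtype=str)
    return cm


def dataset_from_metadata(cm: CountMatrix, meta: pd.DataFrame) -> BagDataset:
    """Build a BagDataset from a count matrix and a sample metadata table.

    The table needs ``cell_id``, ``sample_id``, ``sample_label`` and may
    carry a ``partition`` column.
    """
    cm = join_metadata(cm, meta)
    meta_idx = meta.set_index("cell_id").loc[np.asarray(cm.cell_ids)]
    if "sample_label" not in meta_idx:
        raise ValueError("metadata lacks a sample_label column")
    bag_labels = {}
    for s in np.unique(cm.sample_of_cell):
        labs = np.unique(meta_idx.loc[cm.sample_of_cell == s, "sample_label"])
        if len(labs) != 1:
            raise ValueError(f"sample {s!r} has inconsistent labels")
        bag_labels[str(s)] = int(labs[0])
    partition = {}
    if "partition" in meta_idx:
        for s in bag_labels:
            parts = np.unique(meta_idx.loc[cm.sample_of_cell == s, "partition"])
            if len(parts) != 1:
                raise ValueError(f"sample {s!r} spans partitions")
            partition[s] = str(parts[0])
    return BagDataset(cells=cm, bag_labels=bag_labels, partition=partition)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------
def write_mtx(cm: CountMatrix, directory: str, name: str = "matrix") -> str:
    """Write MTX (genes x cells) plus barcodes/features sidecars."""
    os.makedirs(directory, exist_ok=True)
    path = os.path.join(directory, f"{name}.mtx")
    spio.mmwrite(path, sparse.csr_matrix(cm.counts.T))
    pd.Series(cm.cell_ids).to_csv(os.path.join(directory, "barcodes.tsv"),
                                  sep="\t", index=False, header=False)
    pd.Series(cm.gene_ids).to_csv(os.path.join(directory, "features.tsv"),
                                  sep="\t", index=False, header=False)
    return path


def write_tsv(cm: CountMatrix, path: str) -> str:
    pd.DataFrame(cm.counts, index=pd.Index(cm.cell_ids, name="cell_id"),
                 columns=cm.gene_ids).to_csv(str(path), sep="\t")
    return str(path)


def write_h5ad(cm: CountMatrix, path: str) -> str:
    cm.to_anndata().write_h5ad(str(path))
    return str(path)


def write_bag_metadata(ds: BagDataset, path: str) -> str:
    df = ds.metadata_frame()
    df = df.rename(columns={"bag_label": "sample_label"})
    df.to_csv(str(path), sep="\t", index=False)
    return str(path)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------
def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str, config: dict, seed: int,
                   extra: dict | None = None) -> dict:
    """Run manifest: config hash, seed, package versions."""
    import cellmil

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {
            "cellmil": getattr(cellmil, "__version__", "0"),
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(str(path), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def substream_seed(seed: int, name: str) -> int:
    """Deterministic named sub-seed (< 2**31) derived from the run seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
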