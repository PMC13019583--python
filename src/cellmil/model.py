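"""Differentiable core of the dual-branch attention-MIL model.

A negative-binomial autoencoder learns per-cell latent representations
from raw counts; gated-tanh attention pools cells into a bag (sample)
embedding for sample-level classification; a cell branch distills the
attention signal into a per-cell classifier using attention-derived
pseudo-labels, a class-weighted binary cross-entropy, and an orthogonal
projection loss (OPL) over GMM-defined high/low attention groups.

Everything here is a pure function of tensors (plus the layer containers
holding parameters); the training schedule lives in :mod:`cellmil.training`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .autodiff import Parameter, Tensor, as_tensor

_EPS = 1e-7  # probability clipping in all cross-entropy terms
_THETA_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------
class Linear:
    """Affine layer ``x @ W + b`` with He-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        bound = np.sqrt(6.0 / n_in)
        self.W = Parameter(rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype))
        self.b = Parameter(np.zeros(n_out, dtype=dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Stack of Linear layers with a nonlinearity between them.

    The final layer is linear.  ``activation`` is ``"relu"`` or
    ``"softplus"``; softplus gives an everywhere-smooth network, which
    matters for path-integrated gradient attributions.
    """

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32):
        if activation not in ("relu", "softplus"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.layers = [
            Linear(widths[i], widths[i + 1], rng, dtype=dtype)
            for i in range(len(widths) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        h = as_tensor(x)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1:
                h = h.relu() if self.activation == "relu" else h.softplus()
        return h

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]


class Encoder:
    """Maps a raw count vector to a latent vector z = f_enc(x).

    Counts enter through a fixed variance-stabilizing input transform —
    log1p followed by per-gene standardization (statistics frozen from
    the pretraining cells) — so that low- and high-expression genes
    contribute on comparable scales and minority cell states are not
    drowned out by high-count noise axes.  The latent layer is linear.
    """

    def __init__(self, n_genes: int, widths: tuple[int, ...],
                 rng: np.random.Generator):
        self.n_genes = n_genes
        self.widths = tuple(widths)
        # smooth activation: the attention logit attributed by integrated
        # gradients is then smooth in the input, so the path integral
        # converges quadratically in the step count
        self.net = MLP([n_genes, *widths], rng, activation="softplus")
        self.gene_scale = np.ones(n_genes, dtype=np.float32)

    @property
    def latent_dim(self) -> int:
        return self.widths[-1]

    def set_gene_scale_from(self, counts: np.ndarray,
                            floor: float = 1e-3) -> None:
        """Freeze per-gene log1p standard deviations from ``counts``."""
        sd = np.log1p(np.asarray(counts, dtype=np.float32)).std(axis=0)
        self.gene_scale = np.maximum(sd, floor)

    def __call__(self, x_counts: Tensor) -> Tensor:
        x = as_tensor(x_counts)
        if x.shape[-1] != self.n_genes:
            raise ValueError(
                f"expected {self.n_genes} genes, got {x.shape[-1]}"
            )
        return self.net(x.log1p() * (1.0 / self.gene_scale))

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()


class NBDecoder:
    """Decodes z into per-cell per-gene NB mean and dispersion.

    The mean is the exponential of the output layer; dispersion is
    softplus with a small positive floor — both strictly positive by
    construction.  Pre-activation logits are clipped to keep ``exp``
    finite in float32.
    """

    def __init__(self, n_genes: int, widths: tuple[int, ...],
                 rng: np.random.Generator):
        k = widths[-1]
        trunk_widths = [k, *reversed(widths[:-1])]
        self.trunk = MLP(trunk_widths, rng)
        self.mean_head = Linear(trunk_widths[-1], n_genes, rng)
        self.disp_head = Linear(trunk_widths[-1], n_genes, rng)

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        h = self.trunk(as_tensor(z)).relu()
        mu = self.mean_head(h).clip(-15.0, 15.0).exp()
        theta = self.disp_head(h).clip(-15.0, 15.0).softplus() + _THETA_FLOOR
        return mu, theta

    def parameters(self) -> list[Parameter]:
        return (self.trunk.parameters() + self.mean_head.parameters()
                + self.disp_head.parameters())


class AttentionModule:
    """Gated-tanh attention: logit_i = w^T tanh(V z_i)."""

    def __init__(self, latent_dim: int, hidden: int, rng: np.random.Generator):
        self.V = Linear(latent_dim, hidden, rng, bias=False)
        self.w = Linear(hidden, 1, rng, bias=False)
        self.hidden = hidden

    def logits(self, Z: Tensor) -> Tensor:
        n = as_tensor(Z).shape[0]
        return self.w(self.V(Z).tanh()).reshape(n)

    def parameters(self) -> list[Parameter]:
        return self.V.parameters() + self.w.parameters()


class ClassifierHead:
    """MLP with a sigmoid output giving a probability in (0, 1)."""

    def __init__(self, n_in: int, hidden: tuple[int, ...],
                 rng: np.random.Generator):
        self.net = MLP([n_in, *hidden, 1], rng)

    def __call__(self, x: Tensor) -> Tensor:
        n = as_tensor(x).shape[0]
        return self.net(x).reshape(n).sigmoid()

    def parameters(self) -> list[Parameter]:
        return self.net.parameters()


# ---------------------------------------------------------------------------
# pure ops
# ---------------------------------------------------------------------------
def nb_negloglik(x, mu, theta) -> Tensor:
    """Negative log-likelihood of counts under NB(mean, dispersion).

    Parameterization: mean ``mu`` and dispersion ``theta`` with
    ``Var = mu + mu^2 / theta``.  Reduction is the mean over cells of the
    per-cell sum over genes.
    """
    x, mu, theta = as_tensor(x), as_tensor(mu), as_tensor(theta)
    if np.any(x.data < 0) or np.any(x.data != np.round(x.data)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(mu.data <= 0) or np.any(theta.data <= 0):
        raise ValueError("NB mean and dispersion must be strictly positive")
    xt = x + theta
    ll = (
        xt.lgamma() - theta.lgamma() - (x + 1.0).lgamma()
        + theta * (theta / (theta + mu)).log()
        + x * (mu / (theta + mu)).log()
    )
    per_cell = (-ll).sum(axis=-1)
    return per_cell.mean()


def bag_softmax(logits: Tensor) -> Tensor:
    """Softmax over the cells of one bag (normalizes scores to sum to 1)."""
    logits = as_tensor(logits)
    shifted = logits - float(logits.data.max())  # constant shift, stable
    e = shifted.exp()
    return e / e.sum()


def attention_scores(Z_bag, att: AttentionModule) -> Tensor:
    """Per-cell attention probabilities for one bag; sums to 1."""
    Z_bag = as_tensor(Z_bag)
    if Z_bag.ndim != 2 or Z_bag.shape[0] == 0:
        raise ValueError("Z_bag must be a non-empty (n_cells, k) matrix")
    return bag_softmax(att.logits(Z_bag))


def bag_embedding(Z_bag, a) -> Tensor:
    """Attention-weighted sum of latent vectors: v = sum_i a_i z_i."""
    Z_bag, a = as_tensor(Z_bag), as_tensor(a)
    if a.shape[0] != Z_bag.shape[0]:
        raise ValueError("attention length must match number of cells")
    return (Z_bag * a.reshape(-1, 1)).sum(axis=0)


def _clip_prob(p: Tensor) -> Tensor:
    return as_tensor(p).clip(_EPS, 1.0 - _EPS)


def sample_loss(y_hat, y) -> Tensor:
    """Mean binary cross-entropy between bag probabilities and labels."""
    y_hat = _clip_prob(as_tensor(y_hat))
    y = as_tensor(y)
    ll = y * y_hat.log() + (1.0 - y) * (1.0 - y_hat).log()
    return (-ll).mean()


def weighted_bce(tau_hat, tau, lam: float) -> Tensor:
    """Class-weighted BCE against soft pseudo-labels.

    ``lam`` weights the negative (low pseudo-label) term, ``1 - lam`` the
    positive term, compensating the heavy excess of near-zero targets.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    tau_hat = _clip_prob(as_tensor(tau_hat))
    tau = as_tensor(tau)
    term = lam * (1.0 - tau) * (1.0 - tau_hat).log() + (1.0 - lam) * tau * tau_hat.log()
    return (-term).mean()


def make_pseudo_labels(a: np.ndarray, bag_is_positive: bool,
                       scaling: str = "none") -> np.ndarray:
    """Pseudo-labels tau for the cells of one bag.

    tau = attention score for cells of positive bags, 0 for cells of
    negative bags.  ``scaling="bag_max"`` rescales positive-bag scores by
    the bag maximum so the top cell gets tau = 1 regardless of bag size.
    """
    a = np.asarray(a, dtype=float)
    if not bag_is_positive:
        return np.zeros_like(a)
    if scaling == "none":
        return a.copy()
    if scaling == "bag_max":
        m = a.max()
        return a / m if m > 0 else a.copy()
    raise ValueError(f"unknown scaling mode {scaling!r}")


def gmm_split_scores(scores: np.ndarray, seed: int = 0) -> np.ndarray:
    """Split scores into high/low groups with a 2-component 1-D GMM.

    Returns a boolean array, True for the component with the larger mean.
    Degenerate inputs (constant scores or fewer than 4 points) fall back
    to a rank-based median split with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    n = scores.size
    if n < 2:
        raise ValueError("need at least 2 scores to split")
    if n < 4 or np.std(scores) < 1e-12:
        warnings.warn(
            "degenerate attention scores; falling back to median split",
            RuntimeWarning,
            stacklevel=2,
        )
        order = np.lexsort((np.arange(n), scores))
        high = np.zeros(n, dtype=bool)
        high[order[n // 2:]] = True
        return high
    gmm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    labels = gmm.fit_predict(scores.reshape(-1, 1))
    high_comp = int(np.argmax(gmm.means_.ravel()))
    return labels == high_comp


def opl(Z, high: np.ndarray, absolute_cross: bool = False) -> Tensor:
    """Orthogonal projection loss over high/low embedding clusters.

    L = 1 - mean cosine similarity over same-cluster pairs
          + mean cosine similarity over cross-cluster pairs
    (self-pairs excluded).  ``absolute_cross`` applies ``|.|`` to the
    cross term, the variant used in the original OPL literature.
    """
    Z = as_tensor(Z)
    high = np.asarray(high, dtype=bool)
    n = Z.shape[0]
    if high.size != n:
        raise ValueError("cluster labels must match embedding rows")
    if high.all() or (~high).all():
        return Tensor(np.zeros((), dtype=Z.dtype))
    norm = ((Z * Z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    Zn = Z / norm
    S = Zn @ Zn.T
    same = (high[:, None] == high[None, :]) & ~np.eye(n, dtype=bool)
    cross = high[:, None] != high[None, :]
    s_term = (S * same.astype(Z.dtype.type)).sum() / float(same.sum())
    c_mat = S * cross.astype(Z.dtype.type)
    if absolute_cross:
        c_mat = (c_mat * c_mat + 1e-24).sqrt()
        c_term = (c_mat * cross.astype(Z.dtype.type)).sum() / float(cross.sum())
    else:
        c_term = c_mat.sum() / float(cross.sum())
    return 1.0 - s_term + c_term


def cell_loss(tau_hat, tau, Z, high: np.ndarray | None, lam: float,
              gamma: float, absolute_cross: bool = False) -> Tensor:
    """Total cell-branch loss: weighted BCE + gamma * OPL.

    ``high`` gives the GMM high/low membership of the rows of ``Z``
    (positive-bag cells only); with ``gamma == 0`` or no usable clusters
    the OPL term vanishes and the loss is the weighted BCE alone.
    """
    loss = weighted_bce(tau_hat, tau, lam)
    if gamma != 0.0 and high is not None and Z is not None \
            and np.asarray(Z.data if isinstance(Z, Tensor) else Z).shape[0] > 1:
        loss = loss + gamma * opl(Z, high, absolute_cross=absolute_cross)
    return loss


# ---------------------------------------------------------------------------
# network container / checkpointing
# ---------------------------------------------------------------------------
@dataclass
class ModelState:
    """All parameter groups of the dual-branch model plus loss weights."""

    encoder: Encoder
    decoder: NBDecoder
    attention: AttentionModule
    sample_head: ClassifierHead
    cell_head: ClassifierHead
    lam: float = 0.1
    gamma: float = 1.0
    meta: dict = field(default_factory=dict)

    @classmethod
    def build(cls, n_genes: int, encoder_widths=(512, 256, 128),
              attention_hidden: int = 128, head_hidden=(16, 16),
              lam: float = 0.1, gamma: float = 1.0,
              seed: int = 0) -> "ModelState":
        rng = np.random.default_rng(seed)
        enc = Encoder(n_genes, tuple(encoder_widths), rng)
        dec = NBDecoder(n_genes, tuple(encoder_widths), rng)
        att = AttentionModule(enc.latent_dim, attention_hidden, rng)
        s_head = ClassifierHead(enc.latent_dim, tuple(head_hidden), rng)
        c_head = ClassifierHead(enc.latent_dim, tuple(head_hidden), rng)
        meta = {
            "n_genes": n_genes,
            "encoder_widths": list(encoder_widths),
            "attention_hidden": attention_hidden,
            "head_hidden": list(head_hidden),
            "seed": seed,
        }
        return cls(enc, dec, att, s_head, c_head, lam=lam, gamma=gamma,
                   meta=meta)

    # parameter groups -------------------------------------------------
    def autoencoder_parameters(self) -> list[Parameter]:
        return self.encoder.parameters() + self.decoder.parameters()

    def sample_branch_parameters(self) -> list[Parameter]:
        return self.attention.parameters() + self.sample_head.parameters()

    def cell_branch_parameters(self) -> list[Parameter]:
        return self.cell_head.parameters()

    def all_parameters(self) -> list[Parameter]:
        return (self.autoencoder_parameters()
                + self.sample_branch_parameters()
                + self.cell_branch_parameters())

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.all_parameters()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.all_parameters(), snap):
            p.data = d.copy()

    # inference --------------------------------------------------------
    def encode(self, x_counts) -> np.ndarray:
        """Latent representation of a batch of count vectors."""
        return self.encoder(np.asarray(x_counts, dtype=np.float32)).data

    def bag_forward(self, x_counts) -> tuple[np.ndarray, np.ndarray, float]:
        """Attention scores, latents and bag probability for one bag."""
        Z = self.encoder(np.asarray(x_counts, dtype=np.float32))
        a = attention_scores(Z, self.attention)
        v = bag_embedding(Z, a)
        y_hat = self.sample_head(v.reshape(1, -1))
        return a.data.astype(float), Z.data, float(y_hat.data[0])

    def cell_probabilities(self, x_counts) -> np.ndarray:
        Z = self.encoder(np.asarray(x_counts, dtype=np.float32))
        return self.cell_head(Z).data.astype(float)

    # persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        """Write parameters to ``path`` (.npz) + a JSON metadata sidecar."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.all_parameters())}
        arrays["gene_scale"] = self.encoder.gene_scale
        np.savez(path, **arrays)
        sidecar = str(path)
        if sidecar.endswith(".npz"):
            sidecar = sidecar[:-4]
        with open(sidecar + ".json", "w") as fh:
            json.dump({"lam": self.lam, "gamma": self.gamma, **self.meta}, fh,
                      indent=2)

    @classmethod
    def load(cls, path: str) -> "ModelState":
        sidecar = str(path)
        if sidecar.endswith(".npz"):
            sidecar = sidecar[:-4]
        with open(sidecar + ".json") as fh:
            meta = json.load(fh)
        state = cls.build(
            n_genes=meta["n_genes"],
            encoder_widths=tuple(meta["encoder_widths"]),
            attention_hidden=meta["attention_hidden"],
            head_hidden=tuple(meta["head_hidden"]),
            lam=meta["lam"], gamma=meta["gamma"], seed=meta.get("seed", 0),
        )
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as data:
            for i, p in enumerate(state.all_parameters()):
                p.data = data[f"p{i}"].astype(p.data.dtype)
            if "gene_scale" in data:
                state.encoder.gene_scale = data["gene_scale"]
        return state
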