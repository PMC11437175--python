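"""NumPy implementation of the refinement network and its training loss.

The network is a plain MLP: four fully connected layers of width 512, each
followed by batch normalisation (eps 1e-5, momentum 0.1), leaky ReLU
(negative slope 0.01) and dropout (p 0.2), then a linear output layer with
one logit per leaf of the taxonomic tree. Optimisation is Adam.

The loss is a flat-softmax hierarchical negative log-likelihood: leaf
likelihoods come from a softmax over the logits; the likelihood of an
internal node is the sum over its descendant leaves; the loss of a training
example annotated to node ``t`` is the summed ``-log`` likelihood over
every node on the path from the domain level down to ``t``. A contig
annotated only to an internal node therefore contributes loss only along
its annotated prefix, which is what lets a single model train on
annotations truncated at any rank.

Gradients are exact. With ``p = softmax(z)``, path nodes ``n`` with leaf
incidence masks ``m_n`` and likelihoods ``q_n = m_n . p``:

    dL/dz_j = p_j * (K - sum_n m_nj / q_n)

where ``K`` is the path length — the softmax Jacobian collapses to this
closed form because each ``q_n`` is linear in ``p``.
"""

from __future__ import annotations

import numpy as np

LIKELIHOOD_FLOOR = 1e-12


def leaf_softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stabilised softmax over the last axis."""
    logits = np.asarray(logits, dtype=np.float64)
    shifted = logits - logits.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)


def aggregate_likelihoods(leaf_probs: np.ndarray, tree) -> np.ndarray:
    """Per-node likelihoods: each node sums its descendant leaves.

    Accepts a single probability vector or a batch; returns likelihoods
    with one entry per tree node (the root aggregates to 1).
    """
    return np.asarray(leaf_probs) @ tree.leaf_mask.T


def path_node_matrix(tree, target_nodes: np.ndarray) -> np.ndarray:
    """Stack each target's root-to-node path into an int matrix, -1 padded."""
    from .taxonomy import N_RANKS

    paths = np.full((len(target_nodes), N_RANKS), -1, dtype=np.intp)
    for i, nid in enumerate(target_nodes):
        path = tree.node_path(int(nid))
        paths[i, : len(path)] = path
    return paths


def hierarchical_loss_and_grad(
    logits: np.ndarray, tree, path_nodes: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean ancestor-path NLL over a batch, and its gradient w.r.t. logits.

    ``path_nodes`` is the (batch, max_depth) matrix from
    :func:`path_node_matrix`, row-aligned with ``logits``.
    """
    probs = leaf_softmax(logits)
    batch, _ = probs.shape
    loss = 0.0
    inv_sum = np.zeros_like(probs)  # sum over path nodes of m_n / q_n
    depth = (path_nodes >= 0).sum(axis=1).astype(np.float64)
    for d in range(path_nodes.shape[1]):
        sel = path_nodes[:, d]
        valid = sel >= 0
        if not np.any(valid):
            break
        masks = tree.leaf_mask[sel[valid]]
        q = np.maximum((masks * probs[valid]).sum(axis=1), LIKELIHOOD_FLOOR)
        loss -= np.log(q).sum()
        inv_sum[valid] += masks / q[:, None]
    grad = probs * (depth[:, None] - inv_sum) / batch
    return loss / batch, grad


def hierarchical_loss(leaf_probs: np.ndarray, tree, true_node: int) -> float:
    """Ancestor-path NLL of one probability vector for one true node."""
    leaf_probs = np.asarray(leaf_probs, dtype=np.float64)
    loss = 0.0
    for nid in tree.node_path(true_node):
        q = float(tree.leaf_mask[nid] @ leaf_probs)
        loss -= np.log(max(q, LIKELIHOOD_FLOOR))
    return loss


class MLP:
    """Fully connected network with batch norm, leaky ReLU and dropout.

    Initialisation follows the Kaiming-uniform convention (weights in
    ``±sqrt(1/fan_in)`` after the leaky-ReLU gain, biases likewise), batch
    norm keeps running statistics with the stated momentum, and dropout is
    inverted so inference needs no rescaling.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        hidden_sizes: tuple[int, ...] = (512, 512, 512, 512),
        leaky_slope: float = 0.01,
        bn_eps: float = 1e-5,
        bn_momentum: float = 0.1,
        dropout: float = 0.2,
        rng: np.random.Generator | None = None,
    ):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.hidden_sizes = tuple(hidden_sizes)
        self.slope = leaky_slope
        self.bn_eps = bn_eps
        self.bn_momentum = bn_momentum
        self.dropout = dropout
        rng = rng or np.random.default_rng()

        dims = [in_dim, *hidden_sizes]
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            bound = 1.0 / np.sqrt(d_in)
            self.params[f"W{i}"] = rng.uniform(-bound, bound, size=(d_in, d_out))
            self.params[f"b{i}"] = rng.uniform(-bound, bound, size=d_out)
            self.params[f"gamma{i}"] = np.ones(d_out)
            self.params[f"beta{i}"] = np.zeros(d_out)
            self.running[f"mean{i}"] = np.zeros(d_out)
            self.running[f"var{i}"] = np.ones(d_out)
        bound = 1.0 / np.sqrt(dims[-1])
        self.params["W_out"] = rng.uniform(-bound, bound, size=(dims[-1], out_dim))
        self.params["b_out"] = rng.uniform(-bound, bound, size=out_dim)
        self.n_hidden = len(hidden_sizes)

    def forward(
        self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[dict]]:
        """Return logits and the per-layer cache needed for backward."""
        h = np.asarray(x, dtype=np.float64)
        caches: list[dict] = []
        for i in range(self.n_hidden):
            a = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if train:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                n = a.shape[0]
                unbiased = var * n / max(n - 1, 1)
                m = self.bn_momentum
                self.running[f"mean{i}"] = (1 - m) * self.running[f"mean{i}"] + m * mu
                self.running[f"var{i}"] = (1 - m) * self.running[f"var{i}"] + m * unbiased
            else:
                mu = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            inv_std = 1.0 / np.sqrt(var + self.bn_eps)
            xhat = (a - mu) * inv_std
            z = self.params[f"gamma{i}"] * xhat + self.params[f"beta{i}"]
            act = np.where(z > 0, z, self.slope * z)
            if train and self.dropout > 0:
                if rng is None:
                    raise ValueError("training forward pass requires an rng for dropout")
                keep = rng.random(act.shape) >= self.dropout
                out = act * keep / (1.0 - self.dropout)
            else:
                keep = None
                out = act
            caches.append(
                {"h": h, "a": a, "mu": mu, "inv_std": inv_std, "xhat": xhat,
                 "z": z, "keep": keep, "train": train}
            )
            h = out
        logits = h @ self.params["W_out"] + self.params["b_out"]
        caches.append({"h": h})
        return logits, caches

    def backward(self, dlogits: np.ndarray, caches: list[dict]) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        out_cache = caches[-1]
        grads["W_out"] = out_cache["h"].T @ dlogits
        grads["b_out"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W_out"].T
        for i in range(self.n_hidden - 1, -1, -1):
            c = caches[i]
            if c["keep"] is not None:
                dh = dh * c["keep"] / (1.0 - self.dropout)
            dz = dh * np.where(c["z"] > 0, 1.0, self.slope)
            grads[f"gamma{i}"] = (dz * c["xhat"]).sum(axis=0)
            grads[f"beta{i}"] = dz.sum(axis=0)
            dxhat = dz * self.params[f"gamma{i}"]
            if c["train"]:
                n = dz.shape[0]
                # batch-norm backward through the batch statistics
                da = (
                    dxhat
                    - dxhat.mean(axis=0)
                    - c["xhat"] * (dxhat * c["xhat"]).mean(axis=0)
                ) * c["inv_std"]
            else:
                da = dxhat * c["inv_std"]
            grads[f"W{i}"] = c["h"].T @ da
            grads[f"b{i}"] = da.sum(axis=0)
            dh = da @ self.params[f"W{i}"].T
        return grads


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
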