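"""Structural node embeddings via biased random walks + skip-gram.

Second-order random walks in the style of node2vec: the return parameter
`p` penalizes immediately revisiting the previous node, the in-out
parameter `q` biases walks outward (q < 1) or inward (q > 1).  Walk
corpora are fed to a skip-gram model with negative sampling trained by
vectorized SGD.  With p = q = 1 the walks are first-order uniform and a
fast fully-vectorized sampler is used.

Walks never leave a connected component, so in a disjoint union of
per-sample subnetworks the embedding of each sample's subgraph is learned
from that subgraph's context alone.  Degree-0 nodes receive the zero
vector.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .config import Node2vecConfig

__all__ = ["Node2VecEmbedding", "node2vec_embed"]


class Node2VecEmbedding(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer from adjacency matrix to node embedding.

    Parameters mirror the usual node2vec knobs. `fit_transform(adjacency)`
    returns an (n_nodes, dim) float matrix, deterministic given `seed`.
    """

    def __init__(
        self,
        dim: int = 20,
        walk_length: int = 80,
        walks_per_node: int = 10,
        window: int = 5,
        return_p: float = 1.0,
        inout_q: float = 1.0,
        negative_samples: int = 5,
        epochs: int = 5,
        learning_rate: float = 0.025,
        seed: int = 0,
    ):
        self.dim = dim
        self.walk_length = walk_length
        self.walks_per_node = walks_per_node
        self.window = window
        self.return_p = return_p
        self.inout_q = inout_q
        self.negative_samples = negative_samples
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    # -- walk generation -----------------------------------------------------

    def _uniform_walks(self, indptr, indices, starts, rng) -> np.ndarray:
        walks = np.empty((len(starts), self.walk_length), dtype=np.int64)
        walks[:, 0] = starts
        cur = starts
        for step in range(1, self.walk_length):
            deg = indptr[cur + 1] - indptr[cur]
            offset = (rng.random(len(cur)) * deg).astype(np.int64)
            cur = indices[indptr[cur] + offset]
            walks[:, step] = cur
        return walks

    def _biased_walks(self, indptr, indices, starts, rng) -> np.ndarray:
        # second-order walk with explicit p/q weights; per-walk python loop,
        # adequate for the graph sizes this model targets
        p, q = self.return_p, self.inout_q
        neighbor_sets = {}
        walks = np.empty((len(starts), self.walk_length), dtype=np.int64)
        for w, s in enumerate(starts):
            walk = [s]
            prev = -1
            for _ in range(self.walk_length - 1):
                cur = walk[-1]
                nbrs = indices[indptr[cur]: indptr[cur + 1]]
                if prev < 0:
                    nxt = nbrs[int(rng.random() * len(nbrs))]
                else:
                    if prev not in neighbor_sets:
                        neighbor_sets[prev] = set(
                            indices[indptr[prev]: indptr[prev + 1]]
                        )
                    prev_nbrs = neighbor_sets[prev]
                    weights = np.where(
                        nbrs == prev,
                        1.0 / p,
                        [1.0 if n in prev_nbrs else 1.0 / q for n in nbrs],
                    )
                    weights = weights / weights.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=weights)]
                prev = cur
                walk.append(int(nxt))
            walks[w] = walk
        return walks

    def _walks(self, adjacency: sp.csr_matrix, rng) -> np.ndarray:
        indptr, indices = adjacency.indptr, adjacency.indices
        degrees = np.diff(indptr)
        active = np.flatnonzero(degrees > 0)
        if len(active) == 0:
            return np.empty((0, self.walk_length), dtype=np.int64)
        starts = np.repeat(active, self.walks_per_node)
        rng.shuffle(starts)
        if self.return_p == 1.0 and self.inout_q == 1.0:
            return self._uniform_walks(indptr, indices, starts, rng)
        return self._biased_walks(indptr, indices, starts, rng)

    # -- skip-gram with negative sampling -------------------------------------

    @staticmethod
    def _pairs(walks: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
        centers, contexts = [], []
        for delta in range(1, window + 1):
            if walks.shape[1] <= delta:
                break
            a = walks[:, :-delta].ravel()
            b = walks[:, delta:].ravel()
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
        return np.concatenate(centers), np.concatenate(contexts)

    @staticmethod
    def _averaged_step(weights, rows, grads, lr) -> None:
        acc = np.zeros_like(weights)
        np.add.at(acc, rows, grads)
        counts = np.bincount(rows, minlength=weights.shape[0])[:, None]
        weights -= lr * acc / np.maximum(counts, 1)

    def _train_sgns(self, n_nodes, centers, contexts, rng) -> np.ndarray:
        d = self.dim
        w_in = (rng.random((n_nodes, d)) - 0.5) / d
        w_out = np.zeros((n_nodes, d))
        counts = np.bincount(contexts, minlength=n_nodes).astype(np.float64)
        noise = counts**0.75
        noise_cdf = np.cumsum(noise / noise.sum())
        n_pairs = len(centers)
        total_steps = self.epochs * n_pairs
        lr0, lr_min = self.learning_rate, 1e-4
        # batch scales with vocabulary: row gradients are averaged per batch,
        # so smaller batches mean more (and better-conditioned) row updates
        batch = int(max(256, 4 * n_nodes))
        done = 0
        for _ in range(self.epochs):
            order = rng.permutation(n_pairs)
            for lo in range(0, n_pairs, batch):
                sel = order[lo: lo + batch]
                c, o = centers[sel], contexts[sel]
                neg = np.searchsorted(
                    noise_cdf, rng.random((len(sel), self.negative_samples))
                )
                lr = max(lr_min, lr0 * (1 - done / total_steps))
                v = w_in[c]  # (B, d)
                u_pos = w_out[o]
                g_pos = expit((v * u_pos).sum(1)) - 1.0  # (B,)
                u_neg = w_out[neg]  # (B, k, d)
                g_neg = expit(np.einsum("bd,bkd->bk", v, u_neg))
                grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
                # rows recur many times per batch: average (not sum) the
                # accumulated row gradients so the step stays bounded
                self._averaged_step(w_in, c, grad_v, lr)
                out_rows = np.concatenate([o, neg.reshape(-1)])
                out_grads = np.concatenate(
                    [g_pos[:, None] * v,
                     (g_neg[..., None] * v[:, None, :]).reshape(-1, d)]
                )
                self._averaged_step(w_out, out_rows, out_grads, lr)
                done += len(sel)
        return w_in

    # -- public API ------------------------------------------------------------

    def fit(self, adjacency, y=None) -> "Node2VecEmbedding":
        if self.dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        adjacency = sp.csr_matrix(adjacency)
        rng = np.random.default_rng(self.seed)
        walks = self._walks(adjacency, rng)
        n = adjacency.shape[0]
        if len(walks) == 0:
            self.embedding_ = np.zeros((n, self.dim))
            return self
        centers, contexts = self._pairs(walks, self.window)
        emb = self._train_sgns(n, centers, contexts, rng)
        isolated = np.diff(adjacency.indptr) == 0
        emb[isolated] = 0.0
        self.embedding_ = emb
        return self

    def transform(self, adjacency=None) -> np.ndarray:
        return self.embedding_

    def fit_transform(self, adjacency, y=None) -> np.ndarray:
        return self.fit(adjacency).transform(adjacency)


def node2vec_embed(adjacency, config: Node2vecConfig) -> np.ndarray:
    """Functional wrapper: embed every node of `adjacency` per `config`."""
    config.validate()
    est = Node2VecEmbedding(
        dim=config.dim,
        walk_length=config.walk_length,
        walks_per_node=config.walks_per_node,
        window=config.window,
        return_p=config.return_p,
        inout_q=config.inout_q,
        negative_samples=config.negative_samples,
        epochs=config.epochs,
        seed=config.seed,
    )
    return est.fit_transform(adjacency)
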