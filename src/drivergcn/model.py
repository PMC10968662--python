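"""Graph convolutional network with a conditional-random-field layer.

Architecture: a two-layer GCN over the symmetric-normalized adjacency
with self-loops, Âˆ = D̃^{-1/2} (A + I) D̃^{-1/2}, with a CRF refinement
block between the layers.  The first GCN layer produces per-node
embeddings Q; the CRF block pulls each embedding toward an
attention-weighted average of its neighbors while anchoring it to Q:

    H_i <- (α Q_i + β Σ_{j∈M_i} g_ij H_j) / (α + β Σ_{j∈M_i} g_ij)

iterated T times, where the pairwise weights g_ij are a softmax over node
i's neighborhood M_i of GAT-style attention scores
LeakyReLU(a · [W_t H_i ‖ W_t H_j]).  The same α, β also weight the CRF
energy that joins the supervised loss:

    l_CRF = Σ_i ( α‖H_i − Q_i‖² + β Σ_{j∈M_i} g_ij ‖H_i − H_j‖² )

The supervised term is class-weighted binary cross-entropy,
l_θ = −mean( p·y·log h + (1−y)·log(1−h) ) over training nodes, with p ≥ 1
up-weighting the minority positive class; the total loss l_CRF + l_θ is
minimized with Adam.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, Tensor, constant, parameter

logger = logging.getLogger("drivergcn")

PROB_EPS = 1e-7
LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# graph operators (numpy-facing)
# ---------------------------------------------------------------------------


def normalize_adjacency(A) -> sp.csr_matrix:
    """Symmetric normalization with self-loops: D̃^{-1/2} (A+I) D̃^{-1/2}.

    Isolated nodes keep a unit self-loop, preserving their own signal.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    if (abs(A - A.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    a_tilde = A + sp.identity(A.shape[0], format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()


def gcn_layer(H, A_hat, W, activation: str = "relu") -> np.ndarray:
    """One spectral graph convolution: activation(Â H W)."""
    out = sp.csr_matrix(A_hat) @ np.asarray(H, float) @ np.asarray(W, float)
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation == "identity":
        return out
    if activation == "sigmoid":
        return 1.0 / (1.0 + np.exp(-out))
    raise ValueError(f"unknown activation {activation!r}")


def _edge_arrays(adjacency: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    """Directed (src, dst) arrays of every neighbor pair (self excluded)."""
    coo = sp.coo_matrix(adjacency)
    keep = coo.row != coo.col
    return coo.row[keep], coo.col[keep]


def _attention_edge_weights(
    H: Tensor, Wt: Tensor, a_src: Tensor, a_dst: Tensor,
    src: np.ndarray, dst: np.ndarray, n_nodes: int,
) -> Tensor:
    """Softmax-normalized attention g_e for each directed edge, grouped by
    source node (rows of g are stochastic over each neighborhood)."""
    z = H @ Wt  # (n, h)
    score_src = (z * a_src).sum(axis=1)  # (n,)
    score_dst = (z * a_dst).sum(axis=1)
    e = (score_src.gather_rows(src) + score_dst.gather_rows(dst)).leaky_relu(
        LEAKY_SLOPE
    )
    # max-subtraction per neighborhood for numerical stability (constant shift)
    shift = np.full(n_nodes, -np.inf)
    np.maximum.at(shift, src, e.data)
    shift[~np.isfinite(shift)] = 0.0
    ex = (e - constant(shift[src])).exp()
    denom = ex.segment_sum(src, n_nodes)
    return ex / denom.gather_rows(src)


def attention_coefficients(H, Wt, a, adjacency) -> sp.csr_matrix:
    """Pairwise attention weights g as a sparse (n, n) matrix; row i holds
    the softmax over node i's neighborhood.  `a` is the concatenation
    scorer vector of length 2*h."""
    H = np.asarray(H, float)
    a = np.asarray(a, float).ravel()
    h_dim = np.asarray(Wt).shape[1]
    src, dst = _edge_arrays(adjacency)
    n = H.shape[0]
    if len(src) == 0:
        return sp.csr_matrix((n, n))
    g = _attention_edge_weights(
        constant(H), constant(Wt), constant(a[:h_dim]), constant(a[h_dim:]),
        src, dst, n,
    )
    return sp.csr_matrix((g.data, (src, dst)), shape=(n, n))


def crf_update(Q, g: sp.spmatrix, alpha: float, beta: float, iterations: int = 2):
    """Iterate the anchored neighborhood-average update from H⁰ = Q.

    Nodes with empty neighborhoods keep H_i = Q_i.  With β = 0 the update
    is the identity.
    """
    if alpha == 0 and beta == 0:
        raise ValueError("crf_update requires alpha > 0 or beta > 0")
    Q = np.asarray(Q, float)
    if beta == 0:
        return Q.copy()
    g = sp.csr_matrix(g)
    s = np.asarray(g.sum(axis=1)).ravel()  # Σ_j g_ij (1 or 0)
    denom = (alpha + beta * s)[:, None]
    H = Q.copy()
    for _ in range(iterations):
        H = (alpha * Q + beta * (g @ H)) / denom
    return H


def crf_loss(H, Q, g: sp.spmatrix, alpha: float, beta: float) -> float:
    """CRF energy: unary anchoring to Q plus attention-weighted pairwise
    smoothness."""
    H = np.asarray(H, float)
    Q = np.asarray(Q, float)
    unary = alpha * ((H - Q) ** 2).sum()
    coo = sp.coo_matrix(g)
    diffs = ((H[coo.row] - H[coo.col]) ** 2).sum(axis=1) if coo.nnz else 0.0
    pairwise = beta * float((coo.data * diffs).sum()) if coo.nnz else 0.0
    return float(unary + pairwise)


def weighted_bce(h, y, positive_weight: float = 1.0, mask=None) -> float:
    """Class-weighted binary cross-entropy averaged over `mask`."""
    h = np.clip(np.asarray(h, float).ravel(), PROB_EPS, 1 - PROB_EPS)
    y = np.asarray(y, float).ravel()
    loss = -(positive_weight * y * np.log(h) + (1 - y) * np.log(1 - h))
    if mask is not None:
        loss = loss[np.asarray(mask)]
    return float(loss.mean())


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class GCNCRFClassifier(BaseEstimator, ClassifierMixin):
    """Transductive node classifier: 2-layer GCN with CRF refinement.

    Parameters
    ----------
    hidden_dim : width of the first GCN layer (the CRF operates on this
        embedding).
    alpha, beta : CRF balance factors — anchoring to the GCN embedding vs
        neighborhood smoothing.  beta=0 disables the CRF block entirely.
    crf_iterations : number of unrolled update steps T.
    positive_weight : multiplier p >= 1 on the positive-class loss term.
    learning_rate, weight_decay, dropout, epochs : Adam training recipe;
        weight decay is a coupled L2 penalty.
    random_state : seeds parameter initialization and dropout.
    """

    def __init__(
        self,
        hidden_dim: int = 64,
        alpha: float = 1.0,
        beta: float = 1.0,
        crf_iterations: int = 2,
        positive_weight: float = 1.0,
        learning_rate: float = 0.001,
        weight_decay: float = 0.005,
        dropout: float = 0.1,
        epochs: int = 3000,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.alpha = alpha
        self.beta = beta
        self.crf_iterations = crf_iterations
        self.positive_weight = positive_weight
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.epochs = epochs
        self.random_state = random_state

    # -- internals -----------------------------------------------------------

    def _init_params(self, in_dim: int, rng: np.random.Generator) -> dict[str, Tensor]:
        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return parameter(rng.uniform(-limit, limit, size=shape))

        h = self.hidden_dim
        params = {
            "W1": glorot((in_dim, h)),
            "W2": glorot((h, 1)),
        }
        if self.beta > 0:
            params["Wt"] = glorot((h, h))
            params["a_src"] = parameter(rng.uniform(-0.1, 0.1, size=h))
            params["a_dst"] = parameter(rng.uniform(-0.1, 0.1, size=h))
        return params

    def _dropout(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        if not training or self.dropout == 0:
            return x
        keep = 1.0 - self.dropout
        mask = (rng.random(x.shape) < keep) / keep
        return x * constant(mask)

    def _forward(
        self,
        X: Tensor,
        params: Mapping[str, Tensor],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return (per-node probability h, CRF energy l_CRF)."""
        x = self._dropout(X, rng, training)
        Q = x.__matmul__(params["W1"]).spmm(self._a_hat).relu()
        if self.beta > 0 and len(self._src):
            g = _attention_edge_weights(
                Q, params["Wt"], params["a_src"], params["a_dst"],
                self._src, self._dst, self._n_nodes,
            )
            s = g.segment_sum(self._src, self._n_nodes)  # (n,)
            denom = (self.alpha + self.beta * s.data)[:, None]  # constant per step
            H = Q
            for _ in range(self.crf_iterations):
                msg = (H.gather_rows(self._dst) * g.reshape(-1, 1)).segment_sum(
                    self._src, self._n_nodes
                )
                H = (Q * self.alpha + msg * self.beta) / constant(denom)
            diff_edges = (
                (H.gather_rows(self._src) - H.gather_rows(self._dst)) ** 2
            ).sum(axis=1)
            # energy averaged over nodes so it shares the scale of the
            # (mean) cross-entropy term in the total loss
            l_crf = (
                ((H - Q) ** 2).sum() * self.alpha
                + (g * diff_edges).sum() * self.beta
            ) * (1.0 / self._n_nodes)
        else:
            H = Q
            l_crf = constant(0.0)
        h = self._dropout(H, rng, training)
        logits = h.__matmul__(params["W2"]).spmm(self._a_hat)
        prob = logits.reshape(-1).sigmoid()
        return prob, l_crf

    def _bce(self, prob: Tensor, y: np.ndarray, mask: np.ndarray) -> Tensor:
        p = prob.clip(PROB_EPS, 1 - PROB_EPS)
        yv = constant(y.astype(float))
        per_node = -(
            yv * p.log() * self.positive_weight
            + (constant(1.0) - yv) * (constant(1.0) - p).log()
        )
        return per_node.gather_rows(np.flatnonzero(mask)).mean()

    def _total_loss(
        self,
        X: Tensor,
        params: Mapping[str, Tensor],
        y: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor, Tensor]:
        prob, l_crf = self._forward(X, params, training=training, rng=rng)
        l_bce = self._bce(prob, y, mask)
        return l_crf + l_bce, l_crf, l_bce

    def _attach_graph(self, adjacency) -> None:
        adjacency = sp.csr_matrix(adjacency)
        self._a_hat = normalize_adjacency(adjacency)
        self._src, self._dst = _edge_arrays(adjacency)
        self._n_nodes = adjacency.shape[0]

    # -- sklearn API -----------------------------------------------------------

    def fit(self, X, y, adjacency=None, train_mask=None) -> "GCNCRFClassifier":
        if adjacency is None:
            raise ValueError("fit requires the graph adjacency matrix")
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if train_mask is None:
            train_mask = np.ones(len(y), dtype=bool)
        train_mask = np.asarray(train_mask, bool)
        if len(set(y[train_mask].tolist())) < 2:
            raise ValueError("training mask must contain both classes")
        self._attach_graph(adjacency)
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(X.shape[1], rng)
        opt = Adam(
            list(params.values()),
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
        )
        X_t = constant(X)
        trace = np.empty((self.epochs, 3))
        for epoch in range(self.epochs):
            opt.zero_grad()
            total, l_crf, l_bce = self._total_loss(
                X_t, params, y, train_mask, training=True, rng=rng
            )
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"crf={l_crf.data!r} bce={l_bce.data!r}"
                )
            total.backward()
            opt.step()
            trace[epoch] = (float(total.data), float(l_crf.data), float(l_bce.data))
        self.params_ = {k: v.data.copy() for k, v in params.items()}
        self.loss_trace_ = trace
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def _eval_scores(self, X, adjacency=None) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features_in_}"
            )
        if adjacency is not None:
            self._attach_graph(adjacency)
        params = {k: constant(v) for k, v in self.params_.items()}
        prob, _ = self._forward(constant(X), params, training=False)
        return prob.data

    def predict_proba(self, X, adjacency=None) -> np.ndarray:
        h = self._eval_scores(X, adjacency)
        return np.column_stack([1 - h, h])

    def predict(self, X, adjacency=None) -> np.ndarray:
        return (self._eval_scores(X, adjacency) >= 0.5).astype(int)

    # -- persistence ------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = json.dumps(self.get_params())
        np.savez(
            path,
            _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
            _n_features=np.array([self.n_features_in_]),
            **{f"param_{k}": v for k, v in self.params_.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "GCNCRFClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        est = cls(**meta)
        est.params_ = {
            k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
        }
        est.n_features_in_ = int(data["_n_features"][0])
        est.classes_ = np.array([0, 1])
        return est


# ---------------------------------------------------------------------------
# cross-validated grid search over the training recipe
# ---------------------------------------------------------------------------


def grid_search_cv(
    X,
    y,
    adjacency,
    train_mask,
    grid: Sequence[Mapping],
    base_params: Mapping | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Select the parameter combination with the best mean validation AUPR
    under stratified k-fold CV restricted to training nodes."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    train_idx = np.flatnonzero(np.asarray(train_mask, bool))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    results: list[tuple[dict, float]] = []
    for combo in grid:
        params = dict(base_params or {})
        params.update(combo)
        auprs = []
        for fold_train, fold_val in skf.split(train_idx, y[train_idx]):
            mask = np.zeros(len(y), dtype=bool)
            mask[train_idx[fold_train]] = True
            est = GCNCRFClassifier(**params, random_state=seed)
            est.fit(X, y, adjacency=adjacency, train_mask=mask)
            scores = est.predict_proba(X)[:, 1]
            val = train_idx[fold_val]
            auprs.append(average_precision_score(y[val], scores[val]))
        results.append((dict(combo), float(np.mean(auprs))))
        logger.info("grid %s: mean CV AUPR %.4f", combo, results[-1][1])
    best = max(results, key=lambda t: t[1])[0]
    return best, results
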