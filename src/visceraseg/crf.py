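"""Pairwise CRF over the superpixel adjacency graph.

The model scores a labeling y of the S superpixels by

    score(y) = sum_s  W_u[y_s] . Q_s  +  sum_(a,b)  W_p[y_a, y_b] . F_ab

and the energy to minimize is E(y) = -score(y).  Node features Q_s are
by default the random-forest class probabilities; F_ab are the pairwise
(edge) features of adjacent superpixels.  W_p carries one weight vector
per unordered class pair, so the model learns class-pair relationships
(e.g., "heart above liver is plausible when the color step is large"),
not merely Potts smoothing.

Weights are learned by a margin-rescaled structured SVM with n-slack
cutting planes: repeatedly run loss-augmented MAP inference (weighted
Hamming loss, class weights = inverse training frequency), accumulate
violated constraints, and re-solve the quadratic program.  Features are
standardized (training mean/scale stored on the model) for QP
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

K_CLASSES = 4          # misc, heart, liver, lung (codes 1..4 -> 0..3)
_PAIRS = [(k, l) for k in range(K_CLASSES) for l in range(k, K_CLASSES)]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}
N_PAIRS = len(_PAIRS)  # 10


def _pair_idx(k: int, l: int) -> int:
    return _PAIR_INDEX[(k, l) if k <= l else (l, k)]


@dataclass
class CRFInstance:
    """One image's CRF problem: node features, graph, edge features."""

    node_features: np.ndarray            # S x D_q (e.g. RF probabilities)
    edges: np.ndarray                    # E x 2 superpixel-id pairs
    edge_features: np.ndarray            # E x D_e
    gold: Optional[np.ndarray] = None    # S, class codes 1..4
    node_weights: Optional[np.ndarray] = None  # e.g. pixel counts (training)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=float)
        if len(self.edges) != len(self.edge_features):
            raise ValueError("edge list and edge features disagree in length")
        if self.edges.size and self.edges.max() >= len(self.node_features):
            raise ValueError("edge references an unknown node")
        if self.gold is not None:
            self.gold = np.asarray(self.gold, dtype=np.int64)
            if self.gold.min() < 1 or self.gold.max() > K_CLASSES:
                raise ValueError("gold labels must be class codes 1..4")

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)


@dataclass
class CRFModel:
    """Learned unary and symmetric per-class-pair edge weights."""

    unary_weights: np.ndarray            # K x D_q
    pair_weights: np.ndarray             # N_PAIRS x D_e
    node_mean: np.ndarray
    node_scale: np.ndarray
    edge_mean: np.ndarray
    edge_scale: np.ndarray
    objective_history: list = field(default_factory=list)

    @property
    def pairwise_full(self) -> np.ndarray:
        """K x K x D_e symmetrized view of the pair weights."""
        D = self.pair_weights.shape[1]
        full = np.zeros((K_CLASSES, K_CLASSES, D))
        for (k, l), i in _PAIR_INDEX.items():
            full[k, l] = self.pair_weights[i]
            full[l, k] = self.pair_weights[i]
        return full

    def _standardize(self, inst: CRFInstance):
        q = (inst.node_features - self.node_mean) / self.node_scale
        f = ((inst.edge_features - self.edge_mean) / self.edge_scale
             if len(inst.edge_features) else inst.edge_features)
        return q, f

    def potentials(self, inst: CRFInstance):
        """(theta_u: S x K, theta_p: E x K x K) score tables."""
        q, f = self._standardize(inst)
        theta_u = q @ self.unary_weights.T
        theta_p = (np.einsum("ed,kld->ekl", f, self.pairwise_full)
                   if len(f) else np.zeros((0, K_CLASSES, K_CLASSES)))
        return theta_u, theta_p


def zero_model(d_node: int, d_edge: int) -> CRFModel:
    return CRFModel(unary_weights=np.zeros((K_CLASSES, d_node)),
                    pair_weights=np.zeros((N_PAIRS, d_edge)),
                    node_mean=np.zeros(d_node), node_scale=np.ones(d_node),
                    edge_mean=np.zeros(d_edge), edge_scale=np.ones(d_edge))


def joint_feature(inst: CRFInstance, labeling: np.ndarray,
                  q: np.ndarray, f: np.ndarray) -> np.ndarray:
    """psi(x, y), flattened to match the weight vector layout."""
    y = np.asarray(labeling, dtype=np.int64) - 1
    d_node = q.shape[1]
    d_edge = f.shape[1] if f.ndim == 2 else 0
    psi_u = np.zeros((K_CLASSES, d_node))
    np.add.at(psi_u, y, q)
    psi_p = np.zeros((N_PAIRS, d_edge))
    if len(inst.edges):
        pk = np.minimum(y[inst.edges[:, 0]], y[inst.edges[:, 1]])
        pl = np.maximum(y[inst.edges[:, 0]], y[inst.edges[:, 1]])
        pidx = np.array([_pair_idx(k, l) for k, l in zip(pk, pl)])
        np.add.at(psi_p, pidx, f)
    return np.concatenate([psi_u.ravel(), psi_p.ravel()])


def _unflatten(w: np.ndarray, d_node: int, d_edge: int):
    nu = K_CLASSES * d_node
    return (w[:nu].reshape(K_CLASSES, d_node),
            w[nu:].reshape(N_PAIRS, d_edge))


def energy(model: CRFModel, inst: CRFInstance,
           labeling: Sequence[int]) -> float:
    """E(y) = -score(y) under the model's standardized features."""
    y = np.asarray(labeling, dtype=np.int64) - 1
    if len(y) != inst.n_nodes:
        raise ValueError("labeling length does not match node count")
    if y.min() < 0 or y.max() >= K_CLASSES:
        raise ValueError("labels must be class codes 1..4")
    theta_u, theta_p = model.potentials(inst)
    s = float(theta_u[np.arange(inst.n_nodes), y].sum())
    if len(inst.edges):
        s += float(theta_p[np.arange(len(inst.edges)),
                           y[inst.edges[:, 0]], y[inst.edges[:, 1]]].sum())
    return -s


def _score_tables(model, inst, loss_aug: Optional[np.ndarray] = None):
    theta_u, theta_p = model.potentials(inst)
    if loss_aug is not None:
        theta_u = theta_u + loss_aug
    return theta_u, theta_p


def _labeling_score(theta_u, theta_p, edges, y):
    s = float(theta_u[np.arange(len(y)), y].sum())
    if len(edges):
        s += float(theta_p[np.arange(len(edges)),
                           y[edges[:, 0]], y[edges[:, 1]]].sum())
    return s


def _icm(theta_u, theta_p, edges, init):
    """Greedy coordinate descent; ties go to the lowest class code."""
    y = init.copy()
    S = len(theta_u)
    # per-node incident edge lists
    inc: list = [[] for _ in range(S)]
    for e, (a, b) in enumerate(edges):
        inc[a].append((e, b, False))
        inc[b].append((e, a, True))
    for _ in range(100):
        changed = False
        for s in range(S):
            scores = theta_u[s].copy()
            for e, other, flipped in inc[s]:
                m = theta_p[e]
                scores += m[:, y[other]] if not flipped else m[y[other], :]
            best = int(np.argmax(scores))          # first max = lowest code
            if scores[best] > scores[y[s]] + 1e-12:
                if best != y[s]:
                    y[s] = best
                    changed = True
        if not changed:
            break
    return y


def _maxprod(theta_u, theta_p, edges, n_nodes, damping=0.5, n_iters=50):
    """Damped loopy max-product on the score (max-sum) semiring."""
    E = len(edges)
    if E == 0:
        return np.argmax(theta_u, axis=1)
    # messages for both directions of each edge
    msg = np.zeros((2 * E, K_CLASSES))
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    pair = np.concatenate([theta_p, np.transpose(theta_p, (0, 2, 1))])
    rev = np.concatenate([np.arange(E, 2 * E), np.arange(E)])
    for _ in range(n_iters):
        belief = theta_u.copy()
        np.add.at(belief, dst, msg)
        incoming = belief[src] - msg[rev]       # exclude reverse message
        new = np.max(incoming[:, :, None] + pair, axis=1)
        new -= new.max(axis=1, keepdims=True)   # normalize for stability
        delta = np.abs(new - msg).max()
        msg = damping * msg + (1 - damping) * new
        if delta < 1e-9:
            break
    belief = theta_u.copy()
    np.add.at(belief, dst, msg)
    return np.argmax(belief, axis=1)


def _exact(theta_u, theta_p, edges, n_nodes):
    """Chunked exhaustive maximization over K^S labelings."""
    total = K_CLASSES ** n_nodes
    best_score = -np.inf
    best = None
    chunk = 1 << 16
    powers = K_CLASSES ** np.arange(n_nodes)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total))
        labs = (idx[:, None] // powers[None, :]) % K_CLASSES
        s = theta_u[np.arange(n_nodes), labs].sum(axis=1)
        for e, (a, b) in enumerate(edges):
            s += theta_p[e, labs[:, a], labs[:, b]]
        i = int(np.argmax(s))      # first max: lowest mixed-radix index,
        if s[i] > best_score:      # i.e. lowest class codes on ties
            best_score = float(s[i])
            best = labs[i]
    return best


def map_inference(model: CRFModel, inst: CRFInstance,
                  method: str = "maxprod",
                  loss_aug: Optional[np.ndarray] = None) -> np.ndarray:
    """MAP labeling (class codes 1..4) minimizing the energy.

    ``exact`` enumerates all labelings (refused above 12 nodes);
    ``maxprod`` is damped loopy max-product followed by an ICM polish;
    ``icm`` is coordinate descent from the unary argmax.  All methods
    are deterministic; ties resolve to the lowest class code.
    """
    theta_u, theta_p = _score_tables(model, inst, loss_aug)
    if method == "exact":
        if inst.n_nodes > 12:
            raise ValueError("exact inference is limited to <= 12 nodes")
        y = _exact(theta_u, theta_p, inst.edges, inst.n_nodes)
    elif method == "maxprod":
        y0 = _maxprod(theta_u, theta_p, inst.edges, inst.n_nodes)
        y = _icm(theta_u, theta_p, inst.edges, y0)
        # loopy max-product has no optimality guarantee on cyclic
        # graphs; never return worse than plain coordinate descent
        y_icm = _icm(theta_u, theta_p, inst.edges,
                     np.argmax(theta_u, axis=1))
        if _labeling_score(theta_u, theta_p, inst.edges, y_icm) > \
                _labeling_score(theta_u, theta_p, inst.edges, y):
            y = y_icm
    elif method == "icm":
        y = _icm(theta_u, theta_p, inst.edges, np.argmax(theta_u, axis=1))
    else:
        raise ValueError(f"unknown inference method {method!r}")
    return np.asarray(y, dtype=np.int64) + 1


def _standardization(instances):
    """Scale-only standardization (unit variance, origin preserved).

    Node features (probabilities) and edge features (absolute
    differences) both have a meaningful zero: a zero edge feature means
    two identical superpixels.  Dividing by the training std conditions
    the QP while keeping that origin, so the class-pair weights can
    still express a baseline affinity at small feature values.
    """
    q_all = np.concatenate([i.node_features for i in instances])
    node_mean = np.zeros(q_all.shape[1])
    node_scale = q_all.std(axis=0)
    node_scale[node_scale < 1e-12] = 1.0
    f_all = [i.edge_features for i in instances if len(i.edge_features)]
    if f_all:
        f_all = np.concatenate(f_all)
        edge_scale = f_all.std(axis=0)
        edge_scale[edge_scale < 1e-12] = 1.0
        d_edge = f_all.shape[1]
    else:
        d_edge = instances[0].edge_features.shape[1] \
            if instances[0].edge_features.ndim == 2 else 0
        edge_scale = np.ones(d_edge)
    edge_mean = np.zeros(d_edge)
    return node_mean, node_scale, edge_mean, edge_scale


def _node_weights(inst: CRFInstance) -> np.ndarray:
    if inst.node_weights is None:
        return np.ones(inst.n_nodes)
    return np.asarray(inst.node_weights, dtype=float)


def inverse_frequency_loss_weights(instances) -> np.ndarray:
    """Per-class Hamming-loss weights = inverse gold-label frequency,
    normalized to mean 1 over the classes present.

    Node weights (when instances carry them, e.g. superpixel pixel
    counts) enter the frequencies, making the weighting pixel-level
    rather than superpixel-level.
    """
    counts = np.zeros(K_CLASSES)
    for inst in instances:
        if inst.gold is None:
            raise ValueError("all training instances need gold labels")
        nw = _node_weights(inst)
        np.add.at(counts, inst.gold - 1, nw)
    w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1e-12), 0.0)
    nz = w > 0
    if nz.any():
        w[nz] *= nz.sum() / w[nz].sum()
    return w


def _solve_qp(constraints, n_inst, dim, C, z0, w0=None):
    """min 0.5||w - w0||^2 + C sum_i xi_i
       s.t.  w . dpsi_c >= L_c - xi_inst(c).

    ``w0`` is the regularization prior mean (0 by default).  Solved in
    v = w - w0 with shifted constraint offsets, using SLSQP over
    (v, xi); exact for this convex QP at the solver's tolerance.
    """
    if not constraints:
        return ((np.zeros(dim) if w0 is None else w0.copy()),
                np.zeros(n_inst), 0.0)
    A = np.stack([c[1] for c in constraints])         # n_c x dim
    L = np.array([c[2] for c in constraints])
    if w0 is not None:
        L = L - A @ w0
    inst_of = np.array([c[0] for c in constraints])
    n_c = len(constraints)
    Einst = np.zeros((n_c, n_inst))
    Einst[np.arange(n_c), inst_of] = 1.0

    def fun(z):
        w, xi = z[:dim], z[dim:]
        return 0.5 * w @ w + C * xi.sum()

    def grad(z):
        return np.concatenate([z[:dim], np.full(n_inst, C)])

    cons = {
        "type": "ineq",
        "fun": lambda z: A @ z[:dim] + Einst @ z[dim:] - L,
        "jac": lambda z: np.hstack([A, Einst]),
    }
    bounds = [(None, None)] * dim + [(0.0, None)] * n_inst
    res = minimize(fun, z0, jac=grad, method="SLSQP", bounds=bounds,
                   constraints=[cons],
                   options={"maxiter": 500, "ftol": 1e-10})
    z = res.x
    w = z[:dim] if w0 is None else z[:dim] + w0
    return w, z[dim:], float(fun(z))


def train_ssvm(instances: Sequence[CRFInstance], C: float = 0.1,
               class_loss_weights: Optional[np.ndarray] = None,
               max_cutting_iters: int = 50, tol: float = 1e-3,
               inference: str = "maxprod",
               pairwise_shrink: float = 1.0,
               unary_prior: float = 0.0) -> CRFModel:
    """Margin-rescaled structured SVM with n-slack cutting planes.

    Each cutting-plane round runs loss-augmented MAP inference per
    instance (weighted Hamming loss added to the unary scores of wrong
    labels), adds constraints violated by more than ``tol``, and
    re-solves the accumulated QP.  The QP objective is non-decreasing as
    constraints accumulate.  Feature standardization is fitted on the
    training instances and stored in the model.

    ``pairwise_shrink`` > 1 scales down the standardized edge features,
    which under the shared ridge penalty regularizes the pairwise block
    more strongly than the unary block — rare class-pair adjacencies are
    observed on only a handful of training edges and overfit first.

    ``unary_prior`` > 0 centres the ridge penalty on "identity unary
    weights (scaled by this factor), zero pairwise" instead of the
    all-zero origin.  When the node features are the classifier's class
    probabilities, the heavily regularized limit then reproduces the
    upstream classifier's argmax labeling exactly, and the CRF departs
    from it only where the training data supports a margin violation.
    With the default 0 the classic C -> 0 behaviour (weights -> 0)
    holds.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    instances = list(instances)
    if not instances:
        raise ValueError("need at least one training instance")
    lw = (np.asarray(class_loss_weights, dtype=float)
          if class_loss_weights is not None
          else inverse_frequency_loss_weights(instances))

    nm, ns, em, es = _standardization(instances)
    es = es * float(pairwise_shrink)
    d_node = instances[0].node_features.shape[1]
    d_edge = instances[0].edge_features.shape[1]
    model = CRFModel(unary_weights=np.zeros((K_CLASSES, d_node)),
                     pair_weights=np.zeros((N_PAIRS, d_edge)),
                     node_mean=nm, node_scale=ns,
                     edge_mean=em, edge_scale=es)
    dim = K_CLASSES * d_node + N_PAIRS * d_edge
    n_inst = len(instances)

    std = [model._standardize(inst) for inst in instances]
    psis_gold = [joint_feature(inst, inst.gold, q, f)
                 for inst, (q, f) in zip(instances, std)]
    # node weights (e.g. pixel counts) normalized to mean 1 overall so
    # the scale of C is independent of superpixel granularity
    nw_all = [_node_weights(i) for i in instances]
    nw_mean = np.concatenate(nw_all).mean()
    nw_all = [w / nw_mean for w in nw_all]
    # symmetric class-weighted Hamming: mislabeling node s (true g) as k
    # costs (lw[g] + lw[k]) / 2.  Weighting by the true class alone
    # would make wrongly *claiming* a rare class nearly free, pushing
    # the learner to over-expand rare classes.
    loss_tables = []
    for inst, nw in zip(instances, nw_all):
        t = 0.5 * (lw[inst.gold - 1][:, None] + lw[None, :]) * nw[:, None]
        t[np.arange(inst.n_nodes), inst.gold - 1] = 0.0
        loss_tables.append(t)

    w0 = None
    if unary_prior > 0:
        if d_node != K_CLASSES:
            raise ValueError("unary_prior requires node features that are "
                             "class probabilities (one column per class)")
        w0 = np.concatenate([
            (unary_prior * np.eye(K_CLASSES) * ns).ravel(),
            np.zeros(N_PAIRS * d_edge)])

    constraints: list = []   # (instance index, dpsi, loss)
    w = w0.copy() if w0 is not None else np.zeros(dim)
    xi = np.zeros(n_inst)
    history: list = []
    for _ in range(max_cutting_iters):
        model.unary_weights, model.pair_weights = _unflatten(w, d_node, d_edge)
        added = 0
        for i, inst in enumerate(instances):
            y_hat = map_inference(model, inst, method=inference,
                                  loss_aug=loss_tables[i])
            loss = float(loss_tables[i][np.arange(inst.n_nodes),
                                        y_hat - 1].sum())
            q, f = std[i]
            dpsi = psis_gold[i] - joint_feature(inst, y_hat, q, f)
            if loss - w @ dpsi > xi[i] + tol:
                constraints.append((i, dpsi, loss))
                added += 1
        if added == 0:
            break
        z0 = np.concatenate([w - w0 if w0 is not None else w, xi])
        w, xi, obj = _solve_qp(constraints, n_inst, dim, C, z0, w0=w0)
        history.append(obj)
    model.unary_weights, model.pair_weights = _unflatten(w, d_node, d_edge)
    model.objective_history = history
    return model
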