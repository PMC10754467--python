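"""Competitive low-rank residual encoder-decoder for subtype inference.

Architecture, for a cell expression profile x in R^n:

* shared residual encoder: x^{j+1} = x^j + ReLU(W^j x^j + b^j), j = 0..p-1,
  giving the shared representation x^p;
* per-subtype low-rank propagation: D_k = tanh(S0_k x^p), where
  S0_k = V_k V_k^T with its diagonal zeroed (rank-r gene-gene similarity,
  self-association removed);
* shared decoder nonlinearity F_k = tanh(G D_k + e) and per-subtype affine
  reconstruction xhat_k = M_k * F_k + E_k (elementwise);
* gene weights lambda^k = |mu_k| / ||mu_k||, where mu_k is the left
  eigenvector of I - L_k with the smallest-magnitude eigenvalue and
  L_k = B_k^{-1} V_k V_k^T is the random-walk normalization of the
  similarity (B_k its degree matrix).  For rank 1 this closes to
  lambda^k = |V_k| / ||V_k||_2.

Training minimizes the mean over cells of the minimum over subtypes of the
lambda-weighted squared reconstruction error; gradients flow only through
each cell's winning branch (hard competitive assignment), and lambda is
treated as a constant within each step, recomputed from V every epoch.

Implemented in NumPy with analytic gradients (verified against finite
differences in the test suite) and an Adam optimizer; the network is
full-batch and every layer has width n, so no GPU framework is needed at
the problem sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = [
    "ModelConfig",
    "EncoderParams",
    "DecoderSharedParams",
    "SubtypeBranchParams",
    "GeneWeights",
    "SubtypeAssignment",
    "CSDGIModel",
    "init_model",
    "encoder_forward",
    "lowrank_propagate",
    "decoder_forward",
    "compute_lambda",
    "weighted_cell_loss",
    "total_loss",
    "fit",
    "assign_subtypes",
]

_DEGREE_EPS = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters of the encoder-decoder.

    n_subtypes: number of competing reconstruction branches (the subtype
        count k, chosen upstream, e.g. by the WSS elbow).
    n_res_blocks: residual blocks p in the shared encoder.
    rank: rank r of each branch's gene-similarity factor V_k (the reference
        setting is 1, for which lambda has a closed form).
    epochs / learning_rate: full-batch Adam schedule.
    lambda_detached: treat lambda as a constant within each gradient step
        (it is recomputed from V every epoch either way).
    soft_min_temperature: 0 uses the hard minimum over branches; a positive
        value blends branch losses with softmin weights instead.
    init_scale: scale of the small random init for encoder/decoder weights.
    """

    n_subtypes: int = 2
    n_res_blocks: int = 2
    rank: int = 1
    epochs: int = 400
    learning_rate: float = 1e-3
    seed: int = 0
    lambda_detached: bool = True
    soft_min_temperature: float = 0.0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_subtypes < 1:
            raise ValueError("n_subtypes must be >= 1")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_res_blocks < 1:
            raise ValueError("n_res_blocks must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class EncoderParams:
    weights: list[np.ndarray]  # p square (n, n) matrices
    biases: list[np.ndarray]  # p length-n vectors


@dataclass
class DecoderSharedParams:
    G: np.ndarray  # (n, n)
    e: np.ndarray  # (n,)


@dataclass
class SubtypeBranchParams:
    V: np.ndarray  # (n, rank)
    M: np.ndarray  # (n,) reconstruction scale
    E: np.ndarray  # (n,) reconstruction bias


@dataclass
class GeneWeights:
    """Per-subtype gene weights lam[k] = |mu[k]| normalized to unit L2."""

    lam: list[np.ndarray]
    mu: list[np.ndarray]


@dataclass
class SubtypeAssignment:
    """1-based per-cell subtype labels and the m x k weighted-loss matrix."""

    labels: np.ndarray
    losses: np.ndarray


@dataclass
class CSDGIModel:
    config: ModelConfig
    encoder: EncoderParams
    decoder: DecoderSharedParams
    branches: list[SubtypeBranchParams]
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.decoder.G.shape[0]


def init_model(cfg: ModelConfig, n: int) -> CSDGIModel:
    """Deterministic (per cfg.seed) initialization.

    Encoder weights are small-scale random with zero biases, so the encoder
    starts near the identity (the residual skip dominates).  The decoder
    matrix G starts at the identity plus small noise: the reconstruction
    net begins as a pass-through of the propagated signal, which keeps the
    gradient to each branch's V direct instead of letting a free dense
    layer absorb the gene-loading pattern.  V columns are drawn around
    1/sqrt(n) with spread 0.3/sqrt(n): the common positive offset makes the
    initial gene weights lambda^k near-uniform across branches (fair
    competition for cells — a branch with a randomly favourable weighting
    would otherwise win every cell and starve the rest), and the 1/sqrt(n)
    scale keeps the propagation tanh in its active range so V remains
    trainable.  M starts at ones, E at zeros.
    """
    if n < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(cfg.seed)
    s = cfg.init_scale
    enc = EncoderParams(
        weights=[rng.normal(0.0, s, (n, n)) for _ in range(cfg.n_res_blocks)],
        biases=[np.zeros(n) for _ in range(cfg.n_res_blocks)],
    )
    dec = DecoderSharedParams(G=np.eye(n) + rng.normal(0.0, s, (n, n)), e=np.zeros(n))
    sqrt_n = float(np.sqrt(n))
    branches = []
    for _ in range(cfg.n_subtypes):
        V = rng.normal(1.0 / sqrt_n, 0.3 / sqrt_n, (n, cfg.rank))
        while np.any(np.all(V == 0.0, axis=0)):  # pragma: no cover
            V = rng.normal(1.0 / sqrt_n, 0.3 / sqrt_n, (n, cfg.rank))
        branches.append(SubtypeBranchParams(V=V, M=np.ones(n), E=np.zeros(n)))
    return CSDGIModel(cfg, enc, dec, branches)


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def encoder_forward(x: np.ndarray, enc: EncoderParams) -> np.ndarray:
    """x^p = x + sum_j ReLU(W^j x^j + b^j); accepts (n,) or (m, n)."""
    out = np.atleast_2d(np.asarray(x, dtype=float))
    for W, b in zip(enc.weights, enc.biases):
        out = out + _relu(out @ W.T + b)
    return out[0] if np.ndim(x) == 1 else out

def _zero_diag_similarity(V: np.ndarray) -> np.ndarray:
    S = V @ V.T
    np.fill_diagonal(S, 0.0)
    return S


def lowrank_propagate(xp: np.ndarray, branch: SubtypeBranchParams) -> np.ndarray:
    """D = tanh(S0 xp): propagate through the zero-diagonal similarity."""
    S0 = _zero_diag_similarity(branch.V)
    return np.tanh(np.asarray(xp, dtype=float) @ S0)  # S0 symmetric


def decoder_forward(
    D: np.ndarray, dec: DecoderSharedParams, branch: SubtypeBranchParams
) -> np.ndarray:
    """xhat = M * tanh(G D + e) + E (elementwise scale and bias)."""
    F = np.tanh(np.asarray(D, dtype=float) @ dec.G.T + dec.e)
    return branch.M * F + branch.E


def _guard_degrees(deg: np.ndarray) -> np.ndarray:
    out = deg.copy()
    tiny = np.abs(out) < _DEGREE_EPS
    out[tiny] = np.where(out[tiny] >= 0, _DEGREE_EPS, -_DEGREE_EPS)
    return out


def compute_lambda(branch: SubtypeBranchParams) -> tuple[np.ndarray, np.ndarray]:
    """Gene weights (lam, mu) from the branch's low-rank graph.

    Builds the random-walk matrix L = B^{-1} V V^T (B the degree matrix of
    V V^T, with tiny degrees guarded) and takes mu as the left eigenvector
    of I - L with the smallest-magnitude eigenvalue — the direction that
    carries the rank-r structure rather than one of the degenerate
    eigenvalue-1 directions.  lam = |mu| scaled to unit Euclidean norm.

    For rank 1, L has identical rows V^T / sum(V), so mu is proportional to
    V and lam = |V| / ||V||_2 exactly; that closed form is used directly.
    """
    V = branch.V
    n, r = V.shape
    if r == 1:
        v = V[:, 0]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("V is all-zero; re-initialize the model")
        return np.abs(v) / norm, v / norm
    S = V @ V.T
    deg = _guard_degrees(S.sum(axis=1))
    L = S / deg[:, None]
    M = np.eye(n) - L
    eigvals, left = np.linalg.eig(M.T)  # columns: left eigenvectors of M
    idx = int(np.argmin(np.abs(eigvals)))
    mu = np.real(left[:, idx])
    norm = np.linalg.norm(mu)
    if norm < 1e-300 or not np.all(np.isfinite(mu)):
        raise ValueError("degenerate eigenvector; re-initialize the model")
    mu = mu / norm
    return np.abs(mu), mu


def gene_weights(model: CSDGIModel) -> GeneWeights:
    lams, mus = [], []
    for branch in model.branches:
        lam, mu = compute_lambda(branch)
        lams.append(lam)
        mus.append(mu)
    return GeneWeights(lam=lams, mu=mus)


def weighted_cell_loss(x: np.ndarray, xhat: np.ndarray, lam: np.ndarray) -> float:
    """sum_g (lam_g * (x_g - xhat_g))^2."""
    diff = (np.asarray(x, float) - np.asarray(xhat, float)) * np.asarray(lam, float)
    return float(diff @ diff)


def _forward_all(model: CSDGIModel, X: np.ndarray):
    """Forward pass for all cells and branches; returns intermediates."""
    xp = encoder_forward(X, model.encoder)
    per_branch = []
    for branch in model.branches:
        S0 = _zero_diag_similarity(branch.V)
        preD = xp @ S0
        D = np.tanh(preD)
        preF = D @ model.decoder.G.T + model.decoder.e
        F = np.tanh(preF)
        xhat = branch.M * F + branch.E
        per_branch.append({"S0": S0, "D": D, "F": F, "xhat": xhat})
    return xp, per_branch


def _loss_matrix(X: np.ndarray, per_branch, weights: GeneWeights) -> np.ndarray:
    m = X.shape[0]
    losses = np.empty((m, len(per_branch)))
    for k, fb in enumerate(per_branch):
        resid = (X - fb["xhat"]) * weights.lam[k]
        losses[:, k] = np.einsum("ij,ij->i", resid, resid)
    return losses


def total_loss(
    X: ExpressionMatrix | np.ndarray,
    model: CSDGIModel,
    weights: GeneWeights | None = None,
) -> tuple[float, SubtypeAssignment]:
    """Mean over cells of the min-over-branches weighted loss, plus the
    induced assignment (argmin, ties to the lowest subtype index)."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    weights = weights or gene_weights(model)
    _, per_branch = _forward_all(model, V)
    losses = _loss_matrix(V, per_branch, weights)
    labels = np.argmin(losses, axis=1) + 1  # argmin takes the first minimum
    return float(losses.min(axis=1).mean()), SubtypeAssignment(labels, losses)


def assign_subtypes(
    model: CSDGIModel,
    X: ExpressionMatrix | np.ndarray,
    weights: GeneWeights | None = None,
) -> SubtypeAssignment:
    return total_loss(X, model, weights)[1]


def _adam_update(param, grad, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    m, v = state
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad**2
    mhat = m / (1 - beta1**t)
    vhat = v / (1 - beta2**t)
    param -= lr * mhat / (np.sqrt(vhat) + eps)


def _backward(model: CSDGIModel, X: np.ndarray, weights: GeneWeights):
    """Analytic gradients of the competitive loss w.r.t. every parameter.

    Only each cell's winning branch receives gradient (hard minimum);
    lambda is held constant.  Returns (loss, assignment, grads dict).
    """
    m, n = X.shape
    cfg = model.config
    enc, dec = model.encoder, model.decoder
    p = len(enc.weights)

    # encoder forward, keeping per-block inputs and pre-activations
    xs = [X]
    zs = []
    out = X
    for W, b in zip(enc.weights, enc.biases):
        z = out @ W.T + b
        zs.append(z)
        out = out + _relu(z)
        xs.append(out)
    xp = out

    per_branch = []
    for branch in model.branches:
        S0 = _zero_diag_similarity(branch.V)
        preD = xp @ S0
        D = np.tanh(preD)
        preF = D @ dec.G.T + dec.e
        F = np.tanh(preF)
        xhat = branch.M * F + branch.E
        per_branch.append({"S0": S0, "D": D, "F": F, "xhat": xhat})

    losses = _loss_matrix(X, per_branch, weights)
    labels = np.argmin(losses, axis=1) + 1
    tau = cfg.soft_min_temperature
    if tau > 0:
        # smooth minimum -tau*logsumexp(-l/tau); its gradient w.r.t. the
        # per-branch losses is exactly the softmin responsibility matrix
        shift = losses.min(axis=1, keepdims=True)
        expo = np.exp(-(losses - shift) / tau)
        w = expo / expo.sum(axis=1, keepdims=True)
        loss = float(
            (shift[:, 0] - tau * np.log(expo.sum(axis=1) / 1.0)).mean()
        )
    else:
        w = np.zeros_like(losses)
        w[np.arange(m), labels - 1] = 1.0
        loss = float(losses.min(axis=1).mean())

    grads = {
        "W": [np.zeros_like(Wj) for Wj in enc.weights],
        "b": [np.zeros_like(bj) for bj in enc.biases],
        "G": np.zeros_like(dec.G),
        "e": np.zeros_like(dec.e),
        "V": [np.zeros_like(br.V) for br in model.branches],
        "M": [np.zeros_like(br.M) for br in model.branches],
        "E": [np.zeros_like(br.E) for br in model.branches],
    }
    # responsibilities enter the loss linearly per cell; with the hard min
    # (or detached softmin weights) d loss / d xhat_k[i] = -2 w[i,k] lam^2 r / m
    dxp = np.zeros_like(xp)
    for k, (branch, fb) in enumerate(zip(model.branches, per_branch)):
        lam2 = weights.lam[k] ** 2
        resid = X - fb["xhat"]
        dxhat = (-2.0 / m) * w[:, [k]] * lam2 * resid
        grads["E"][k] = dxhat.sum(axis=0)
        grads["M"][k] = (dxhat * fb["F"]).sum(axis=0)
        dF = dxhat * branch.M
        dpreF = dF * (1.0 - fb["F"] ** 2)
        grads["G"] += dpreF.T @ fb["D"]
        grads["e"] += dpreF.sum(axis=0)
        dD = dpreF @ dec.G
        dpreD = dD * (1.0 - fb["D"] ** 2)
        dS0 = dpreD.T @ xp
        np.fill_diagonal(dS0, 0.0)  # S0's diagonal is clamped to zero
        grads["V"][k] = (dS0 + dS0.T) @ branch.V
        dxp += dpreD @ fb["S0"]

    dX = dxp
    for j in range(p - 1, -1, -1):
        dZ = dX * (zs[j] > 0)
        grads["W"][j] = dZ.T @ xs[j]
        grads["b"][j] = dZ.sum(axis=0)
        dX = dX + dZ @ enc.weights[j]
    return loss, SubtypeAssignment(labels, losses), grads


def fit(
    X: ExpressionMatrix | np.ndarray,
    cfg: ModelConfig | None = None,
) -> tuple[CSDGIModel, GeneWeights, SubtypeAssignment, list[float]]:
    """Train by full-batch Adam for cfg.epochs epochs.

    lambda is recomputed from the current V at the start of every epoch and
    held fixed within the gradient step.  Deterministic given cfg.seed.
    Aborts with a diagnostic if the loss becomes non-finite.
    """
    cfg = cfg or ModelConfig()
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    m, n = V.shape
    if m < cfg.n_subtypes:
        raise ValueError(f"{cfg.n_subtypes} subtypes but only {m} cells")
    model = init_model(cfg, n)

    params = (
        model.encoder.weights
        + model.encoder.biases
        + [model.decoder.G, model.decoder.e]
        + [br.V for br in model.branches]
        + [br.M for br in model.branches]
        + [br.E for br in model.branches]
    )
    adam_state = [(np.zeros_like(q), np.zeros_like(q)) for q in params]
    trace: list[float] = []
    assignment = None
    for epoch in range(1, cfg.epochs + 1):
        weights = gene_weights(model)
        loss, assignment, grads = _backward(model, V, weights)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; lower the learning rate"
            )
        trace.append(loss)
        flat_grads = (
            grads["W"] + grads["b"] + [grads["G"], grads["e"]]
            + grads["V"] + grads["M"] + grads["E"]
        )
        for q, g, st in zip(params, flat_grads, adam_state):
            _adam_update(q, g, st, cfg.learning_rate, epoch)

    weights = gene_weights(model)
    _, assignment = total_loss(V, model, weights)
    model.loss_trace = trace
    return model, weights, assignment, trace
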