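"""Invariant-information clustering core: network, loss, training.

A sequence's normalized FCGR vector x and the FCGR x~ of one of its mimics
are mapped by a shared multilayer perceptron Phi to probability vectors
over c clusters.  Training maximizes a weighted mutual information between
the paired predictions, i.e. minimizes

    L = -lambda * H(Phi(x)) + H(Phi(x) | Phi(x~))

where the joint distribution of the two cluster variables is estimated
per batch as the symmetrized average outer product of the paired outputs.
The marginal-entropy term (weight lambda) fights the degenerate solution
that dumps every sequence into one cluster; the conditional-entropy term
demands that a sequence be predictable from its mimic.

The network is Linear(4^k -> 512) -> ReLU -> Dropout(0.5)
-> Linear(512 -> 64) -> ReLU -> Dropout(0.5) -> Linear(64 -> c) -> Softmax,
Kaiming-initialized and trained with Adam.  Everything — forward pass,
analytic loss gradient, backpropagation, the optimizer — is implemented
on NumPy arrays, which keeps the method CPU-only and fully reproducible
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence as TypingSequence

import numpy as np

from .mimics import TrainingPair, pairs_as_arrays

_EPS = 1e-12  # clamp below this before taking logs

HIDDEN_SIZES = (512, 64)
DROPOUT_RATE = 0.5


def input_scale(input_dim: int) -> float:
    """Scale factor applied to L1-normalized FCGR vectors at the network entry.

    An L1-normalized 4^k vector has entries of order 4^-k, which starves the
    Kaiming-initialized first layer (its variance analysis assumes order-one
    inputs) and leaves the optimizer stuck at the uniform-output saddle where
    the mutual-information signal vanishes.  Multiplying by the number of
    cells re-expresses each frequency relative to the uniform composition
    (mean entry 1) without changing the L1-normalization contract of the
    stored vectors.
    """
    return float(input_dim)


@dataclass
class Hyperparameters:
    """Training configuration; defaults follow the published recipe."""

    c: int = 2
    k: int = 6
    m: int = 3
    p_ts: float = 1e-4
    p_tv: float = 0.5e-4
    lam: float = 2.5
    learning_rate: float = 5e-5
    epochs: int = 150
    batch_size: int = 512
    noise_period_epochs: int = 50
    noise_sigma: float = 0.01
    voters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("c must be >= 2")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.voters < 1:
            raise ValueError("rates and counts must be positive")


@dataclass
class NetworkParams:
    """Weights and biases of the three linear layers."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def c(self) -> int:
        return self.weights[-1].shape[1]

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])


@dataclass
class JointDistribution:
    P: np.ndarray
    row_marginal: np.ndarray
    col_marginal: np.ndarray


@dataclass
class LossBreakdown:
    marginal_entropy: float
    conditional_entropy: float
    loss: float


@dataclass
class ClusterAssignment:
    ids: list[str]
    probabilities: np.ndarray  # n x c, rows on the simplex
    hard_labels: np.ndarray  # argmax per row, lowest index on ties


def init_network(c: int, input_dim: int, seed: int) -> NetworkParams:
    """Kaiming (fan-in, ReLU gain) normal initialization, zero biases."""
    rng = np.random.default_rng(seed)
    sizes = (input_dim, *HIDDEN_SIZES, c)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        std = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)).astype(np.float32))
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return NetworkParams(weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    params: NetworkParams,
    batch: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Forward pass; dropout (inverted scaling) only in train mode.

    Returns the n x c matrix of cluster probabilities, plus the layer
    cache when ``return_cache`` is set (needed for backpropagation).
    """
    x = np.asarray(batch, dtype=np.float32)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != params.input_dim:
        raise ValueError(f"input dim {x.shape[1]} != network dim {params.input_dim}")
    if train_mode and rng is None:
        raise ValueError("train_mode forward needs an rng for dropout")

    cache = {"inputs": [], "relu_masks": [], "drop_masks": []}
    h = x
    for layer in range(2):
        cache["inputs"].append(h)
        z = h @ params.weights[layer] + params.biases[layer]
        mask = z > 0
        h = np.where(mask, z, 0.0)
        cache["relu_masks"].append(mask)
        if train_mode:
            keep = (rng.random(h.shape) >= DROPOUT_RATE).astype(np.float32)
            h = h * keep / (1.0 - DROPOUT_RATE)
            cache["drop_masks"].append(keep)
        else:
            cache["drop_masks"].append(None)
    cache["inputs"].append(h)
    logits = h @ params.weights[2] + params.biases[2]
    probs = _softmax(logits.astype(np.float64))
    if return_cache:
        cache["probs"] = probs
        return probs, cache
    return probs


def joint_distribution(probs_x: np.ndarray, probs_xt: np.ndarray) -> JointDistribution:
    """Batch estimate of the joint cluster distribution, symmetrized."""
    px = np.asarray(probs_x, dtype=np.float64)
    pxt = np.asarray(probs_xt, dtype=np.float64)
    if px.shape != pxt.shape:
        raise ValueError("paired batches must have identical shapes")
    b = px.shape[0]
    P = px.T @ pxt / b
    P = (P + P.T) / 2.0
    return JointDistribution(P=P, row_marginal=P.sum(axis=1), col_marginal=P.sum(axis=0))


def iic_loss(joint: JointDistribution, lam: float) -> LossBreakdown:
    """L = -lambda * H(marginal) + H(conditional), natural-log entropies."""
    P = np.maximum(joint.P, _EPS)
    p = np.maximum(joint.row_marginal, _EPS)
    q = np.maximum(joint.col_marginal, _EPS)
    h_marg = float(-(p * np.log(p)).sum())
    h_cond = float(-(joint.P * (np.log(P) - np.log(q)[None, :])).sum())
    return LossBreakdown(
        marginal_entropy=h_marg,
        conditional_entropy=h_cond,
        loss=-lam * h_marg + h_cond,
    )


def _loss_and_grads(probs_x: np.ndarray, probs_xt: np.ndarray, lam: float):
    """Loss plus analytic gradients w.r.t. both probability batches.

    With A = (1/B) Phi_x^T Phi_xt and P = (A + A^T)/2, the derivative of the
    loss w.r.t. P_ab is lambda*(ln p_a + 1) - ln P_ab + ln q_b (the +1 terms
    from the marginal cancel against the normalization of P, but P's total
    is exactly 1 here so the constant shifts nothing after symmetrization).
    """
    b = probs_x.shape[0]
    joint = joint_distribution(probs_x, probs_xt)
    breakdown = iic_loss(joint, lam)

    P = np.maximum(joint.P, _EPS)
    p = np.maximum(joint.row_marginal, _EPS)
    q = np.maximum(joint.col_marginal, _EPS)
    G = lam * (np.log(p)[:, None] + 1.0) - np.log(P) + np.log(q)[None, :]
    dA = (G + G.T) / 2.0
    d_px = probs_xt @ dA.T / b
    d_pxt = probs_x @ dA / b
    return breakdown, d_px, d_pxt


def _backward(params: NetworkParams, cache: dict, d_probs: np.ndarray):
    """Backpropagate a gradient w.r.t. the softmax output through the MLP."""
    probs = cache["probs"]
    # softmax Jacobian-vector product
    dz = (probs * (d_probs - (d_probs * probs).sum(axis=1, keepdims=True))).astype(np.float32)
    grads_w = [None, None, None]
    grads_b = [None, None, None]
    grads_w[2] = cache["inputs"][2].T @ dz
    grads_b[2] = dz.sum(axis=0)
    dh = dz @ params.weights[2].T
    for layer in (1, 0):
        keep = cache["drop_masks"][layer]
        if keep is not None:
            dh = dh * keep / (1.0 - DROPOUT_RATE)
        dh = dh * cache["relu_masks"][layer]
        grads_w[layer] = cache["inputs"][layer].T @ dh
        grads_b[layer] = dh.sum(axis=0)
        if layer:
            dh = dh @ params.weights[layer].T
    return grads_w, grads_b


class _Adam:
    """Adam with conventional moment defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: NetworkParams, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(a) for a in params.weights + params.biases]
        self.v = [np.zeros_like(a) for a in params.weights + params.biases]

    def step(self, params: NetworkParams, grads_w, grads_b) -> None:
        self.t += 1
        arrays = params.weights + params.biases
        grads = list(grads_w) + list(grads_b)
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            a -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def perturb_parameters(
    params: NetworkParams, sigma: float, rng: np.random.Generator
) -> NetworkParams:
    """Add i.i.d. Normal(0, sigma^2) noise to every weight and bias."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return params.copy()
    out = params.copy()
    for arr in out.weights + out.biases:
        arr += rng.normal(0.0, sigma, size=arr.shape).astype(arr.dtype)
    return out


def _make_batches(n: int, batch_size: int, c: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled batches; a final short batch with < c samples is merged into
    the previous one, since the batch marginal needs at least c samples."""
    perm = rng.permutation(n)
    batches = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and len(batches[-1]) < c:
        tail = batches.pop()
        batches[-1] = np.concatenate([batches[-1], tail])
    return batches


def train_single(
    pairs: TypingSequence[TrainingPair] | tuple[np.ndarray, np.ndarray],
    hp: Hyperparameters,
    seed: int,
) -> tuple[NetworkParams, list[LossBreakdown]]:
    """Train one network on FCGR pairs; returns parameters and per-epoch loss.

    Adam minimizes the invariant-information loss over shuffled batches for
    ``hp.epochs`` epochs with no early stopping; Gaussian parameter noise is
    injected at the end of every ``hp.noise_period_epochs``-th epoch except
    the last.  Fully reproducible given ``seed``.
    """
    if isinstance(pairs, tuple):
        x, xt = pairs
    else:
        if len(pairs) == 0:
            raise ValueError("empty pair list")
        x, xt = pairs_as_arrays(list(pairs))
    if x.shape[0] == 0:
        raise ValueError("empty pair list")
    scale = input_scale(x.shape[1])
    x = np.ascontiguousarray(x * scale, dtype=np.float32)
    xt = np.ascontiguousarray(xt * scale, dtype=np.float32)
    n = x.shape[0]

    ss = np.random.SeedSequence(seed)
    init_ss, shuffle_ss, drop_ss, noise_ss = ss.spawn(4)
    params = init_network(hp.c, x.shape[1], int(init_ss.generate_state(1)[0] % (2**31)))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    drop_rng = np.random.default_rng(drop_ss)
    noise_rng = np.random.default_rng(noise_ss)

    opt = _Adam(params, hp.learning_rate)
    history: list[LossBreakdown] = []
    for epoch in range(1, hp.epochs + 1):
        sums = np.zeros(3)
        batches = _make_batches(n, hp.batch_size, hp.c, shuffle_rng)
        for idx in batches:
            probs_x, cache_x = forward(params, x[idx], train_mode=True, rng=drop_rng, return_cache=True)
            probs_xt, cache_xt = forward(params, xt[idx], train_mode=True, rng=drop_rng, return_cache=True)
            breakdown, d_px, d_pxt = _loss_and_grads(probs_x, probs_xt, hp.lam)
            gw_x, gb_x = _backward(params, cache_x, d_px)
            gw_xt, gb_xt = _backward(params, cache_xt, d_pxt)
            gw = [a + b for a, b in zip(gw_x, gw_xt)]
            gb = [a + b for a, b in zip(gb_x, gb_xt)]
            opt.step(params, gw, gb)
            sums += (breakdown.marginal_entropy, breakdown.conditional_entropy, breakdown.loss)
        k = len(batches)
        history.append(LossBreakdown(sums[0] / k, sums[1] / k, sums[2] / k))
        if (
            hp.noise_period_epochs > 0
            and epoch % hp.noise_period_epochs == 0
            and epoch != hp.epochs
        ):
            params = perturb_parameters(params, hp.noise_sigma, noise_rng)
    return params, history


def assign_clusters(
    params: NetworkParams,
    fcgrs: np.ndarray,
    ids: list[str] | None = None,
) -> ClusterAssignment:
    """Eval-mode forward pass on the original sequences' FCGRs.

    Hard labels are the per-row argmax with ties broken toward the lowest
    cluster index.
    """
    fcgrs = np.asarray(fcgrs)
    if fcgrs.ndim == 1:
        fcgrs = fcgrs[None, :]
    probs = forward(params, fcgrs * input_scale(fcgrs.shape[1]), train_mode=False)
    labels = probs.argmax(axis=1)
    if ids is None:
        ids = [str(i) for i in range(probs.shape[0])]
    return ClusterAssignment(ids=list(ids), probabilities=probs, hard_labels=labels)
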