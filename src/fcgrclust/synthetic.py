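"""Synthetic labelled DNA datasets with cluster-specific genomic signatures.

Each cluster is a Markov chain over {A,C,G,T} (order 1 by default).  A
base transition matrix T0 is drawn with Dirichlet(1,1,1,1) rows, and
cluster c receives T_c = (1 - delta) * T0 + delta * T'_c with T'_c an
independent draw, so a single knob delta in [0, 1] moves the benchmark
from indistinguishable clusters (delta = 0, chance-level clustering is
the correct outcome) to fully independent compositional signatures
(delta = 1).  Because the FCGR grid is exactly the k-mer composition,
Markov sources guarantee the kind of separability the genomic-signature
hypothesis posits for real taxa, without pretending to model mutation,
indels, or phylogeny.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .sequence_io import LabelledDataset, Sequence, write_fasta, write_labels


@dataclass(frozen=True)
class SignatureModel:
    """Order-r Markov source for one cluster; rows of `transition` are
    next-base distributions conditioned on the preceding r-mer context."""

    order: int
    transition: np.ndarray  # 4^order x 4, row-stochastic
    cluster_id: int


@dataclass(frozen=True)
class SyntheticSpec:
    c: int = 4
    n_per_cluster: int = 150
    length_range: tuple[int, int] = (5000, 10000)
    delta: float = 0.8
    order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 2 or self.n_per_cluster < 1:
            raise ValueError("need c >= 2 and n_per_cluster >= 1")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if not (1 <= self.order <= 3):
            raise ValueError("order must be in 1..3")
        lo, hi = self.length_range
        if lo > hi or lo < self.order + 1:
            raise ValueError("length_range must satisfy order + 1 <= L_min <= L_max")


def _model_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0]))


def _sample_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1]))


def make_signature_models(spec: SyntheticSpec) -> list[SignatureModel]:
    """Draw the per-cluster transition matrices (see module docstring)."""
    rng = _model_rng(spec.seed)
    n_ctx = 4 ** spec.order
    t0 = rng.dirichlet(np.ones(4), size=n_ctx)
    models = []
    for cluster in range(spec.c):
        tc = rng.dirichlet(np.ones(4), size=n_ctx)
        blend = (1.0 - spec.delta) * t0 + spec.delta * tc
        models.append(SignatureModel(order=spec.order, transition=blend, cluster_id=cluster))
    return models


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def sample_sequences(models: list[SignatureModel], spec: SyntheticSpec) -> LabelledDataset:
    """Sample n_per_cluster sequences per model; lengths uniform in range.

    The initial order-mer is uniform; every subsequent base is drawn from
    the model row of the preceding context.  Sampling is vectorized across
    the sequences of a cluster (one position of all sequences per step).
    """
    rng = _sample_rng(spec.seed)
    lo, hi = spec.length_range
    order = spec.order
    n_ctx = 4 ** order
    sequences: list[Sequence] = []
    labels: dict[str, str] = {}
    for model in models:
        cum = np.cumsum(model.transition, axis=1)
        n = spec.n_per_cluster
        lengths = rng.integers(lo, hi + 1, size=n)
        max_len = int(lengths.max())
        ctx = rng.integers(0, n_ctx, size=n)
        out = np.empty((n, max_len), dtype=np.int64)
        # spell out the initial context digits, most significant first
        for pos in range(order):
            shift = 4 ** (order - 1 - pos)
            out[:, pos] = (ctx // shift) % 4
        for pos in range(order, max_len):
            u = rng.random(n)
            nxt = (u[:, None] > cum[ctx]).sum(axis=1)
            out[:, pos] = nxt
            ctx = (ctx * 4 + nxt) % n_ctx
        for i in range(n):
            seq_id = f"c{model.cluster_id}_s{i}"
            sequences.append(Sequence(id=seq_id, residues=_decode(out[i, : lengths[i]])))
            labels[seq_id] = f"taxon_{model.cluster_id}"
    return LabelledDataset(
        sequences,
        labels=labels,
        provenance=f"synthetic Markov signatures (c={spec.c}, delta={spec.delta}, seed={spec.seed})",
    )


def _stationary(model: SignatureModel, tol: float = 1e-12, max_iter: int = 10000) -> np.ndarray:
    """Stationary distribution of the context chain by power iteration."""
    n_ctx = 4 ** model.order
    # context transition: ctx -> (ctx*4 + b) mod n_ctx with prob transition[ctx, b]
    pi = np.full(n_ctx, 1.0 / n_ctx)
    for _ in range(max_iter):
        nxt = np.zeros(n_ctx)
        for b in range(4):
            targets = (np.arange(n_ctx) * 4 + b) % n_ctx
            np.add.at(nxt, targets, pi * model.transition[:, b])
        if np.abs(nxt - pi).sum() < tol:
            return nxt
        pi = nxt
    raise ValueError("non-ergodic transition matrix: stationary distribution did not converge")


def expected_kmer_frequencies(model: SignatureModel, k: int) -> np.ndarray:
    """Analytic length-4^k vector of stationary k-mer probabilities."""
    order = model.order
    pi = _stationary(model)
    if k <= order:
        # contexts are contiguous order-mers; marginalize the trailing bases
        return pi.reshape(4 ** k, 4 ** (order - k)).sum(axis=1)
    probs = pi
    n_ctx = 4 ** order
    for _ in range(k - order):
        m = probs.size
        ctx = np.arange(m) % n_ctx
        probs = (probs[:, None] * model.transition[ctx]).reshape(m * 4)
    return probs


def signature_separation(models: list[SignatureModel], k: int) -> np.ndarray:
    """Pairwise L1 distances between the models' expected k-mer spectra."""
    if len(models) < 2:
        raise ValueError("need at least two models")
    freqs = [expected_kmer_frequencies(m, k) for m in models]
    c = len(models)
    dist = np.zeros((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            d = float(np.abs(freqs[i] - freqs[j]).sum())
            dist[i, j] = dist[j, i] = d
    return dist


def write_dataset(dataset: LabelledDataset, spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write FASTA + labels TSV + spec JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "sequences.fasta"
    labels = out / "labels.tsv"
    spec_json = out / "spec.json"
    write_fasta(dataset, fasta)
    assert dataset.labels is not None
    write_labels(dataset.labels, labels)
    spec_json.write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return {"fasta": str(fasta), "labels": str(labels), "spec": str(spec_json)}
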