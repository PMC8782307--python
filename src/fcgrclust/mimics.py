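"""Mimic sequences: near-copies made by random transition/transversion
substitutions, used to build the training pairs for mutual-information
clustering.

The substitution model is a mathematical device, not a biological one:
each position independently mutates with a small probability, either to
its transition partner (A<->G, C<->T) or to one of its two transversion
partners, producing sequences minimally different from the original that
should therefore share its cluster.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .fcgr import fcgr_vector
from .sequence_io import Sequence

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MODES = ("transitions", "transversions", "both")


@dataclass(frozen=True)
class MimicParams:
    """Number of mimics per sequence and per-position substitution rates."""

    m: int = 3
    p_ts: float = 1e-4
    p_tv: float = 0.5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 3:
            raise ValueError("m must be >= 3 (transitions, transversions, and both)")
        if not (0.0 <= self.p_ts <= 1.0 and 0.0 <= self.p_tv <= 1.0):
            raise ValueError("substitution probabilities must lie in [0, 1]")


@dataclass
class MimicSet:
    original_id: str
    mimics: list[tuple[Sequence, str]]  # (sequence, mode)


@dataclass
class TrainingPair:
    """Normalized flattened FCGRs of an original sequence and one mimic."""

    x: np.ndarray
    x_tilde: np.ndarray
    original_id: str


def _substream(seed: int, seq_id: str, mimic_index: int) -> np.random.Generator:
    # Keyed by (seed, id, index) so adding sequences leaves existing mimics
    # unchanged; crc32 gives a stable integer for the id.
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(seq_id.encode()), mimic_index])
    )


def substitute(
    seq: Sequence,
    mode: str,
    p_ts: float,
    p_tv: float,
    rng: np.random.Generator,
) -> Sequence:
    """Apply per-position random substitutions of the requested mode.

    ``transitions``: with probability ``p_ts`` a base is swapped with its
    purine/pyrimidine partner.  ``transversions``: with probability ``p_tv``
    a base becomes one of its two cross-class partners, chosen uniformly.
    ``both`` applies the transition draw first, then an independent
    transversion draw on the (possibly updated) base.  Positions holding
    ambiguity codes are never substituted; length is preserved.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    chars = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[chars]
    mutable = codes >= 0
    codes = np.where(mutable, codes, 0)
    n = len(chars)

    if mode in ("transitions", "both"):
        hit = (rng.random(n) < p_ts) & mutable
        # transition partner: A(0)<->G(2), C(1)<->T(3) — XOR with 2.
        codes = np.where(hit, codes ^ 2, codes)
    if mode in ("transversions", "both"):
        hit = (rng.random(n) < p_tv) & mutable
        pick = rng.integers(0, 2, size=n)
        # the two transversion partners of code b are (b+1)%4 and (b+3)%4
        codes = np.where(hit, (codes + 1 + 2 * pick) % 4, codes)

    out = np.where(mutable, _BASES[codes], chars)
    return Sequence(id=seq.id, residues=out.tobytes().decode("ascii"))


def mimic_modes(m: int) -> list[str]:
    """Mode of each mimic: one transitions, one transversions, rest both."""
    return ["transitions", "transversions"] + ["both"] * (m - 2)


def generate_mimics(seq: Sequence, params: MimicParams) -> MimicSet:
    """Produce the m mimics of one sequence, each from its own RNG stream."""
    mimics: list[tuple[Sequence, str]] = []
    for j, mode in enumerate(mimic_modes(params.m), start=1):
        rng = _substream(params.seed, seq.id, j)
        mutant = substitute(seq, mode, params.p_ts, params.p_tv, rng)
        mimics.append((Sequence(id=f"{seq.id}|mimic{j}|{mode}", residues=mutant.residues), mode))
    return MimicSet(original_id=seq.id, mimics=mimics)


def build_training_pairs(
    sequences: list[Sequence],
    params: MimicParams,
    k: int,
) -> list[TrainingPair]:
    """m pairs (FCGR(original), FCGR(mimic_j)) per sequence, L1-normalized."""
    pairs: list[TrainingPair] = []
    for seq in sequences:
        x = fcgr_vector(seq, k)
        for mimic, _mode in generate_mimics(seq, params).mimics:
            pairs.append(TrainingPair(x=x, x_tilde=fcgr_vector(mimic, k), original_id=seq.id))
    return pairs


def pairs_as_arrays(pairs: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (N, 4^k) arrays for batched training."""
    x = np.stack([p.x for p in pairs])
    xt = np.stack([p.x_tilde for p in pairs])
    return x, xt


def write_mimic_fasta(mimic_sets: list[MimicSet], path) -> None:
    """Audit export; headers are '<original_id>|mimic<j>|<mode>'."""
    from .sequence_io import write_fasta

    seqs = [seq for ms in mimic_sets for seq, _mode in ms.mimics]
    write_fasta(seqs, path)
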