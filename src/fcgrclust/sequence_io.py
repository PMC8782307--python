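"""Reading, validating and assembling DNA sequence datasets.

Sequences are plain uppercase nucleotide strings.  True taxonomic labels,
when available, live in a side table that is consulted only by the
evaluation code path: every training-facing function in this package
accepts bare sequences, so labels can never leak into the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Unambiguous DNA alphabet.
ACGT = frozenset("ACGT")

#: IUPAC nucleotide codes accepted under the tolerant cleaning policy.
#: k-mer counting skips any window containing a non-ACGT code.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class Sequence:
    """An identified DNA sequence."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class LabelledDataset:
    """A set of sequences plus an optional id -> taxon table (evaluation only)."""

    sequences: list[Sequence]
    labels: dict[str, str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate id in dataset")

    def __len__(self) -> int:
        return len(self.sequences)

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def label_list(self) -> list[str]:
        """Labels in sequence order; requires a complete label table."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        missing = [s.id for s in self.sequences if s.id not in self.labels]
        if missing:
            raise ValueError(f"missing label for ids: {missing[:5]}")
        return [self.labels[s.id] for s in self.sequences]


def read_fasta(path: str | Path, labels_path: str | Path | None = None) -> LabelledDataset:
    """Read a multi-record FASTA file (wrapped lines allowed).

    The record id is the first whitespace-delimited token of the header and
    residues are uppercased.  Raises ``ValueError`` on an empty file, an
    empty record, or duplicate ids.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    seen: set[str] = set()
    sequences: list[Sequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        if not residues:
            raise ValueError(f"empty record {rec.id}")
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        sequences.append(Sequence(id=rec.id, residues=residues))
    labels = read_labels(labels_path) if labels_path is not None else None
    return LabelledDataset(sequences, labels=labels, provenance=str(path))


def write_fasta(dataset: LabelledDataset | Iterable[Sequence], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA with fixed line wrapping."""
    seqs = dataset.sequences if isinstance(dataset, LabelledDataset) else list(dataset)
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column id<TAB>taxon file (no header)."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        seq_id, taxon = parts[0].strip(), parts[1].strip()
        if seq_id in labels:
            raise ValueError(f"{path}:{lineno}: duplicate id {seq_id}")
        labels[seq_id] = taxon
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, taxon in labels.items():
            fh.write(f"{seq_id}\t{taxon}\n")


def clean_sequence(seq: Sequence, policy: str = "tolerant") -> Sequence:
    """Uppercase and validate residues.

    ``strict`` admits only A/C/G/T; ``tolerant`` additionally retains IUPAC
    ambiguity codes (they are skipped later during k-mer counting).  Any
    other character is an error, reported with its 1-based position.
    """
    if policy not in ("strict", "tolerant"):
        raise ValueError(f"unknown policy {policy!r}")
    if not seq.residues:
        raise ValueError(f"empty record {seq.id}")
    residues = seq.residues.upper()
    allowed = ACGT if policy == "strict" else IUPAC_CODES
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise ValueError(
                f"disallowed character {ch!r} at position {pos} in sequence {seq.id!r}"
            )
    return Sequence(id=seq.id, residues=residues)


def balance_clusters(
    dataset: LabelledDataset,
    min_required: int = 20,
    max_excess_fraction: float = 0.2,
    seed: int = 0,
) -> LabelledDataset:
    """Discard undersized clusters and subsample the rest for balance.

    The *test minimum* is the size of the smallest cluster with at least
    ``min_required`` members.  Clusters below the test minimum are dropped,
    and every remaining cluster is randomly subsampled (without replacement)
    to at most ``floor((1 + max_excess_fraction) * test_minimum)`` members,
    so that no cluster exceeds the smallest by more than the stated excess.
    Sequences lacking a label are excluded up front.
    """
    if dataset.labels is None:
        raise ValueError("balance_clusters requires labels")
    if min_required < 1:
        raise ValueError("min_required must be >= 1")

    by_cluster: dict[str, list[Sequence]] = {}
    for s in dataset.sequences:
        taxon = dataset.labels.get(s.id)
        if taxon is None:
            continue
        by_cluster.setdefault(taxon, []).append(s)

    viable = {t: members for t, members in by_cluster.items() if len(members) >= min_required}
    if not viable:
        raise ValueError("no viable clusters")
    test_minimum = min(len(m) for m in viable.values())
    cap = int(np.floor((1.0 + max_excess_fraction) * test_minimum))

    rng = np.random.default_rng(seed)
    kept: list[Sequence] = []
    labels: dict[str, str] = {}
    for taxon in sorted(viable):
        members = viable[taxon]
        if len(members) > cap:
            idx = rng.choice(len(members), size=cap, replace=False)
            members = [members[i] for i in sorted(idx)]
        for s in members:
            kept.append(s)
            labels[s.id] = taxon
    return LabelledDataset(kept, labels=labels, provenance=dataset.provenance + " [balanced]")


def write_manifest(dataset: LabelledDataset, path: str | Path) -> None:
    """Write a TSV manifest: id, length, label (empty if unlabelled)."""
    with open(path, "w") as fh:
        fh.write("id\tlength\tlabel\n")
        for s in dataset.sequences:
            label = "" if dataset.labels is None else dataset.labels.get(s.id, "")
            fh.write(f"{s.id}\t{s.length}\t{label}\n")
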