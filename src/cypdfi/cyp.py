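"""The CYP450 isoenzyme panel.

The model conditions on a fixed panel of five cytochrome P450 isoenzymes
(CYP1A2, CYP3A4, CYP2C19, CYP2C9, CYP2D6 — the isoenzymes with the densest
substrate/inhibition annotation coverage), each represented by a single
480-dimensional embedding of its amino-acid sequence.  In production those
embeddings come from a protein language model (one vector per isoenzyme,
mean-pooled over residues); this module treats them as an injected input so
the package runs fully offline:

* :meth:`CypPanel.from_embedding_table` loads a precomputed 5x480 table
  (e.g. exported from a protein language model elsewhere);
* :meth:`CypPanel.from_fasta` reads the five sequences and featurizes them
  with a deterministic sequence-hash embedding — a synthetic stand-in with
  the right shape and per-isoenzyme distinctness, not a learned embedding;
* :meth:`CypPanel.synthetic` draws a seeded random table for tests and
  benchmarks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

ISOENZYMES: tuple[str, ...] = ("CYP1A2", "CYP3A4", "CYP2C19", "CYP2C9", "CYP2D6")
INTERACTION_TYPES: tuple[str, str] = ("substrate", "inhibition")
EMBEDDING_DIM = 480

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "ISOENZYMES",
    "INTERACTION_TYPES",
    "EMBEDDING_DIM",
    "CypPanel",
    "sequence_hash_embedding",
]


def sequence_hash_embedding(sequence: str, dim: int = EMBEDDING_DIM) -> np.ndarray:
    """Deterministic synthetic embedding of an amino-acid sequence.

    Seeds a PCG64 stream from the SHA-256 of the sequence and draws a
    standard-normal vector.  Distinct sequences map to (almost surely)
    distinct vectors; identical sequences always map to the same vector.
    """
    digest = hashlib.sha256(sequence.encode("ascii")).digest()
    seed = int.from_bytes(digest[:8], "big") % (2**31)
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.standard_normal(dim)


@dataclass(frozen=True)
class CypPanel:
    """Five isoenzymes in canonical order with their 480-dim embeddings."""

    embeddings: np.ndarray  # (5, 480)
    sequences: tuple[str, ...] | None = None

    def __post_init__(self):
        emb = np.asarray(self.embeddings, dtype=np.float64)
        if emb.shape != (len(ISOENZYMES), EMBEDDING_DIM):
            raise ValueError(
                f"panel embeddings must have shape {(len(ISOENZYMES), EMBEDDING_DIM)}, got {emb.shape}"
            )
        object.__setattr__(self, "embeddings", emb)
        if self.sequences is not None:
            if len(self.sequences) != len(ISOENZYMES):
                raise ValueError("panel needs exactly five sequences")
            for seq in self.sequences:
                bad = set(seq.upper()) - _AA_ALPHABET
                if bad:
                    raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")

    @classmethod
    def from_embedding_table(cls, path) -> "CypPanel":
        """Load a whitespace/tab-delimited table: isoenzyme name + 480 reals per row."""
        rows: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                rows[parts[0]] = np.asarray([float(v) for v in parts[1:]], dtype=np.float64)
        missing = [iso for iso in ISOENZYMES if iso not in rows]
        if missing:
            raise ValueError(f"embedding table missing isoenzymes: {missing}")
        emb = np.stack([rows[iso] for iso in ISOENZYMES])
        if emb.shape[1] != EMBEDDING_DIM:
            raise ValueError(f"embeddings must be {EMBEDDING_DIM}-dimensional, got {emb.shape[1]}")
        return cls(embeddings=emb)

    def to_embedding_table(self, path) -> None:
        with open(path, "w") as fh:
            for iso, row in zip(ISOENZYMES, self.embeddings):
                fh.write(iso + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_fasta(cls, path) -> "CypPanel":
        """Read the five sequences from FASTA (record ids must contain the
        isoenzyme names) and featurize them with the sequence-hash embedding."""
        seqs: dict[str, str] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            for iso in ISOENZYMES:
                if iso.lower() in record.id.lower() or iso.lower() in record.description.lower():
                    seqs[iso] = str(record.seq).upper()
        missing = [iso for iso in ISOENZYMES if iso not in seqs]
        if missing:
            raise ValueError(f"FASTA missing isoenzymes: {missing}")
        ordered = tuple(seqs[iso] for iso in ISOENZYMES)
        emb = np.stack([sequence_hash_embedding(s) for s in ordered])
        return cls(embeddings=emb, sequences=ordered)

    @classmethod
    def synthetic(cls, seed: int = 0) -> "CypPanel":
        """Seeded random panel for tests and synthetic benchmarks."""
        rng = np.random.Generator(np.random.PCG64(seed))
        return cls(embeddings=rng.standard_normal((len(ISOENZYMES), EMBEDDING_DIM)))
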