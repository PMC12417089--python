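"""Protein-embedding ingestion and pooling.

Per-residue embedding matrices produced externally by protein language
models (ProtT5-XL-U50, ProteinBERT, Ankh, the ESM C family) are mean-pooled
along the sequence axis into one global vector per protein, then averaged
over the three structural nitrogenase proteins of a sample. Model inference
itself is out of scope; matrices arrive as numeric tables. A deterministic
pseudo-embedding backend is provided so the full pipeline is testable
without any external model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import AminoAcidSequence, logger

#: Expected embedding widths per declared source; unknown sources accept any.
KNOWN_SOURCE_WIDTHS: dict[str, int] = {
    "ProtT5": 1024,
    "ProteinBERT": 512,
    "Ankh": 1536,
    "ESMC_300M": 960,
    "ESMC_600M": 1152,
    "ESMC_6B": 2560,
}


@dataclass(frozen=True)
class ResidueEmbeddingMatrix:
    """L x D matrix of per-residue embedding rows with a source tag."""

    values: np.ndarray
    source: str = "pseudo"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError(f"expected an L x D matrix with L >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding matrix contains non-finite entries")
        expected = KNOWN_SOURCE_WIDTHS.get(self.source)
        if expected is not None and v.shape[1] != expected:
            raise ValueError(
                f"source {self.source} declares width {expected}, matrix has {v.shape[1]}"
            )
        object.__setattr__(self, "values", v)


def mean_pool(matrix: ResidueEmbeddingMatrix) -> np.ndarray:
    """Column-wise mean over residues: one global vector per protein."""
    return matrix.values.mean(axis=0)


def aggregate_sample_embedding(
    pooled: dict[str, np.ndarray], permissive: bool = False
) -> np.ndarray:
    """Element-wise mean of the three pooled per-gene vectors; width preserved."""
    from .protein import aggregate_protein_block

    return aggregate_protein_block(pooled, permissive=permissive)


def pseudo_embedding(
    seq: AminoAcidSequence, width: int = 16, seed: int = 0
) -> ResidueEmbeddingMatrix:
    """Deterministic stand-in embedding derived from residue identity.

    Row i is a seeded hash of (residue i, a coarse position window), mapped
    to [-1, 1]; identical (seq, width, seed) triples reproduce bit-exactly,
    and sequences sharing residues in similar positions get correlated rows.
    Purely synthetic: carries no learned biology.
    """
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    rows = np.empty((len(seq), width))
    for i, aa in enumerate(seq.residues):
        window = i // 25  # coarse position bucket keeps near-identical seqs correlated
        digest = hashlib.sha256(f"{seed}:{aa}:{window}".encode()).digest()
        row_rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        rows[i] = row_rng.uniform(-1.0, 1.0, size=width)
    return ResidueEmbeddingMatrix(rows, source="pseudo")


def write_embedding_table(path: str | Path, table: dict[str, np.ndarray]) -> None:
    """Write a sample-level (or gene-level) embedding TSV: id + D columns."""
    widths = {np.asarray(v).shape[0] for v in table.values()}
    if len(widths) > 1:
        raise ValueError(f"inconsistent embedding widths {widths}")
    (width,) = widths
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(f"e{i}" for i in range(width)) + "\n")
        for sid, vec in table.items():
            fh.write(sid + "\t" + "\t".join(f"{x:.10g}" for x in np.asarray(vec)) + "\n")


def load_embedding_table(
    path: str | Path, known_ids: set[str] | None = None
) -> dict[str, np.ndarray]:
    """Load an embedding TSV into id -> vector.

    Ids may be sample-level (``sampleID``) or gene-level (``sampleID|gene``);
    gene-level tables should be pooled/aggregated by the caller. Ragged rows
    are an error; ids absent from ``known_ids`` trigger a warning only.
    """
    table: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"embedding table {path}: no numeric columns")
        width = len(header) - 1
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != width + 1:
                raise ValueError(
                    f"embedding table {path}:{lineno}: expected {width + 1} fields, "
                    f"got {len(fields)}"
                )
            sid = fields[0]
            if known_ids is not None and sid.split("|")[0] not in known_ids:
                logger.warning("embedding table %s: unknown id %r", path, sid)
            table[sid] = np.array([float(x) for x in fields[1:]])
    if not table:
        raise ValueError(f"embedding table {path} is empty")
    return table
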