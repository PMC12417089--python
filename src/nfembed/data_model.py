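"""Core domain types, manifest/FASTA ingestion, labels and dataset splits.

The unit of analysis is one diazotrophic strain: the three structural
nitrogenase proteins (NifH, NifD, NifK), coding sequences for eight
expression-related nif genes, gene coordinates, copy counts for 34
nitrogen-fixation-associated genes, and a measured nitrogenase activity
in nmol C2H4/mg protein/hour.

Labels: a strain is "high activity" (class 1) when its activity strictly
exceeds a threshold (default 50 nmol C2H4/mg protein/hour). The regression
target is y = log10(x + 2), which compresses the heavy right tail of
activity values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("nfembed")

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Structural genes of molybdenum nitrogenase.
STRUCTURAL_GENES: tuple[str, ...] = ("nifH", "nifD", "nifK")

#: Genes whose coding sequences feed the codon-usage expression block.
EXPRESSION_GENES: tuple[str, ...] = (
    "nifA", "nifB", "nifD", "nifE", "nifH", "nifK", "nifN", "nifX",
)

#: Canonical order of the 34 genes counted in the copy-number block.
COPY_NUMBER_GENES: tuple[str, ...] = (
    "nifD", "nifH", "nifK", "amtB", "fixA", "fixB", "fixC", "fixX",
    "glnK", "glnA", "nifA", "nifB", "nifE", "nifF", "nifJ", "nifL",
    "nifM", "nifN", "nifP", "nifQ", "nifS", "nifT", "nifU", "nifV",
    "nifW", "nifX", "nifY", "nifZ", "rnfA", "rnfB", "rnfC", "rnfD",
    "rnfE", "rnfG",
)

#: Default activity threshold separating low/high activity strains.
DEFAULT_ACTIVITY_THRESHOLD: float = 50.0

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def clean_protein(residues: str, policy: str = "reject") -> str:
    """Apply the ambiguity policy to a raw protein string.

    ``policy='reject'`` raises on any residue outside the 20-letter
    alphabet; ``policy='drop'`` removes such residues with a warning.
    """
    residues = residues.strip().upper()
    bad = [c for c in residues if c not in AMINO_ACIDS]
    if not bad:
        return residues
    if policy == "drop":
        logger.warning("dropping %d ambiguous residue(s): %s", len(bad), sorted(set(bad)))
        return "".join(c for c in residues if c in AMINO_ACIDS)
    raise ValueError(f"non-canonical residue(s) {sorted(set(bad))} in protein sequence")


@dataclass(frozen=True)
class AminoAcidSequence:
    """A protein sequence over the 20 canonical one-letter codes."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty protein sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residue(s) {sorted(bad)}; apply clean_protein first")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence:
    """A DNA coding sequence: length divisible by 3, no internal stop codon.

    A terminal stop codon is permitted and is excluded from codon counting.
    """

    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty coding sequence")
        bad = set(self.bases) - set("ACGT")
        if bad:
            raise ValueError(f"invalid base(s) {sorted(bad)} in coding sequence")
        if len(self.bases) % 3 != 0:
            raise ValueError(f"CDS length {len(self.bases)} not divisible by 3")
        for i in range(0, len(self.bases) - 3, 3):
            if self.bases[i:i + 3] in _STOP_CODONS:
                raise ValueError(f"internal stop codon at position {i + 1}")

    @property
    def codons(self) -> list[str]:
        """Codons with a terminal stop, if present, stripped."""
        cods = [self.bases[i:i + 3] for i in range(0, len(self.bases), 3)]
        if cods and cods[-1] in _STOP_CODONS:
            cods = cods[:-1]
        return cods

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GeneCoordinate:
    """1-based inclusive genomic coordinates of a gene (GenBank convention)."""

    replicon_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class NifSample:
    """One strain: proteins, coding sequences, coordinates, copy counts, activity."""

    sample_id: str
    proteins: dict[str, AminoAcidSequence]
    cds: dict[str, CodingSequence]
    coordinates: dict[str, GeneCoordinate]
    copy_numbers: dict[str, int]
    activity: float | None = None

    def __post_init__(self) -> None:
        missing = [g for g in STRUCTURAL_GENES if g not in self.proteins]
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing protein(s) {missing}")
        if set(self.copy_numbers) != set(COPY_NUMBER_GENES):
            extra = set(self.copy_numbers) - set(COPY_NUMBER_GENES)
            absent = set(COPY_NUMBER_GENES) - set(self.copy_numbers)
            raise ValueError(
                f"sample {self.sample_id}: copy_numbers keys must be the canonical "
                f"34-gene list (extra={sorted(extra)}, absent={sorted(absent)})"
            )
        if any(v < 0 for v in self.copy_numbers.values()):
            raise ValueError(f"sample {self.sample_id}: negative copy number")
        if self.activity is not None and self.activity < 0:
            raise ValueError(f"sample {self.sample_id}: negative activity {self.activity}")


def binarize_activity(x: float, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> int:
    """Class label for an activity value: 1 iff strictly above the threshold."""
    if x < 0:
        raise ValueError(f"negative activity {x}")
    return int(x > threshold)


def transform_activity(x: float) -> float:
    """Log-scale regression target y = log10(x + 2)."""
    if x < -2:
        raise ValueError(f"activity {x} below -2; log transform undefined")
    return math.log10(x + 2.0)


def inverse_transform_activity(y: float) -> float:
    """Inverse of :func:`transform_activity`: x = 10**y - 2."""
    return 10.0 ** y - 2.0


@dataclass
class LabeledDataset:
    """An ordered collection of samples with binary labels and log targets."""

    samples: list[NifSample]
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD
    binary_labels: np.ndarray = field(init=False)
    regression_targets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        missing = [s.sample_id for s in self.samples if s.activity is None]
        if missing:
            raise ValueError(f"samples without activity cannot be labeled: {missing[:5]}")
        acts = np.array([s.activity for s in self.samples], dtype=float)
        self.binary_labels = (acts > self.threshold).astype(int)
        self.regression_targets = np.log10(acts + 2.0)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def activities(self) -> np.ndarray:
        return np.array([s.activity for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices], threshold=self.threshold)


@dataclass(frozen=True)
class SplitSpec:
    """How to split a dataset: fraction to the first partition, stratified or not."""

    fraction: float
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")


def stratified_split_indices(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Index-level split: per-class ``floor(fraction * n_class)`` to partition A.

    Remainders go to partition B, which reproduces e.g. 167/154 vs 42/39 from
    a 209-negative / 193-positive dataset at fraction 0.8. Membership within a
    class is a seeded permutation, so the split is reproducible.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    a_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    if spec.stratified:
        classes = np.unique(labels)
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            n_a = int(math.floor(spec.fraction * len(idx)))
            if n_a == 0 or n_a == len(idx):
                raise ValueError(
                    f"class {cls} would leave an empty partition "
                    f"(n={len(idx)}, fraction={spec.fraction})"
                )
            perm = rng.permutation(idx)
            a_parts.append(perm[:n_a])
            b_parts.append(perm[n_a:])
    else:
        idx = np.arange(len(labels))
        n_a = int(math.floor(spec.fraction * len(idx)))
        if n_a == 0 or n_a == len(idx):
            raise ValueError("split would leave an empty partition")
        perm = rng.permutation(idx)
        a_parts.append(perm[:n_a])
        b_parts.append(perm[n_a:])
    part_a = np.sort(np.concatenate(a_parts))
    part_b = np.sort(np.concatenate(b_parts))
    return part_a, part_b


def stratified_split(
    dataset: LabeledDataset, spec: SplitSpec
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split a labeled dataset into two disjoint, exhaustive partitions."""
    labels = dataset.binary_labels if spec.stratified else np.zeros(len(dataset), dtype=int)
    idx_a, idx_b = stratified_split_indices(labels, spec)
    return dataset.subset(idx_a), dataset.subset(idx_b)


# ---------------------------------------------------------------------------
# Manifest and FASTA ingestion
#
# Manifest: TSV with header sample_id, activity, protein_fasta, cds_fasta,
# coords_tsv, copy_numbers (34 comma-separated integers in canonical order).
# FASTA record ids are "sampleID|gene". Coordinates: TSV with columns
# sample_id, gene, replicon, start, end, strand.
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "sample_id", "activity", "protein_fasta", "cds_fasta", "coords_tsv", "copy_numbers",
)


def _read_fasta_map(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _read_coords(path: Path) -> dict[tuple[str, str], GeneCoordinate]:
    coords: dict[tuple[str, str], GeneCoordinate] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "gene", "replicon", "start", "end", "strand"]
        if header != expected:
            raise ValueError(f"coordinates file {path}: header {header} != {expected}")
        for line in fh:
            sid, gene, rep, start, end, strand = line.rstrip("\n").split("\t")
            coords[(sid, gene)] = GeneCoordinate(rep, int(start), int(end), strand)
    return coords


def read_manifest(path: str | Path, ambiguity_policy: str = "reject") -> list[NifSample]:
    """Read a sample manifest and its referenced FASTA/coordinate files.

    Returns one :class:`NifSample` per manifest row, in row order. Relative
    file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    base = path.parent
    samples: list[NifSample] = []
    seen: set[str] = set()
    fasta_cache: dict[Path, dict[str, str]] = {}
    coords_cache: dict[Path, dict[tuple[str, str], GeneCoordinate]] = {}

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing_cols = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing_cols:
            raise ValueError(f"manifest {path}: missing column(s) {missing_cols}")
        col = {c: header.index(c) for c in MANIFEST_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sid = fields[col["sample_id"]]
            if sid in seen:
                raise ValueError(f"manifest {path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)

            act_str = fields[col["activity"]]
            activity = float(act_str) if act_str not in ("", "NA") else None

            prot_path = base / fields[col["protein_fasta"]]
            cds_path = base / fields[col["cds_fasta"]]
            coords_path = base / fields[col["coords_tsv"]]
            for p, cache, reader in (
                (prot_path, fasta_cache, _read_fasta_map),
                (cds_path, fasta_cache, _read_fasta_map),
                (coords_path, coords_cache, _read_coords),
            ):
                if p not in cache:
                    if not p.exists():
                        raise FileNotFoundError(f"manifest {path}:{lineno}: {p} does not exist")
                    cache[p] = reader(p)

            prot_map = fasta_cache[prot_path]
            proteins = {}
            for gene in STRUCTURAL_GENES:
                key = f"{sid}|{gene}"
                if key not in prot_map:
                    raise ValueError(
                        f"sample {sid}: protein FASTA record {key!r} absent from {prot_path}"
                    )
                proteins[gene] = AminoAcidSequence(clean_protein(prot_map[key], ambiguity_policy))

            cds_map = fasta_cache[cds_path]
            cds = {}
            for gene in EXPRESSION_GENES:
                key = f"{sid}|{gene}"
                if key in cds_map:
                    cds[gene] = CodingSequence(cds_map[key])

            coords_map = coords_cache[coords_path]
            coordinates = {
                gene: coords_map[(sid, gene)]
                for gene in STRUCTURAL_GENES
                if (sid, gene) in coords_map
            }

            counts = [int(v) for v in fields[col["copy_numbers"]].split(",")]
            if len(counts) != len(COPY_NUMBER_GENES):
                raise ValueError(
                    f"sample {sid}: expected {len(COPY_NUMBER_GENES)} copy counts, "
                    f"got {len(counts)}"
                )
            copy_numbers = dict(zip(COPY_NUMBER_GENES, counts))

            samples.append(
                NifSample(
                    sample_id=sid,
                    proteins=proteins,
                    cds=cds,
                    coordinates=coordinates,
                    copy_numbers=copy_numbers,
                    activity=activity,
                )
            )
    return samples
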