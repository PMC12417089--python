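"""Sequence-level protein descriptors: conjoint triad, dipeptide composition,
pseudo-amino-acid composition, and the per-sample average over NifH/D/K.

Conjoint triad (CT) groups the 20 amino acids into 7 classes by side-chain
dipole moment and volume, then counts class triplets in a sliding window of
width 3; dipeptide composition (DPC) counts ordered residue pairs; PAAC
augments plain amino-acid composition with lagged physicochemical
correlation factors (hydrophobicity, hydrophilicity, side-chain mass),
giving 20 composition components plus ``lambda`` pseudo-components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AMINO_ACIDS, AminoAcidSequence

# Conjoint-triad classes after dipole/volume clustering. Class indices 1..7.
CONJOINT_TRIAD_CLASSES: dict[int, str] = {
    1: "AGV",
    2: "ILFP",
    3: "YMTS",
    4: "HNQW",
    5: "RK",
    6: "DE",
    7: "C",
}


def build_class_map(classes: dict[int, str] | None = None) -> dict[str, int]:
    """Residue -> class index map; validates full coverage and 7 classes."""
    classes = classes if classes is not None else CONJOINT_TRIAD_CLASSES
    mapping: dict[str, int] = {}
    for idx, members in classes.items():
        if not members:
            raise ValueError(f"class {idx} is empty")
        for aa in members:
            if aa in mapping:
                raise ValueError(f"residue {aa} assigned to two classes")
            mapping[aa] = idx
    if set(mapping) != set(AMINO_ACIDS):
        raise ValueError("class map must cover exactly the 20 canonical amino acids")
    if len(classes) != 7:
        raise ValueError(f"expected 7 classes, got {len(classes)}")
    return mapping


_DEFAULT_CLASS_MAP = build_class_map()

# Classical PAAC property tables (hydrophobicity, hydrophilicity,
# side-chain mass), standardized over the 20 amino acids before use.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardize(table: dict[str, float]) -> np.ndarray:
    vals = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
    return (vals - vals.mean()) / vals.std()


@dataclass(frozen=True)
class PaacConfig:
    """PAAC parameters: lag depth ``lam``, pseudo-component weight ``weight``."""

    lam: int = 30
    weight: float = 0.05
    properties: tuple[np.ndarray, ...] = field(
        default_factory=lambda: (
            _standardize(_HYDROPHOBICITY),
            _standardize(_HYDROPHILICITY),
            _standardize(_SIDE_CHAIN_MASS),
        )
    )

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_ct(
    seq: AminoAcidSequence,
    class_map: dict[str, int] | None = None,
    rescale: bool = False,
) -> np.ndarray:
    """343-dim conjoint-triad vector: relative frequency of class triplets.

    Entry (a, b, c), flattened a-major, is the count of consecutive residue
    triplets classed (a, b, c) divided by L-2. ``rescale=True`` applies the
    original min-max rescaling of the counts instead.
    """
    class_map = class_map if class_map is not None else _DEFAULT_CLASS_MAP
    s = seq.residues
    if len(s) < 3:
        raise ValueError(f"sequence length {len(s)} < 3; no triplets")
    counts = np.zeros((7, 7, 7), dtype=float)
    cls = [class_map[c] - 1 for c in s]
    for i in range(len(s) - 2):
        counts[cls[i], cls[i + 1], cls[i + 2]] += 1
    flat = counts.ravel()
    if rescale:
        lo, hi = flat.min(), flat.max()
        return (flat - lo) / (hi - lo) if hi > lo else np.zeros(343)
    return flat / (len(s) - 2)


def encode_dpc(seq: AminoAcidSequence) -> np.ndarray:
    """400-dim dipeptide composition: count of ordered pair (a, b) / (L-1).

    Amino acids in alphabetical one-letter order, row-major flatten.
    """
    s = seq.residues
    if len(s) < 2:
        raise ValueError(f"sequence length {len(s)} < 2; no dipeptides")
    counts = np.zeros((20, 20), dtype=float)
    for i in range(len(s) - 1):
        counts[_AA_INDEX[s[i]], _AA_INDEX[s[i + 1]]] += 1
    return counts.ravel() / (len(s) - 1)


def encode_paac(seq: AminoAcidSequence, cfg: PaacConfig | None = None) -> np.ndarray:
    """(20 + lambda)-dim pseudo-amino-acid composition (50 by default).

    Components 1..20 are the damped amino-acid frequencies
    f_i / (sum f + w * sum tau); components 21..20+lambda are
    w * tau_j / (sum f + w * sum tau), where tau_j averages the
    three-property squared-difference correlation at lag j.
    """
    cfg = cfg if cfg is not None else PaacConfig()
    s = seq.residues
    L = len(s)
    if L <= cfg.lam:
        raise ValueError(f"sequence length {L} must exceed lambda={cfg.lam}")

    idx = np.array([_AA_INDEX[c] for c in s])
    props = np.stack(cfg.properties)  # (3, 20)
    prof = props[:, idx]  # (3, L)

    tau = np.empty(cfg.lam)
    for j in range(1, cfg.lam + 1):
        diff = prof[:, j:] - prof[:, :-j]  # (3, L-j)
        tau[j - 1] = np.mean(np.mean(diff**2, axis=0))

    freqs = np.bincount(idx, minlength=20).astype(float) / L
    denom = freqs.sum() + cfg.weight * tau.sum()
    return np.concatenate([freqs, cfg.weight * tau]) / denom


def aggregate_protein_block(
    vectors: dict[str, np.ndarray], permissive: bool = False
) -> np.ndarray:
    """Element-wise mean of the per-gene descriptor vectors (NifH, NifD, NifK).

    In permissive mode missing genes are skipped with a warning; by default
    all three must be present.
    """
    from .data_model import STRUCTURAL_GENES, logger

    present = [g for g in STRUCTURAL_GENES if g in vectors and vectors[g] is not None]
    missing = [g for g in STRUCTURAL_GENES if g not in present]
    if missing:
        if not permissive:
            raise ValueError(f"missing descriptor vector(s) for {missing}")
        if not present:
            raise ValueError("no descriptor vectors available")
        logger.warning("averaging over %s only; missing %s", present, missing)
    arrs = [np.asarray(vectors[g], dtype=float) for g in present]
    widths = {a.shape for a in arrs}
    if len(widths) > 1:
        raise ValueError(f"mismatched vector shapes {widths}")
    return np.mean(arrs, axis=0)
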