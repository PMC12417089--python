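"""Codon-usage statistics over coding sequences.

Implements relative synonymous codon usage (RSCU) over the 61 sense codons,
the Euclidean distance of an RSCU vector from neutral usage (all values 1),
the codon adaptation index (CAI), the frequency of optimal codons (Fop),
a within-family codon-bias statistic E, and the 24-dimensional expression
block (CAI, E, Fop for each of the eight nif expression genes).

The E statistic used here is the family-share-weighted mean absolute
deviation of within-family codon frequencies from uniform usage; it is 0
exactly when every used multi-codon family is used uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .data_model import EXPRESSION_GENES, CodingSequence, NifSample, logger

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]

#: The 61 sense codons, lexicographic over A<C<G<T (standard genetic code).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: Codon -> encoded amino acid (one-letter), sense codons only.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: Amino acid -> tuple of synonymous codons, lexicographic order.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    SYNONYMOUS_FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_SINGLETON_AAS = frozenset(aa for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) == 1)

MIN_CAI_WEIGHT = 1e-4


def _codon_counts(cds: CodingSequence) -> np.ndarray:
    counts = np.zeros(61, dtype=float)
    for cod in cds.codons:
        counts[_CODON_INDEX[cod]] += 1
    return counts


def compute_rscu(cds: CodingSequence, fill: float = 0.0) -> np.ndarray:
    """61-dim RSCU vector aligned to :data:`SENSE_CODONS`.

    For a codon in a family of size n_f whose family total is N_f > 0,
    RSCU = count * n_f / N_f; codons of unobserved families take ``fill``
    (0 by default; 1 treats them as neutral).
    """
    counts = _codon_counts(cds)
    rscu = np.full(61, fill, dtype=float)
    for fam in SYNONYMOUS_FAMILIES.values():
        idx = [_CODON_INDEX[c] for c in fam]
        total = counts[idx].sum()
        if total > 0:
            rscu[idx] = counts[idx] * len(fam) / total
    return rscu


def euclidean_codon_distance(rscu: np.ndarray) -> float:
    """Distance of an RSCU vector from the neutral reference (all ones)."""
    rscu = np.asarray(rscu, dtype=float)
    if rscu.shape != (61,):
        raise ValueError(f"expected a 61-length RSCU vector, got shape {rscu.shape}")
    return float(np.sqrt(np.sum((rscu - 1.0) ** 2)))


@dataclass(frozen=True)
class ReferenceUsage:
    """Relative adaptiveness weights from a highly-expressed reference gene set.

    ``weights[c]`` = reference RSCU of codon c divided by the family maximum,
    so every family's best codon has weight 1. ``optimal`` maps each amino
    acid to its family's preferred codon.
    """

    weights: dict[str, float]
    optimal: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.weights) != set(SENSE_CODONS):
            raise ValueError("weights must cover exactly the 61 sense codons")
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            fam_max = max(self.weights[c] for c in fam)
            if not np.isclose(fam_max, 1.0):
                raise ValueError(f"family {aa}: max weight {fam_max} != 1")

    @classmethod
    def from_genes(cls, genes: list[CodingSequence]) -> "ReferenceUsage":
        """Derive weights from pooled codon counts of a reference gene set."""
        counts = np.zeros(61, dtype=float)
        for g in genes:
            counts += _codon_counts(g)
        weights: dict[str, float] = {}
        optimal: dict[str, str] = {}
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            fam_counts = np.array([counts[_CODON_INDEX[c]] for c in fam])
            fam_max = fam_counts.max()
            if fam_max == 0:
                # unobserved family: treat all members as equally adapted
                fam_counts = np.ones(len(fam))
                fam_max = 1.0
            for c, n in zip(fam, fam_counts):
                weights[c] = max(n / fam_max, MIN_CAI_WEIGHT)
            optimal[aa] = fam[int(np.argmax(fam_counts))]
        return cls(weights=weights, optimal=optimal)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceUsage":
        """Load a codon -> weight table (TSV, columns codon, weight)."""
        weights: dict[str, float] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["codon", "weight"]:
                raise ValueError(f"reference usage {path}: header {header}")
            for line in fh:
                codon, w = line.rstrip("\n").split("\t")
                weights[codon] = max(float(w), MIN_CAI_WEIGHT)
        optimal = {
            aa: max(fam, key=lambda c: weights[c])
            for aa, fam in SYNONYMOUS_FAMILIES.items()
        }
        return cls(weights=weights, optimal=optimal)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tweight\n")
            for c in SENSE_CODONS:
                fh.write(f"{c}\t{self.weights[c]:.6g}\n")


def default_reference_usage() -> ReferenceUsage:
    """A documented synthetic default reference, built deterministically.

    Emulates a highly-expressed gene set by drawing 40 genes of 300 codons
    whose families prefer their lexicographically first codon; real analyses
    should supply an organism-specific reference table instead.
    """
    rng = np.random.default_rng(20240614)
    aas = [aa for aa in SYNONYMOUS_FAMILIES]
    genes = []
    for _ in range(40):
        codons = []
        for aa in rng.choice(aas, size=300):
            fam = SYNONYMOUS_FAMILIES[str(aa)]
            if len(fam) == 1 or rng.random() < 0.6:
                codons.append(fam[0])
            else:
                codons.append(fam[1 + int(rng.integers(len(fam) - 1))])
        genes.append(CodingSequence("".join(codons)))
    return ReferenceUsage.from_genes(genes)


def _eligible_codons(cds: CodingSequence) -> list[str]:
    """Codons belonging to multi-codon families (Met/Trp excluded)."""
    return [c for c in cds.codons if CODON_TO_AA[c] not in _SINGLETON_AAS]


def compute_cai(cds: CodingSequence, ref: ReferenceUsage) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness weights.

    Codons of singleton families (Met, Trp) are excluded; weights are floored
    at 1e-4 so an unused reference codon cannot zero the product.
    """
    eligible = _eligible_codons(cds)
    if not eligible:
        raise ValueError("no codons from multi-codon families; CAI undefined")
    logs = [np.log(max(ref.weights[c], MIN_CAI_WEIGHT)) for c in eligible]
    return float(np.exp(np.mean(logs)))


def compute_fop(cds: CodingSequence, ref: ReferenceUsage) -> float:
    """Frequency of optimal codons among codons of multi-codon families."""
    eligible = _eligible_codons(cds)
    if not eligible:
        raise ValueError("no codons from multi-codon families; Fop undefined")
    n_opt = sum(1 for c in eligible if c == ref.optimal[CODON_TO_AA[c]])
    return n_opt / len(eligible)


def compute_bias_E(cds: CodingSequence) -> float:
    """Within-family codon bias: deviation of family usage from uniform.

    E = sum over used multi-codon families a of p_a * sum_{c in a}
    |q_{c|a} - 1/n_a|, with p_a the family's share of eligible codons and
    q_{c|a} the within-family frequency. Invariant to gene length at fixed
    within-family proportions.
    """
    eligible = _eligible_codons(cds)
    if not eligible:
        raise ValueError("no codons from multi-codon families; E undefined")
    counts = _codon_counts(cds)
    n_eligible = len(eligible)
    e_val = 0.0
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        if aa in _SINGLETON_AAS:
            continue
        idx = [_CODON_INDEX[c] for c in fam]
        fam_total = counts[idx].sum()
        if fam_total == 0:
            continue
        q = counts[idx] / fam_total
        p_a = fam_total / n_eligible
        e_val += p_a * np.abs(q - 1.0 / len(fam)).sum()
    return float(e_val)


def expression_block(sample: NifSample, ref: ReferenceUsage) -> np.ndarray:
    """24-dim block: (CAI, E, Fop) for each of the eight expression genes.

    Missing genes contribute (0, 0, 0) with a warning; all eight missing is
    an error.
    """
    if not any(g in sample.cds for g in EXPRESSION_GENES):
        raise ValueError(f"sample {sample.sample_id}: no expression-gene CDS available")
    out = np.zeros(3 * len(EXPRESSION_GENES))
    for i, gene in enumerate(EXPRESSION_GENES):
        if gene in sample.cds:
            cds = sample.cds[gene]
            out[3 * i: 3 * i + 3] = (
                compute_cai(cds, ref),
                compute_bias_E(cds),
                compute_fop(cds, ref),
            )
        else:
            logger.warning("sample %s: CDS for %s missing; (0,0,0)", sample.sample_id, gene)
    return out


def aggregate_codon_block(
    vectors: dict[str, np.ndarray], permissive: bool = False
) -> np.ndarray:
    """Element-wise mean of per-gene codon statistics over NifH/D/K CDS."""
    from .protein import aggregate_protein_block

    return aggregate_protein_block(vectors, permissive=permissive)
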