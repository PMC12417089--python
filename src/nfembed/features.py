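"""Assembly of named feature-group blocks from a list of samples.

The nine feature groups are: CT (343), DPC (400), PAAC (50), RSCU (61),
Euclidean_distance (1), Expression (24), Gene_distance (1), Copy_number (34)
and a protein-embedding group whose width depends on the source (1152 for
ESMC_600M). Protein descriptors and codon statistics computed per gene are
averaged over the three structural genes per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import codon, embeddings as emb, genome, protein
from .data_model import STRUCTURAL_GENES, NifSample

FEATURE_GROUP_WIDTHS = {
    "CT": 343,
    "DPC": 400,
    "PAAC": 50,
    "RSCU": 61,
    "Euclidean_distance": 1,
    "Expression": 24,
    "Gene_distance": 1,
    "Copy_number": 34,
}


@dataclass(frozen=True)
class FeatureBlock:
    """A named fixed-width numeric block, one row per sample."""

    name: str
    sample_ids: tuple[str, ...]
    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError(
                f"block {self.name}: shape {v.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.columns)} columns"
            )
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> int:
        return len(self.columns)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.columns) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str) -> "FeatureBlock":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                ids.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(name, tuple(ids), np.array(rows), tuple(header[1:]))


@dataclass
class FeatureGroupSet:
    """Named feature blocks row-aligned to one sample order."""

    blocks: dict[str, FeatureBlock]

    def __post_init__(self) -> None:
        orders = {b.sample_ids for b in self.blocks.values()}
        if len(orders) > 1:
            raise ValueError("feature blocks are not row-aligned to the same samples")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return next(iter(self.blocks.values())).sample_ids

    def design_matrix(self, group_names: list[str] | tuple[str, ...]) -> np.ndarray:
        """Concatenate the listed blocks column-wise into one design matrix."""
        missing = [g for g in group_names if g not in self.blocks]
        if missing:
            raise KeyError(f"unknown feature group(s) {missing}")
        return np.hstack([self.blocks[g].values for g in group_names])

    def subset_rows(self, indices) -> "FeatureGroupSet":
        idx = np.asarray(indices)
        return FeatureGroupSet(
            {
                name: FeatureBlock(
                    name,
                    tuple(np.array(b.sample_ids, dtype=object)[idx]),
                    b.values[idx],
                    b.columns,
                )
                for name, b in self.blocks.items()
            }
        )


def _ct_columns() -> tuple[str, ...]:
    return tuple(
        f"CT_{a}{b}{c}" for a in range(1, 8) for b in range(1, 8) for c in range(1, 8)
    )


def _dpc_columns() -> tuple[str, ...]:
    from .data_model import AMINO_ACIDS

    return tuple(f"DPC_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)


def featurize(
    samples: list[NifSample],
    ref: codon.ReferenceUsage | None = None,
    embedding_table: dict[str, np.ndarray] | None = None,
    embedding_source: str = "pseudo",
    pseudo_width: int = 16,
    pseudo_seed: int = 0,
    paac_cfg: protein.PaacConfig | None = None,
) -> FeatureGroupSet:
    """Compute all feature groups for an ordered list of samples.

    The embedding group comes from ``embedding_table`` (sample-level id ->
    vector) when given, otherwise from the deterministic pseudo-embedding
    backend. The block is named after the embedding source.
    """
    ref = ref if ref is not None else codon.default_reference_usage()
    paac_cfg = paac_cfg if paac_cfg is not None else protein.PaacConfig()
    ids = tuple(s.sample_id for s in samples)
    n = len(samples)

    ct = np.empty((n, 343))
    dpc = np.empty((n, 400))
    paac = np.empty((n, 20 + paac_cfg.lam))
    rscu = np.empty((n, 61))
    ecd = np.empty((n, 1))
    expr = np.empty((n, 24))
    gdist = np.empty((n, 1))
    cnv = np.empty((n, 34))
    emb_rows = []

    for i, s in enumerate(samples):
        ct[i] = protein.aggregate_protein_block(
            {g: protein.encode_ct(s.proteins[g]) for g in STRUCTURAL_GENES}
        )
        dpc[i] = protein.aggregate_protein_block(
            {g: protein.encode_dpc(s.proteins[g]) for g in STRUCTURAL_GENES}
        )
        paac[i] = protein.aggregate_protein_block(
            {g: protein.encode_paac(s.proteins[g], paac_cfg) for g in STRUCTURAL_GENES}
        )
        rscu_per_gene = {
            g: codon.compute_rscu(s.cds[g]) for g in STRUCTURAL_GENES if g in s.cds
        }
        rscu[i] = codon.aggregate_codon_block(rscu_per_gene)
        ecd[i, 0] = np.mean(
            [codon.euclidean_codon_distance(v) for v in rscu_per_gene.values()]
        )
        expr[i] = codon.expression_block(s, ref)
        gdist[i, 0] = genome.gene_distance(s.coordinates)
        cnv[i] = genome.copy_number_vector(s.copy_numbers)

        if embedding_table is not None:
            if s.sample_id in embedding_table:
                emb_rows.append(np.asarray(embedding_table[s.sample_id], dtype=float))
            else:
                # gene-level table: rows keyed "sampleID|gene", one pooled
                # vector per structural gene, averaged here
                per_gene = {
                    g: embedding_table[key]
                    for g in STRUCTURAL_GENES
                    if (key := f"{s.sample_id}|{g}") in embedding_table
                }
                if not per_gene:
                    raise KeyError(f"embedding table lacks sample {s.sample_id!r}")
                emb_rows.append(emb.aggregate_sample_embedding(per_gene))
        else:
            pooled = {
                g: emb.mean_pool(emb.pseudo_embedding(s.proteins[g], pseudo_width, pseudo_seed))
                for g in STRUCTURAL_GENES
            }
            emb_rows.append(emb.aggregate_sample_embedding(pooled))

    emb_mat = np.vstack(emb_rows)
    blocks = {
        "CT": FeatureBlock("CT", ids, ct, _ct_columns()),
        "DPC": FeatureBlock("DPC", ids, dpc, _dpc_columns()),
        "PAAC": FeatureBlock(
            "PAAC", ids, paac, tuple(f"PAAC_{i + 1}" for i in range(paac.shape[1]))
        ),
        "RSCU": FeatureBlock("RSCU", ids, rscu, tuple(codon.SENSE_CODONS)),
        "Euclidean_distance": FeatureBlock("Euclidean_distance", ids, ecd, ("ECD",)),
        "Expression": FeatureBlock(
            "Expression",
            ids,
            expr,
            tuple(
                f"{g}_{stat}"
                for g in ("nifA", "nifB", "nifD", "nifE", "nifH", "nifK", "nifN", "nifX")
                for stat in ("CAI", "E", "Fop")
            ),
        ),
        "Gene_distance": FeatureBlock("Gene_distance", ids, gdist, ("gene_distance",)),
        "Copy_number": FeatureBlock(
            "Copy_number", ids, cnv, tuple(f"copy_{g}" for g in genome.COPY_NUMBER_GENES)
        ),
        embedding_source: FeatureBlock(
            embedding_source,
            ids,
            emb_mat,
            tuple(f"{embedding_source}_{i}" for i in range(emb_mat.shape[1])),
        ),
    }
    return FeatureGroupSet(blocks)
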