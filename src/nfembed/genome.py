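"""Genome-organization features: nifHDK gene distance and copy-number vector."""

from __future__ import annotations

import numpy as np

from .data_model import COPY_NUMBER_GENES, STRUCTURAL_GENES, GeneCoordinate, logger


def gene_distance(
    coords: dict[str, GeneCoordinate],
    mode: str = "span",
    different_replicon: float | None = None,
) -> float:
    """Scalar genomic distance between the nifH, nifD and nifK genes.

    ``mode='span'`` (default) returns max(end) - min(start) over the three
    genes; ``mode='pairwise'`` returns the sum of the three pairwise midpoint
    distances. Genes on different replicons raise, unless a sentinel value
    is supplied via ``different_replicon``. Circular replicons are treated
    as linear.
    """
    missing = [g for g in STRUCTURAL_GENES if g not in coords]
    if missing:
        raise ValueError(f"missing coordinates for {missing}")
    replicons = {coords[g].replicon_id for g in STRUCTURAL_GENES}
    if len(replicons) > 1:
        if different_replicon is not None:
            logger.warning("nifHDK on different replicons %s; using sentinel", sorted(replicons))
            return float(different_replicon)
        raise ValueError(f"nifHDK genes on different replicons: {sorted(replicons)}")
    cs = [coords[g] for g in STRUCTURAL_GENES]
    if mode == "span":
        return float(max(c.end for c in cs) - min(c.start for c in cs))
    if mode == "pairwise":
        mids = [(c.start + c.end) / 2.0 for c in cs]
        return float(
            abs(mids[0] - mids[1]) + abs(mids[0] - mids[2]) + abs(mids[1] - mids[2])
        )
    raise ValueError(f"unknown mode {mode!r}")


def copy_number_vector(counts: dict[str, int]) -> np.ndarray:
    """34-vector of gene copy counts in canonical order.

    Absent genes count 0 (with a warning); unknown gene keys are ignored
    with a warning; negative counts are an error.
    """
    for gene, n in counts.items():
        if n < 0:
            raise ValueError(f"negative copy count for {gene}: {n}")
        if gene not in COPY_NUMBER_GENES:
            logger.warning("unknown gene %r in copy-number map; ignored", gene)
    absent = [g for g in COPY_NUMBER_GENES if g not in counts]
    if absent:
        logger.warning("copy counts absent for %s; assuming 0", absent)
    return np.array([counts.get(g, 0) for g in COPY_NUMBER_GENES], dtype=float)
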