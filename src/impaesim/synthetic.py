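"""Synthetic association edge lists with planted disease communities.

The generator partitions diseases, genes, lncRNAs and miRNAs into
``n_communities`` blocks (as equal as integer division allows, remainders to
the first blocks).  A disease links to a gene of its own community with
probability ``p_within`` and to a foreign gene with ``p_between``; gene-ncRNA
edges follow the same within/between rule, so ncRNAs mostly target their
community's genes.  Every disease and every ncRNA is guaranteed at least one
within-community edge so no planted node is silently dropped as isolated.
The ground-truth community labels let tests ask whether diffusion,
embedding and similarity recover the planted structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .network_io import AssociationTable, write_association_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted-community generator settings.

    The default scale (60 diseases, 150 genes, 12 lncRNAs, 40 miRNAs in 3
    communities) keeps a full pipeline run to a few seconds while leaving
    each community enough genes for reliable overlap.
    """

    n_diseases: int = 60
    n_genes: int = 150
    n_lncrnas: int = 12
    n_mirnas: int = 40
    n_communities: int = 3
    p_within: float = 0.3
    p_between: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("n_diseases", "n_genes", "n_lncrnas", "n_mirnas",
                     "n_communities"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_communities > self.n_diseases:
            raise ValueError("n_communities cannot exceed n_diseases")
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValueError(
                f"need 0 <= p_between < p_within <= 1, got "
                f"p_within={self.p_within}, p_between={self.p_between}"
            )


def _partition(n: int, k: int) -> np.ndarray:
    """Community label per item; sizes differ by at most 1, remainder first."""
    base, rem = divmod(n, k)
    sizes = [base + (1 if c < rem else 0) for c in range(k)]
    return np.repeat(np.arange(k), sizes)


def _bipartite_edges(
    rng: np.random.Generator,
    left_labels: np.ndarray,
    right_labels: np.ndarray,
    p_within: float,
    p_between: float,
) -> np.ndarray:
    same = left_labels[:, None] == right_labels[None, :]
    probs = np.where(same, p_within, p_between)
    return rng.random(probs.shape) < probs


def generate(
    config: SyntheticConfig,
) -> tuple[AssociationTable, AssociationTable, AssociationTable, dict[str, int]]:
    """Draw disease-gene, gene-lncRNA and gene-miRNA tables plus true labels.

    Returns the three association tables and a ``disease id -> community``
    mapping.  Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    diseases = [f"D{i:03d}" for i in range(config.n_diseases)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    lncrnas = [f"L{i:03d}" for i in range(config.n_lncrnas)]
    mirnas = [f"M{i:03d}" for i in range(config.n_mirnas)]

    d_lab = _partition(config.n_diseases, config.n_communities)
    g_lab = _partition(config.n_genes, config.n_communities)
    l_lab = _partition(config.n_lncrnas, config.n_communities)
    m_lab = _partition(config.n_mirnas, config.n_communities)

    def table(left, left_lab, right, right_lab, left_kind, right_kind):
        mask = _bipartite_edges(rng, left_lab, right_lab,
                                config.p_within, config.p_between)
        # guarantee each left node one within-community partner so that no
        # planted disease/ncRNA is dropped as isolated
        for i in range(len(left)):
            if not mask[i].any():
                own = np.flatnonzero(right_lab == left_lab[i])
                pool = own if own.size else np.arange(len(right))
                mask[i, rng.choice(pool)] = True
        edges = {
            (left[i], right[j]): 1.0
            for i, j in zip(*np.nonzero(mask))
        }
        return AssociationTable(left_kind, right_kind, edges)

    dg = table(diseases, d_lab, genes, g_lab, "disease", "gene")
    # ncRNA tables are gene-major, mirroring how the raw sources are shipped
    gl = table(genes, g_lab, lncrnas, l_lab, "gene", "lncRNA")
    gm = table(genes, g_lab, mirnas, m_lab, "gene", "miRNA")
    for name, t in (("disease-gene", dg), ("gene-lncRNA", gl), ("gene-miRNA", gm)):
        if t.n_edges == 0:
            raise ValueError(f"config produced an empty {name} table")
    labels = {d: int(c) for d, c in zip(diseases, d_lab)}
    logger.info(
        "synthetic data (seed %d): |dg|=%d, |gl|=%d, |gm|=%d edges",
        config.seed, dg.n_edges, gl.n_edges, gm.n_edges,
    )
    return dg, gl, gm, labels


def write_dataset(
    config: SyntheticConfig, outdir: Union[str, Path]
) -> dict[str, Path]:
    """Generate and write the three edge lists plus a community-label sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dg, gl, gm, labels = generate(config)
    paths = {
        "disease_gene": outdir / "disease_gene.tsv",
        "gene_lncrna": outdir / "gene_lncrna.tsv",
        "gene_mirna": outdir / "gene_mirna.tsv",
        "labels": outdir / "community_labels.tsv",
    }
    write_association_table(dg, paths["disease_gene"])
    write_association_table(gl, paths["gene_lncrna"])
    write_association_table(gm, paths["gene_mirna"])
    with paths["labels"].open("w") as fh:
        fh.write("disease\tcommunity\n")
        for d, c in sorted(labels.items()):
            fh.write(f"{d}\t{c}\n")
    return paths
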