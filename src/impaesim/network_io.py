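"""Edge-list ingestion and disease-centric network construction.

Three bipartite association sources feed the pipeline: disease-gene,
gene-lncRNA and gene-miRNA edge lists.  Disease-ncRNA networks are not
usually distributed as curated files, so they are derived by composing the
disease-gene table with a gene-ncRNA table through shared target genes.
Every network is kept as a symmetric bipartite adjacency matrix over
``diseases + partners`` with isolated nodes removed, plus a deterministic
(lexicographically sorted) node index so downstream matrices align.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

NODE_KINDS = ("disease", "gene", "lncRNA", "miRNA")

#: networks with at most this many nodes use dense adjacency storage
DENSE_NODE_LIMIT = 2000


@dataclass(frozen=True)
class NodeIndex:
    """Ordered, duplicate-free collection of node identifiers of one kind.

    Ids are sorted lexicographically so that every run of the pipeline maps
    the same id set to the same matrix rows.
    """

    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        if list(self.ids) != sorted(set(self.ids)):
            raise ValueError("NodeIndex ids must be sorted and unique")
        object.__setattr__(self, "_pos", {n: i for i, n in enumerate(self.ids)})

    @classmethod
    def from_ids(cls, ids: Iterable[str], kind: str) -> "NodeIndex":
        return cls(tuple(sorted(set(ids))), kind)

    def position(self, node_id: str) -> int:
        try:
            return self._pos[node_id]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {node_id!r}") from None

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: object) -> bool:
        return node_id in self._pos  # type: ignore[attr-defined]

    def __iter__(self):
        return iter(self.ids)


@dataclass
class AssociationTable:
    """Bipartite edge list between two distinct node universes.

    ``edges`` maps ``(left_id, right_id)`` to a positive weight.  Duplicate
    pairs are collapsed at ingestion time with weights summed.
    """

    left_kind: str
    right_kind: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left_kind == self.right_kind:
            raise ValueError("left_kind and right_kind must differ")
        for pair, w in self.edges.items():
            if not (w > 0):
                raise ValueError(f"non-positive weight {w} for edge {pair}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def left_ids(self) -> set[str]:
        return {l for l, _ in self.edges}

    def right_ids(self) -> set[str]:
        return {r for _, r in self.edges}


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_association_table(
    path: Union[str, Path], left_kind: str, right_kind: str
) -> AssociationTable:
    """Read a two- or three-column edge list (TSV or CSV, auto-detected).

    Lines starting with ``#`` and blank lines are skipped.  The optional
    third column is a positive weight (default 1.0).  Duplicate pairs are
    collapsed with weights summed.

    Raises
    ------
    ValueError
        On a row with fewer than two columns, an unparsable weight, or a
        non-positive weight; the message names the offending line number.
    """
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    delim: str | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _detect_delimiter(line)
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {raw.rstrip()!r}"
                )
            weight = 1.0
            if len(parts) >= 3 and parts[2]:
                try:
                    weight = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric weight at line {lineno}: {parts[2]!r}"
                    ) from None
            if not (weight > 0):
                raise ValueError(
                    f"{path}: non-positive weight {weight} at line {lineno}"
                )
            key = (parts[0], parts[1])
            edges[key] = edges.get(key, 0.0) + weight
    table = AssociationTable(left_kind, right_kind, edges)
    logger.info(
        "read %s: %d edges, %d %s nodes, %d %s nodes",
        path,
        table.n_edges,
        len(table.left_ids()),
        left_kind,
        len(table.right_ids()),
        right_kind,
    )
    return table


def write_association_table(table: AssociationTable, path: Union[str, Path]) -> None:
    """Write a table in the same TSV dialect :func:`read_association_table` reads."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {table.left_kind}\t{table.right_kind}\tweight\n")
        for (left, right), w in sorted(table.edges.items()):
            fh.write(f"{left}\t{right}\t{w:g}\n")


def derive_disease_ncrna_table(
    dg: AssociationTable, gr: AssociationTable
) -> AssociationTable:
    """Compose disease-gene with gene-ncRNA edges through shared genes.

    A disease ``d`` and an ncRNA ``r`` are linked iff they share at least one
    gene; the edge weight is the number of shared genes.
    """
    if dg.left_kind != "disease" or dg.right_kind != "gene":
        raise ValueError(
            f"expected a disease-gene table, got {dg.left_kind}-{dg.right_kind}"
        )
    if gr.left_kind != "gene":
        raise ValueError(f"expected a gene-ncRNA table, got left kind {gr.left_kind}")
    gene_to_diseases: dict[str, set[str]] = {}
    for (d, g) in dg.edges:
        gene_to_diseases.setdefault(g, set()).add(d)
    counts: dict[tuple[str, str], float] = {}
    for (g, r) in gr.edges:
        for d in gene_to_diseases.get(g, ()):
            key = (d, r)
            counts[key] = counts.get(key, 0.0) + 1.0
    table = AssociationTable("disease", gr.right_kind, counts)
    logger.info(
        "derived disease-%s table: %d edges over %d diseases",
        gr.right_kind,
        table.n_edges,
        len(table.left_ids()),
    )
    return table


@dataclass
class DiseaseNetwork:
    """One disease-centric bipartite network with symmetric adjacency.

    Node ordering is ``disease_index.ids`` followed by ``partner_index.ids``;
    the adjacency matrix is dense below :data:`DENSE_NODE_LIMIT` nodes and
    CSR-sparse above.
    """

    name: str
    disease_index: NodeIndex
    partner_index: NodeIndex
    adjacency: Union[np.ndarray, sp.csr_array]

    @property
    def n_nodes(self) -> int:
        return len(self.disease_index) + len(self.partner_index)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.disease_index.ids + self.partner_index.ids

    def node_position(self, node_id: str) -> int:
        if node_id in self.disease_index:
            return self.disease_index.position(node_id)
        return len(self.disease_index) + self.partner_index.position(node_id)

    def dense_adjacency(self) -> np.ndarray:
        if sp.issparse(self.adjacency):
            return np.asarray(self.adjacency.todense())
        return self.adjacency


def build_disease_network(table: AssociationTable, name: str) -> DiseaseNetwork:
    """Build a symmetric bipartite adjacency from an association table.

    Nodes without any edge never enter the table, so isolated-node removal
    reduces to indexing only the ids that appear in at least one edge.
    """
    if table.n_edges == 0:
        raise ValueError(f"cannot build network {name!r} from an empty table")
    disease_index = NodeIndex.from_ids(table.left_ids(), table.left_kind)
    partner_index = NodeIndex.from_ids(table.right_ids(), table.right_kind)
    n_d, n_p = len(disease_index), len(partner_index)
    n = n_d + n_p
    rows, cols, vals = [], [], []
    for (d, p), w in table.edges.items():
        i = disease_index.position(d)
        j = n_d + partner_index.position(p)
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    adj = sp.coo_array((vals, (rows, cols)), shape=(n, n)).tocsr()
    adjacency: Union[np.ndarray, sp.csr_array]
    if n <= DENSE_NODE_LIMIT:
        adjacency = np.asarray(adj.todense())
    else:
        adjacency = adj
    logger.info(
        "network %s: %d diseases + %d partners, %d edges",
        name,
        n_d,
        n_p,
        table.n_edges,
    )
    return DiseaseNetwork(name, disease_index, partner_index, adjacency)


def shared_disease_index(networks: Sequence[DiseaseNetwork]) -> NodeIndex:
    """Sorted intersection of disease ids across networks.

    Diseases missing from any one network cannot contribute an aligned row to
    the concatenated hidden representation and are dropped here.
    """
    if not networks:
        raise ValueError("need at least one network")
    shared = set(networks[0].disease_index.ids)
    for net in networks[1:]:
        shared &= set(net.disease_index.ids)
    if not shared:
        raise ValueError(
            "no disease appears in every network; relax the inputs (e.g. add "
            "associations or drop the sparsest network) so the disease sets overlap"
        )
    dropped = {
        net.name: len(net.disease_index) - len(shared) for net in networks
    }
    logger.info("shared disease index: %d diseases (dropped per network: %s)",
                len(shared), dropped)
    return NodeIndex.from_ids(shared, "disease")


def count_disease_pairs(index: Union[NodeIndex, int]) -> int:
    """Number of unordered disease pairs, n(n-1)/2."""
    n = index if isinstance(index, int) else len(index)
    if n < 2:
        raise ValueError(f"need at least 2 diseases, got {n}")
    return math.comb(n, 2)


def save_network(network: DiseaseNetwork, prefix: Union[str, Path]) -> None:
    """Serialize adjacency as MatrixMarket triplets plus a node-index sidecar."""
    prefix = Path(prefix)
    mmwrite(str(prefix) + ".mtx", sp.coo_array(network.adjacency))
    with open(str(prefix) + ".nodes.tsv", "w") as fh:
        fh.write("node_id\trole\tkind\n")
        for d in network.disease_index:
            fh.write(f"{d}\tdisease\t{network.disease_index.kind}\n")
        for p in network.partner_index:
            fh.write(f"{p}\tpartner\t{network.partner_index.kind}\n")


def load_network(prefix: Union[str, Path], name: str) -> DiseaseNetwork:
    """Inverse of :func:`save_network`."""
    prefix = Path(prefix)
    adj = sp.csr_array(mmread(str(prefix) + ".mtx"))
    diseases, partners = [], []
    kinds = {}
    with open(str(prefix) + ".nodes.tsv") as fh:
        next(fh)
        for line in fh:
            node_id, role, kind = line.rstrip("\n").split("\t")
            (diseases if role == "disease" else partners).append(node_id)
            kinds[role] = kind
    n = adj.shape[0]
    adjacency: Union[np.ndarray, sp.csr_array]
    adjacency = np.asarray(adj.todense()) if n <= DENSE_NODE_LIMIT else adj
    return DiseaseNetwork(
        name,
        NodeIndex(tuple(diseases), kinds.get("disease", "disease")),
        NodeIndex(tuple(partners), kinds.get("partner", "gene")),
        adjacency,
    )
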