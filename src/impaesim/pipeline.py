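"""End-to-end orchestration: networks -> diffusion -> AEs -> similarity.

The stages run in a fixed order: build the three disease-centric networks,
diffuse with RWR, train one classic autoencoder per network, mine link
constraints from the per-network hidden vectors (or raw diffusion profiles),
merge them, train the constraint-regularized autoencoder on the concatenated
hidden vectors, and score all disease pairs by cosine similarity.  Every
stage's output is exposed on the result object and, when run through
:func:`run_pipeline`, written to disk with a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
from sklearn.metrics import roc_auc_score

from . import __version__
from .constraints import (
    ConstraintParams,
    ConstraintSet,
    extract_constraints,
    merge_constraints,
    pairwise_pcc,
    save_constraints,
)
from .diffusion import (
    DiffusionProfile,
    RwrParams,
    diffusion_profiles,
    exclude_self_mass,
    save_profiles,
)
from .embedding import (
    AeParams,
    DiseaseEmbedding,
    ImpAeParams,
    _train,
    concatenate_hidden,
    save_embedding,
    train_impae,
)
from .network_io import (
    AssociationTable,
    DiseaseNetwork,
    NodeIndex,
    build_disease_network,
    derive_disease_ncrna_table,
    read_association_table,
    save_network,
    shared_disease_index,
)
from .similarity import (
    SimilarityMatrix,
    save_similarity,
    save_similarity_matrix,
    similarity_matrix,
)
from .synthetic import SyntheticConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Input is either a :class:`SyntheticConfig` or three edge-list paths.
    With ``ncrna_derivation='shared-genes'`` the ncRNA tables are gene-major
    (gene-lncRNA, gene-miRNA) and disease-ncRNA edges are derived through
    shared target genes; with ``'direct-file'`` they are curated
    disease-lncRNA / disease-miRNA tables used as-is.
    """

    synthetic: Optional[SyntheticConfig] = None
    disease_gene_path: Optional[str] = None
    lncrna_path: Optional[str] = None
    mirna_path: Optional[str] = None
    ncrna_derivation: str = "shared-genes"
    rwr: RwrParams = field(default_factory=RwrParams)
    constraint: ConstraintParams = field(default_factory=ConstraintParams)
    constraint_source: str = "hidden"
    hidden_dim: int = 128
    final_dim: int = 64
    learning_rate: float = 1e-3
    epochs: int = 200
    gamma1: float = 100.0
    gamma2: float = 1.0
    gamma: float = 1000.0
    neg_cap: float = 1.0
    normalize: bool = True
    exclude_self: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.ncrna_derivation not in ("shared-genes", "direct-file"):
            raise ValueError(f"unknown ncrna_derivation {self.ncrna_derivation!r}")
        if self.constraint_source not in ("hidden", "rwr"):
            raise ValueError(f"unknown constraint_source {self.constraint_source!r}")
        if self.synthetic is None and not (
            self.disease_gene_path and self.lncrna_path and self.mirna_path
        ):
            raise ValueError(
                "provide either a synthetic config or all three edge-list paths"
            )


@dataclass
class PipelineResult:
    """Every intermediate and final artifact of one run, in memory."""

    networks: dict[str, DiseaseNetwork]
    shared: NodeIndex
    profiles: dict[str, DiffusionProfile]
    hidden: dict[str, np.ndarray]
    per_network_constraints: dict[str, ConstraintSet]
    constraints: ConstraintSet
    embedding: DiseaseEmbedding
    similarity: SimilarityMatrix
    losses: dict[str, list[float]]
    timings: dict[str, float]
    labels: Optional[dict[str, int]] = None


def _effective_hidden_dim(requested: int, input_dim: int) -> int:
    """Requested width, shrunk to input_dim // 4 when it would not compress."""
    if requested < input_dim:
        return requested
    return max(2, input_dim // 4)


def _effective_final_dim(requested: int, concat_dim: int) -> int:
    """Requested width, shrunk to concat_dim // 2 when it would not compress."""
    if requested < concat_dim:
        return requested
    return max(2, concat_dim // 2)


def load_tables(
    config: PipelineConfig,
) -> tuple[dict[str, AssociationTable], Optional[dict[str, int]]]:
    """Resolve the three disease-centric association tables from the config."""
    labels: Optional[dict[str, int]] = None
    if config.synthetic is not None:
        dg, gl, gm, labels = generate(config.synthetic)
        lnc_raw, mir_raw = gl, gm
    else:
        dg = read_association_table(config.disease_gene_path, "disease", "gene")
        if config.ncrna_derivation == "shared-genes":
            lnc_raw = read_association_table(config.lncrna_path, "gene", "lncRNA")
            mir_raw = read_association_table(config.mirna_path, "gene", "miRNA")
        else:
            lnc_raw = read_association_table(config.lncrna_path, "disease", "lncRNA")
            mir_raw = read_association_table(config.mirna_path, "disease", "miRNA")
    if config.synthetic is not None or config.ncrna_derivation == "shared-genes":
        dl = derive_disease_ncrna_table(dg, lnc_raw)
        dm = derive_disease_ncrna_table(dg, mir_raw)
    else:
        dl, dm = lnc_raw, mir_raw
    return {"disease_gene": dg, "disease_lncRNA": dl, "disease_miRNA": dm}, labels


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline in memory."""
    timings: dict[str, float] = {}
    losses: dict[str, list[float]] = {}

    t0 = time.perf_counter()
    tables, labels = load_tables(config)
    networks = {
        name: build_disease_network(table, name) for name, table in tables.items()
    }
    shared = shared_disease_index(list(networks.values()))
    timings["networks"] = time.perf_counter() - t0
    n = len(shared)

    t0 = time.perf_counter()
    profiles = {
        name: diffusion_profiles(net, config.rwr, shared)
        for name, net in networks.items()
    }
    if config.exclude_self:
        # the restart spike encodes identity, not relatedness; drop it
        # before feature learning
        profiles = {name: exclude_self_mass(p) for name, p in profiles.items()}
    timings["diffusion"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    hidden: dict[str, np.ndarray] = {}
    hidden_dim = _effective_hidden_dim(config.hidden_dim, n)
    for k, (name, prof) in enumerate(sorted(profiles.items())):
        params = AeParams(
            hidden_dim=hidden_dim,
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            seed=config.seed + k,
        )
        _, H, hist = _train(
            prof.profiles, params.hidden_dim, params.learning_rate,
            params.epochs, params.seed,
        )
        hidden[name] = H
        losses[f"classic_ae/{name}"] = hist
    timings["classic_ae"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    per_net: dict[str, ConstraintSet] = {}
    for name in sorted(networks):
        source = hidden[name] if config.constraint_source == "hidden" else (
            profiles[name].profiles
        )
        pcc_mat = pairwise_pcc(source, shared)
        per_net[name] = extract_constraints(pcc_mat, shared, config.constraint)
    merged = merge_constraints(
        [per_net[name] for name in sorted(per_net)], config.constraint.merge
    )
    timings["constraints"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    concat = concatenate_hidden([hidden[name] for name in sorted(hidden)], shared)
    imp_params = ImpAeParams(
        final_dim=_effective_final_dim(config.final_dim, concat.shape[1]),
        gamma1=config.gamma1,
        gamma2=config.gamma2,
        gamma=config.gamma,
        neg_cap=config.neg_cap,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=config.seed + len(hidden),
    )
    embedding = train_impae(concat, merged, imp_params, shared)
    timings["impae"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sim = similarity_matrix(embedding, normalize=config.normalize)
    timings["similarity"] = time.perf_counter() - t0

    logger.info("pipeline done: %d shared diseases, timings %s", n,
                {k: round(v, 3) for k, v in timings.items()})
    return PipelineResult(
        networks=networks,
        shared=shared,
        profiles=profiles,
        hidden=hidden,
        per_network_constraints=per_net,
        constraints=merged,
        embedding=embedding,
        similarity=sim,
        losses=losses,
        timings=timings,
        labels=labels,
    )


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> PipelineResult:
    """Run the pipeline and persist every stage artifact plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "pipeline"
    try:
        stage = "run"
        result = run(config)
        stage = "write-artifacts"
        for name, net in result.networks.items():
            save_network(net, outdir / f"network_{name}")
        for name, prof in result.profiles.items():
            save_profiles(prof, outdir / f"profiles_{name}.tsv")
        for name, cs in result.per_network_constraints.items():
            save_constraints(cs, outdir / f"constraints_{name}")
        save_constraints(result.constraints, outdir / "constraints_merged")
        save_embedding(result.embedding, outdir / "embedding.tsv")
        save_similarity(result.similarity, outdir / "similarity_pairs.tsv")
        save_similarity_matrix(result.similarity, outdir / "similarity_matrix.tsv")
        manifest = {
            "impaesim_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "n_shared_diseases": len(result.shared),
            "config": _jsonable(config),
            "constraint_counts": {
                "positives": len(result.constraints.positives),
                "negatives": len(result.constraints.negatives),
            },
            "final_losses": {k: v[-1] for k, v in result.losses.items()},
            "timings_sec": result.timings,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return result


def _jsonable(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["neg_cap"] = None if not np.isfinite(config.neg_cap) else config.neg_cap
    return d


def community_auroc(
    matrix: SimilarityMatrix, labels: Mapping[str, int]
) -> float:
    """AUROC of similarity scores separating within- vs between-community pairs."""
    ids = matrix.disease_index.ids
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    y = np.array([labels[ids[i]] == labels[ids[j]] for i, j in zip(iu, ju)])
    scores = matrix.scores[iu, ju]
    if y.all() or not y.any():
        raise ValueError("need both within- and between-community pairs")
    return float(roc_auc_score(y, scores))
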