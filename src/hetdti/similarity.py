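"""Per-node-type similarity network inventories.

Each node type gets a list of similarity networks: one precomputed
(chemical structure for drugs, sequence identity for proteins) plus Jaccard
similarities derived from the association and interaction networks. The
drug-protein association matrix is the prediction label and is never
admitted into an inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, DataValidationError
from .hetnet_io import BipartiteAssociation, HeterogeneousNetworkSet, SimilarityMatrix

#: default inventory composition; order is fixed and part of the contract
DEFAULT_DRUG_NETWORKS = ("chemical", "drug_drug", "drug_disease", "drug_side_effect")
DEFAULT_PROTEIN_NETWORKS = ("sequence", "protein_protein", "protein_disease")

#: the five-network core used by the network-ablation experiments: similarity
#: networks and homogeneous interactions only (plus the label matrix itself,
#: which never enters the inventory)
CORE_DRUG_NETWORKS = ("chemical", "drug_drug")
CORE_PROTEIN_NETWORKS = ("sequence", "protein_protein")


@dataclass
class SimilarityInventory:
    """Ordered similarity networks per node type, ready for diffusion."""

    drug: list[SimilarityMatrix] = field(default_factory=list)
    protein: list[SimilarityMatrix] = field(default_factory=list)

    def for_type(self, node_type: str) -> list[SimilarityMatrix]:
        if node_type == "drug":
            return self.drug
        if node_type == "protein":
            return self.protein
        raise ConfigurationError(f"no similarity inventory for node type {node_type!r}")


def jaccard_similarity(assoc: BipartiteAssociation) -> SimilarityMatrix:
    """Jaccard similarity between rows of a binary association matrix.

    ``Sim[i, j] = |N(i) & N(j)| / |N(i) | N(j)|`` where N(i) is the set of
    columns associated with row i. For square same-type matrices the self
    column is excluded from each neighbour set. Conventions: ``Sim[i, i] = 1``
    and two empty neighbour sets give 0 (avoids 0/0 and spurious similarity
    between annotation-free nodes).
    """
    assoc.validate_binary()
    B = assoc.matrix.copy()
    if assoc.row_type == assoc.col_type and B.shape[0] == B.shape[1]:
        np.fill_diagonal(B, 0.0)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(assoc.row_type, sim, name=f"jaccard({assoc.row_type},{assoc.col_type})")


def _drug_network(hs: HeterogeneousNetworkSet, key: str, homogeneous_mode: str) -> SimilarityMatrix:
    if key == "chemical":
        return hs.precomputed["drug_chemical"]
    if key == "drug_drug":
        return _homogeneous(hs.intra_type["drug_drug"], homogeneous_mode, "drug_drug")
    if key in ("drug_disease", "drug_side_effect"):
        return jaccard_similarity(hs.associations[key])
    if key == "drug_protein":
        raise ConfigurationError(
            "the drug_protein association is the label matrix and cannot be "
            "used as a similarity network (leakage guard)"
        )
    raise ConfigurationError(f"unknown drug network {key!r}")


def _protein_network(hs: HeterogeneousNetworkSet, key: str, homogeneous_mode: str) -> SimilarityMatrix:
    if key == "sequence":
        return hs.precomputed["protein_sequence"]
    if key == "protein_protein":
        return _homogeneous(hs.intra_type["protein_protein"], homogeneous_mode, "protein_protein")
    if key == "protein_disease":
        return jaccard_similarity(hs.associations[key])
    if key == "drug_protein":
        raise ConfigurationError(
            "the drug_protein association is the label matrix and cannot be "
            "used as a similarity network (leakage guard)"
        )
    raise ConfigurationError(f"unknown protein network {key!r}")


def _homogeneous(assoc: BipartiteAssociation, mode: str, name: str) -> SimilarityMatrix:
    """Similarity network from a homogeneous interaction network.

    ``jaccard`` (default): Jaccard over interaction partners, self excluded.
    ``adjacency``: the binary interaction matrix itself (unit diagonal added),
    i.e. random walks run directly on the interaction graph.
    """
    if mode == "jaccard":
        sim = jaccard_similarity(assoc)
        sim.name = f"jaccard({name})"
        return sim
    if mode == "adjacency":
        assoc.validate_binary()
        M = assoc.matrix.copy()
        if not np.allclose(M, M.T):
            raise DataValidationError(f"{name} interaction matrix is not symmetric")
        return SimilarityMatrix(assoc.row_type, np.clip(M, 0, 1), name=f"adjacency({name})")
    raise ConfigurationError(f"unknown homogeneous_mode {mode!r} (expected jaccard|adjacency)")


def build_inventory(
    hs: HeterogeneousNetworkSet,
    drug_networks: Optional[Sequence[str]] = None,
    protein_networks: Optional[Sequence[str]] = None,
    homogeneous_mode: str = "jaccard",
) -> SimilarityInventory:
    """Build the similarity inventory from a validated network set.

    With defaults this yields 4 drug networks (chemical structure; Jaccard
    over drug-drug interactions, drug-disease and drug-side-effect
    associations) and 3 protein networks (sequence; Jaccard over
    protein-protein interactions and protein-disease associations). Partial
    inventories for network-ablation experiments are requested explicitly
    via ``drug_networks`` / ``protein_networks``.
    """
    drug_keys = tuple(drug_networks) if drug_networks is not None else DEFAULT_DRUG_NETWORKS
    protein_keys = (
        tuple(protein_networks) if protein_networks is not None else DEFAULT_PROTEIN_NETWORKS
    )
    if not drug_keys or not protein_keys:
        raise ConfigurationError("inventory needs at least one network per node type")
    try:
        drug = [_drug_network(hs, k, homogeneous_mode) for k in drug_keys]
        protein = [_protein_network(hs, k, homogeneous_mode) for k in protein_keys]
    except KeyError as exc:
        raise ConfigurationError(f"network set is missing {exc.args[0]!r}") from exc
    return SimilarityInventory(drug=drug, protein=protein)
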