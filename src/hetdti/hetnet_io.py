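"""Read, validate, index and write heterogeneous drug/protein/disease/side-effect networks.

All matrices are dense NumPy arrays indexed by :class:`NodeRegistry` objects.
Edge lists are tab-separated text (``row_id<TAB>col_id[<TAB>weight]``, ``#``
comments allowed); similarity matrices are dense TSV tables, optionally with
an id header row and column. Node ids are opaque strings; indexing is 0-based
everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError, DataValidationError, ParseError

logger = logging.getLogger(__name__)

NODE_TYPES = ("drug", "protein", "disease", "side_effect")

#: canonical bipartite association names -> (row node type, col node type)
ASSOCIATION_SCHEMA = {
    "drug_protein": ("drug", "protein"),
    "drug_disease": ("drug", "disease"),
    "protein_disease": ("protein", "disease"),
    "drug_side_effect": ("drug", "side_effect"),
}

#: homogeneous interaction networks, stored as square binary matrices
INTRA_TYPE_SCHEMA = {
    "drug_drug": "drug",
    "protein_protein": "protein",
}

#: precomputed similarity matrices -> node type
PRECOMPUTED_SCHEMA = {
    "drug_chemical": "drug",
    "protein_sequence": "protein",
}


@dataclass
class NodeRegistry:
    """Ordered registry of unique node identifiers for one node type.

    ``index`` maps each id to its 0-based row/column position; ordering is
    exactly insertion (file) order, so repeated reads of the same file yield
    the same indexing.
    """

    node_type: str
    ids: list[str] = field(default_factory=list)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise DataValidationError(f"unknown node type {self.node_type!r}")
        if len(set(self.ids)) != len(self.ids):
            raise DataValidationError(f"duplicate ids in {self.node_type} registry")
        self.ids = list(self.ids)
        self.index = {nid: i for i, nid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.index

    def add(self, node_id: str) -> int:
        """Append a new id, returning its position (or the existing position)."""
        if node_id in self.index:
            return self.index[node_id]
        self.index[node_id] = len(self.ids)
        self.ids.append(node_id)
        return self.index[node_id]

    def subset(self, keep: Sequence[int]) -> "NodeRegistry":
        """New registry restricted to the given positions, order preserved."""
        return NodeRegistry(self.node_type, [self.ids[i] for i in keep])

    @classmethod
    def from_file(cls, path: str | Path, node_type: str) -> "NodeRegistry":
        """One id per line; line order defines the index."""
        ids = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(node_type, ids)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.ids) + "\n")


@dataclass
class BipartiteAssociation:
    """Binary association matrix between two (possibly equal) node types."""

    row_type: str
    col_type: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataValidationError("association matrix must be 2-dimensional")

    def validate_binary(self) -> None:
        vals = np.unique(self.matrix)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DataValidationError(
                f"{self.row_type}-{self.col_type} association is not binary"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1] and unit diagonal.

    The unit diagonal is forced on construction: both the random-walk row
    normalization and the self-loop graph-convolution normalization require
    strictly positive diagonals.
    """

    node_type: str
    matrix: np.ndarray
    name: str = ""

    _SYM_TOL = 1e-6
    _RANGE_TOL = 1e-9

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise DataValidationError(f"similarity matrix {self.name!r} is not square")
        asym = np.abs(M - M.T).max() if M.size else 0.0
        if asym > self._SYM_TOL:
            raise DataValidationError(
                f"similarity matrix {self.name!r} asymmetric (max deviation {asym:.3g})"
            )
        if asym > 0:
            M = (M + M.T) / 2.0
        if M.size and (M.min() < -self._RANGE_TOL or M.max() > 1 + self._RANGE_TOL):
            raise DataValidationError(
                f"similarity matrix {self.name!r} has entries outside [0, 1] "
                f"(range [{M.min():.3g}, {M.max():.3g}])"
            )
        M = np.clip(M, 0.0, 1.0)
        np.fill_diagonal(M, 1.0)
        self.matrix = M

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class HeterogeneousNetworkSet:
    """The full network collection, consistently indexed by per-type registries.

    The ``drug_protein`` association is the label matrix Y and is never used
    to build similarity networks or diffusion inputs (leakage guard enforced
    in :mod:`hetdti.similarity`).
    """

    registries: dict[str, NodeRegistry]
    associations: dict[str, BipartiteAssociation]
    intra_type: dict[str, BipartiteAssociation]
    precomputed: dict[str, SimilarityMatrix]

    @property
    def label_matrix(self) -> np.ndarray:
        return self.associations["drug_protein"].matrix

    @property
    def n_drugs(self) -> int:
        return len(self.registries["drug"])

    @property
    def n_proteins(self) -> int:
        return len(self.registries["protein"])

    def validate(self) -> None:
        """Check every matrix against the registries and its type contract."""
        for name, (rt, ct) in ASSOCIATION_SCHEMA.items():
            if name not in self.associations:
                raise ConfigurationError(f"missing association network {name!r}")
            a = self.associations[name]
            expected = (len(self.registries[rt]), len(self.registries[ct]))
            if a.shape != expected:
                raise DataValidationError(
                    f"{name} shape {a.shape} does not match registries {expected}"
                )
            a.validate_binary()
        for name, nt in INTRA_TYPE_SCHEMA.items():
            if name not in self.intra_type:
                raise ConfigurationError(f"missing interaction network {name!r}")
            a = self.intra_type[name]
            n = len(self.registries[nt])
            if a.shape != (n, n):
                raise DataValidationError(f"{name} shape {a.shape}, expected ({n}, {n})")
            a.validate_binary()
            if not np.allclose(a.matrix, a.matrix.T):
                raise DataValidationError(f"{name} interaction matrix is not symmetric")
        for name, nt in PRECOMPUTED_SCHEMA.items():
            if name not in self.precomputed:
                raise ConfigurationError(f"missing precomputed similarity {name!r}")
            if self.precomputed[name].n != len(self.registries[nt]):
                raise DataValidationError(f"{name} size does not match {nt} registry")


def read_edge_list(
    path: str | Path,
    row_registry: NodeRegistry,
    col_registry: NodeRegistry,
    binary: bool = True,
) -> BipartiteAssociation:
    """Parse a TSV edge list into an association matrix.

    A registry that already contains ids is treated as frozen: an id absent
    from it raises :class:`DataValidationError`. Empty registries are
    populated in file order. When row and column registries refer to the same
    node type and object, edges are mirrored symmetrically.

    Parameters
    ----------
    binary:
        Store 1 for every listed edge (default). When False, a third column
        is used as the edge weight (missing weight defaults to 1).
    """
    path = Path(path)
    row_frozen = len(row_registry) > 0
    col_frozen = len(col_registry) > 0
    same_type = row_registry.node_type == col_registry.node_type
    if same_type and row_registry is not col_registry:
        raise ConfigurationError(
            "same-type edge lists must be read with a single shared registry"
        )
    edges: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            rid, cid = parts[0].strip(), parts[1].strip()
            weight = 1.0
            if len(parts) >= 3 and parts[2].strip():
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            for nid, reg, frozen in ((rid, row_registry, row_frozen), (cid, col_registry, col_frozen)):
                if nid not in reg:
                    if frozen:
                        raise DataValidationError(
                            f"{path}:{lineno}: unknown {reg.node_type} id {nid!r}"
                        )
                    reg.add(nid)
            edges.append((rid, cid, weight))

    M = np.zeros((len(row_registry), len(col_registry)))
    for rid, cid, w in edges:
        val = 1.0 if binary else w
        i, j = row_registry.index[rid], col_registry.index[cid]
        M[i, j] = val
        if same_type:
            M[j, i] = val
    return BipartiteAssociation(row_registry.node_type, col_registry.node_type, M)


def read_similarity_matrix(
    path: str | Path,
    registry: Optional[NodeRegistry] = None,
    node_type: Optional[str] = None,
    name: str = "",
) -> SimilarityMatrix:
    """Read a dense TSV similarity table.

    The table may carry an id header row and leading id column; if so and a
    frozen registry is given, rows/columns are reordered to registry order.
    Mild asymmetry (<= 1e-6) is symmetrized as (M + M^T)/2 and entries are
    clipped to [0, 1] when the overshoot is within 1e-9; anything larger is a
    validation error.
    """
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: empty similarity table")
    first = lines[0].split("\t")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(t) for t in first if t.strip())
    ids: Optional[list[str]] = None
    if has_header:
        ids = [t.strip() for t in first if t.strip()]
        rows = []
        row_ids = []
        for lineno, ln in enumerate(lines[1:], start=2):
            parts = ln.split("\t")
            row_ids.append(parts[0].strip())
            try:
                rows.append([float(t) for t in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
        if row_ids != ids:
            raise DataValidationError(f"{path}: header ids and row ids disagree")
        M = np.array(rows)
    else:
        try:
            M = np.array([[float(t) for t in ln.split("\t")] for ln in lines])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric entry") from exc

    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataValidationError(f"{path}: similarity table is not square {M.shape}")

    if registry is not None and len(registry) > 0:
        if ids is not None:
            unknown = [i for i in ids if i not in registry]
            if unknown:
                raise DataValidationError(f"{path}: unknown ids {unknown[:3]}")
            order = [ids.index(i) for i in registry.ids]
            M = M[np.ix_(order, order)]
        elif M.shape[0] != len(registry):
            raise DataValidationError(
                f"{path}: table size {M.shape[0]} does not match registry {len(registry)}"
            )
        nt = registry.node_type
    else:
        nt = node_type or "drug"
    return SimilarityMatrix(nt, M, name=name or path.stem)


def write_similarity_matrix(sim: SimilarityMatrix, registry: NodeRegistry, path: str | Path) -> None:
    """Dense TSV with id header row and column (inverse of read_similarity_matrix)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(registry.ids) + "\n")
        for i, rid in enumerate(registry.ids):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in sim.matrix[i]) + "\n")


def write_edge_list(assoc: BipartiteAssociation, row_registry: NodeRegistry,
                    col_registry: NodeRegistry, path: str | Path) -> None:
    """Write the nonzero entries as a TSV edge list (upper triangle for square same-type)."""
    same = assoc.row_type == assoc.col_type
    with Path(path).open("w") as fh:
        rows, cols = np.nonzero(assoc.matrix)
        for i, j in zip(rows, cols):
            if same and j < i:
                continue
            fh.write(f"{row_registry.ids[i]}\t{col_registry.ids[j]}\n")


def write_score_matrix(
    scores,
    drug_registry: NodeRegistry,
    protein_registry: NodeRegistry,
    path: str | Path,
    top_k: Optional[int] = None,
    exclude_mask: Optional[np.ndarray] = None,
) -> None:
    """Write (drug_id, protein_id, score) rows sorted by descending score.

    ``exclude_mask`` (binary, 1 = training pair) restricts the output to
    non-training pairs. Ties are broken by (drug_id, protein_id)
    lexicographic order so output is deterministic.
    """
    M = np.asarray(getattr(scores, "matrix", scores), dtype=float)
    if M.shape != (len(drug_registry), len(protein_registry)):
        raise DataValidationError(
            f"score matrix shape {M.shape} does not match registries "
            f"({len(drug_registry)}, {len(protein_registry)})"
        )
    entries = []
    for i in range(M.shape[0]):
        for j in range(M.shape[1]):
            if exclude_mask is not None and exclude_mask[i, j]:
                continue
            entries.append((-M[i, j], drug_registry.ids[i], protein_registry.ids[j]))
    entries.sort()
    if top_k is not None:
        entries = entries[:top_k]
    with Path(path).open("w") as fh:
        for neg_score, did, pid in entries:
            fh.write(f"{did}\t{pid}\t{-neg_score:.10g}\n")


def assemble(
    registries: Mapping[str, NodeRegistry],
    associations: Mapping[str, BipartiteAssociation],
    intra_type: Mapping[str, BipartiteAssociation],
    precomputed: Mapping[str, SimilarityMatrix],
    drop_isolated: bool = True,
) -> HeterogeneousNetworkSet:
    """Assemble and validate a network set, optionally dropping isolated nodes.

    A node is isolated when it has zero degree across ALL association and
    interaction networks it participates in (precomputed similarities do not
    count: their forced unit diagonal is not evidence of connectivity).
    Dropped nodes are logged.
    """
    hs = HeterogeneousNetworkSet(
        registries=dict(registries),
        associations=dict(associations),
        intra_type=dict(intra_type),
        precomputed=dict(precomputed),
    )
    hs.validate()
    if not drop_isolated:
        return hs

    degree = {nt: np.zeros(len(reg)) for nt, reg in hs.registries.items()}
    for name, (rt, ct) in ASSOCIATION_SCHEMA.items():
        M = hs.associations[name].matrix
        degree[rt] += M.sum(axis=1)
        degree[ct] += M.sum(axis=0)
    for name, nt in INTRA_TYPE_SCHEMA.items():
        M = hs.intra_type[name].matrix
        off = M.copy()
        np.fill_diagonal(off, 0.0)
        degree[nt] += off.sum(axis=1)

    keep = {nt: np.nonzero(deg > 0)[0] for nt, deg in degree.items()}
    n_dropped = sum(len(hs.registries[nt]) - len(k) for nt, k in keep.items())
    if n_dropped == 0:
        return hs
    for nt, k in keep.items():
        dropped = [hs.registries[nt].ids[i] for i in range(len(hs.registries[nt])) if i not in set(k)]
        if dropped:
            logger.info("dropping %d isolated %s node(s): %s", len(dropped), nt, dropped)

    new_reg = {nt: hs.registries[nt].subset(list(k)) for nt, k in keep.items()}
    new_assoc = {
        name: BipartiteAssociation(rt, ct, hs.associations[name].matrix[np.ix_(keep[rt], keep[ct])])
        for name, (rt, ct) in ASSOCIATION_SCHEMA.items()
    }
    new_intra = {
        name: BipartiteAssociation(nt, nt, hs.intra_type[name].matrix[np.ix_(keep[nt], keep[nt])])
        for name, nt in INTRA_TYPE_SCHEMA.items()
    }
    new_pre = {
        name: SimilarityMatrix(nt, hs.precomputed[name].matrix[np.ix_(keep[nt], keep[nt])],
                               name=hs.precomputed[name].name)
        for name, nt in PRECOMPUTED_SCHEMA.items()
    }
    out = HeterogeneousNetworkSet(new_reg, new_assoc, new_intra, new_pre)
    out.validate()
    return out
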