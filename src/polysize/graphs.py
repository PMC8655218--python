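"""Polymer graph construction and atom featurization.

A polymer is represented by its repeat unit — a SMILES string with exactly two
wildcard atoms (``*``) marking the backbone attachment points.  From one unit
two graph representations can be built:

* a **linear** chain of ``n`` units, head-to-tail, chain ends capped with
  implicit hydrogens, and
* a **cyclic** ("pseudo-infinite") macrocycle of ``m`` units in which the last
  unit bonds back onto the first.  Because every unit then has an identical
  environment, each atom sees what an interior atom of an infinitely long chain
  would see — provided no feature encodes membership in the macrocycle and the
  convolutional awareness range does not wrap around the ring.

Hydrogens are implicit: the graph contains heavy atoms only, with the attached
hydrogen count as a node feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdmolops

from .errors import FeaturizationError, ParseError, ValidationError

__all__ = [
    "AtomFeatureSpec",
    "RepeatUnit",
    "MolecularGraph",
    "parse_repeat_unit",
    "featurize_atoms",
    "build_linear_polymer",
    "build_cyclic_polymer",
    "normalized_adjacency",
    "graph_to_csv",
    "default_feature_spec",
]

# Featurizers a spec may contain, in the order their blocks are emitted.
KNOWN_FEATURIZERS = (
    "element",
    "degree",
    "formal_charge",
    "hybridization",
    "h_count",
    "partial_charge",
)

# Any featurizer that would let a node detect that it sits in the synthetic
# macrocycle would break the equivalence between the cyclic representation and
# an infinite linear chain, so these are rejected outright.
FORBIDDEN_FEATURIZERS = frozenset(
    {"in_ring", "ring_membership", "ring_size", "is_in_ring", "macrocycle"}
)

_HYBRIDIZATION_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class AtomFeatureSpec:
    """Ordered per-atom featurization recipe.

    Each entry of ``featurizers`` contributes a block to the node feature
    vector: one-hot blocks for categorical featurizers, a single scalar for
    charges.  Out-of-vocabulary values fall into an ``other`` slot where the
    vocabulary provides one, otherwise featurization fails naming the value.
    """

    featurizers: tuple = KNOWN_FEATURIZERS
    elements: tuple = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "other")
    degrees: tuple = (0, 1, 2, 3, 4, 5)
    hybridizations: tuple = ("sp", "sp2", "sp3", "other")
    h_counts: tuple = (0, 1, 2, 3, 4)

    def __post_init__(self):
        for f in self.featurizers:
            if f in FORBIDDEN_FEATURIZERS:
                raise ValidationError(
                    f"featurizer {f!r} encodes ring membership; the cyclic "
                    "polymer representation requires nodes to be blind to the "
                    "macrocycle"
                )
            if f not in KNOWN_FEATURIZERS:
                raise ValidationError(f"unknown featurizer {f!r}")
        if len(set(self.featurizers)) != len(self.featurizers):
            raise ValidationError("duplicate featurizer in spec")

    @property
    def include_partial_charge(self) -> bool:
        return "partial_charge" in self.featurizers

    def block_dims(self) -> dict:
        dims = {
            "element": len(self.elements),
            "degree": len(self.degrees),
            "formal_charge": 1,
            "hybridization": len(self.hybridizations),
            "h_count": len(self.h_counts),
            "partial_charge": 1,
        }
        return {f: dims[f] for f in self.featurizers}

    @property
    def total_dim(self) -> int:
        return sum(self.block_dims().values())


def default_feature_spec() -> AtomFeatureSpec:
    return AtomFeatureSpec()


@dataclass(frozen=True)
class RepeatUnit:
    """A validated polymer repeat unit.

    ``head`` and ``tail`` are atom indices (into the de-marked core molecule)
    that carry the two attachment points; consecutive units bond tail→head.
    They may coincide (single-backbone-atom units such as ``*C*``).
    """

    smiles: str
    name: str = ""
    core: Chem.Mol = field(repr=False, compare=False, default=None)
    head: int = 0
    tail: int = 0

    @property
    def n_heavy(self) -> int:
        return self.core.GetNumAtoms()

    @property
    def backbone_length(self) -> int:
        """Number of atoms on the shortest head→tail backbone path."""
        if self.head == self.tail:
            return 1
        return len(rdmolops.GetShortestPath(self.core, self.head, self.tail))


@dataclass
class MolecularGraph:
    """A featurized heavy-atom polymer graph.

    Edges are stored once as unordered index pairs; the convolution expands
    them to both directions via the symmetric adjacency.  ``unit_index`` and
    ``atom_index`` locate every node as (repeat unit, atom within unit).
    """

    n_nodes: int
    edges: np.ndarray  # (E, 2) int
    H0: np.ndarray  # (n_nodes, total_dim) float64
    unit_index: np.ndarray  # (n_nodes,) int
    atom_index: np.ndarray  # (n_nodes,) int
    n_units: int
    unit_size: int
    cyclic: bool
    mol: Chem.Mol = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.H0.shape[0] != self.n_nodes:
            raise ValidationError(
                f"feature matrix has {self.H0.shape[0]} rows for "
                f"{self.n_nodes} nodes"
            )
        e = np.asarray(self.edges)
        if e.size and (
            (e < 0).any() or (e >= self.n_nodes).any() or (e[:, 0] == e[:, 1]).any()
        ):
            raise ValidationError("edge indices out of range or self-loop present")

    def nodes_of_unit(self, unit: int) -> np.ndarray:
        return np.nonzero(self.unit_index == unit)[0]


def parse_repeat_unit(smiles: str, name: str = "") -> RepeatUnit:
    """Parse a repeat-unit SMILES with two ``*`` attachment markers."""
    if not smiles or not smiles.strip():
        raise ParseError("empty repeat-unit SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse repeat-unit SMILES {smiles!r}")
    wild = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(wild) != 2:
        raise ValidationError(
            f"repeat unit must carry exactly 2 attachment markers, found "
            f"{len(wild)} in {smiles!r}"
        )
    attachments = []
    for w in wild:
        nbrs = mol.GetAtomWithIdx(w).GetNeighbors()
        if len(nbrs) != 1 or nbrs[0].GetAtomicNum() == 0:
            raise ValidationError(
                f"attachment marker in {smiles!r} must bond exactly one heavy atom"
            )
        attachments.append(nbrs[0].GetIdx())
    # De-mark: drop the wildcards, remapping the attachment indices.
    rw = Chem.RWMol(mol)
    for w in sorted(wild, reverse=True):
        rw.RemoveAtom(w)
        attachments = [a - 1 if a > w else a for a in attachments]
    core = rw.GetMol()
    try:
        Chem.SanitizeMol(core)
    except Exception as exc:  # pragma: no cover - rdkit message varies
        raise ParseError(f"de-marked structure of {smiles!r} is invalid: {exc}")
    head, tail = attachments
    return RepeatUnit(smiles=smiles, name=name, core=core, head=head, tail=tail)


def _assemble_mol(unit: RepeatUnit, n_units: int, cyclic: bool) -> Chem.Mol:
    core, k = unit.core, unit.n_heavy
    rw = Chem.RWMol()
    for _ in range(n_units):
        for a in core.GetAtoms():
            atom = Chem.Atom(a.GetAtomicNum())
            atom.SetFormalCharge(a.GetFormalCharge())
            rw.AddAtom(atom)
    for i in range(n_units):
        for b in core.GetBonds():
            rw.AddBond(
                i * k + b.GetBeginAtomIdx(), i * k + b.GetEndAtomIdx(), b.GetBondType()
            )
    for i in range(n_units - 1):
        rw.AddBond(i * k + unit.tail, (i + 1) * k + unit.head, Chem.BondType.SINGLE)
    if cyclic and n_units > 1:
        rw.AddBond((n_units - 1) * k + unit.tail, unit.head, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def featurize_atoms(mol: Chem.Mol, spec: AtomFeatureSpec) -> np.ndarray:
    """Featurize every atom of a finalized topology into the matrix ``H0``.

    Must run on the final (linear or cyclic) molecule so that
    neighborhood-dependent features — degree, hydrogen count, partial charge —
    see the built graph rather than the bare repeat unit.
    """
    if spec.include_partial_charge:
        AllChem.ComputeGasteigerCharges(mol)
    n = mol.GetNumAtoms()
    H0 = np.zeros((n, spec.total_dim))
    for i, atom in enumerate(mol.GetAtoms()):
        row = []
        for f in spec.featurizers:
            if f == "element":
                row.append(_one_hot(atom.GetSymbol(), spec.elements, "element"))
            elif f == "degree":
                row.append(_one_hot(atom.GetDegree(), spec.degrees, "degree"))
            elif f == "formal_charge":
                row.append(np.array([float(atom.GetFormalCharge())]))
            elif f == "hybridization":
                name = _HYBRIDIZATION_NAMES.get(atom.GetHybridization(), "other")
                row.append(_one_hot(name, spec.hybridizations, "hybridization"))
            elif f == "h_count":
                row.append(_one_hot(atom.GetTotalNumHs(), spec.h_counts, "h_count"))
            elif f == "partial_charge":
                q = float(atom.GetProp("_GasteigerCharge"))
                row.append(np.array([q]))
        H0[i] = np.concatenate(row)
    return H0


def _one_hot(value, vocab, block_name):
    v = np.zeros(len(vocab))
    if value in vocab:
        v[vocab.index(value)] = 1.0
    elif "other" in vocab:
        v[vocab.index("other")] = 1.0
    else:
        raise FeaturizationError(
            f"value {value!r} outside the {block_name} vocabulary and no "
            "'other' slot is configured"
        )
    return v


def _graph_from_mol(
    mol: Chem.Mol, unit: RepeatUnit, n_units: int, cyclic: bool, spec: AtomFeatureSpec
) -> MolecularGraph:
    k = unit.n_heavy
    edges = np.array(
        [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()], dtype=int
    ).reshape(-1, 2)
    H0 = featurize_atoms(mol, spec)
    idx = np.arange(mol.GetNumAtoms())
    return MolecularGraph(
        n_nodes=mol.GetNumAtoms(),
        edges=edges,
        H0=H0,
        unit_index=idx // k,
        atom_index=idx % k,
        n_units=n_units,
        unit_size=k,
        cyclic=cyclic,
        mol=mol,
    )


def build_linear_polymer(
    unit: RepeatUnit, n_units: int, spec: AtomFeatureSpec | None = None
) -> MolecularGraph:
    """Head-to-tail chain of ``n_units`` copies, ends capped with implicit H."""
    if n_units < 1:
        raise ValidationError(f"n_units must be >= 1, got {n_units}")
    spec = spec or default_feature_spec()
    mol = _assemble_mol(unit, n_units, cyclic=False)
    return _graph_from_mol(mol, unit, n_units, False, spec)


def build_cyclic_polymer(
    unit: RepeatUnit,
    ring_size: int = 10,
    spec: AtomFeatureSpec | None = None,
    n_conv_layers: int | None = None,
) -> MolecularGraph:
    """Macrocycle of ``ring_size`` units — the pseudo-infinite representation.

    If ``n_conv_layers`` is given, warns when the convolutional awareness range
    could wrap around the backbone cycle and let a node see itself, which would
    break the equivalence with an infinite chain.
    """
    if ring_size < 3:
        raise ValidationError(f"ring_size must be >= 3, got {ring_size}")
    spec = spec or default_feature_spec()
    if n_conv_layers is not None:
        check_ring_wrap(unit, ring_size, n_conv_layers)
    mol = _assemble_mol(unit, ring_size, cyclic=True)
    return _graph_from_mol(mol, unit, ring_size, True, spec)


def check_ring_wrap(unit: RepeatUnit, ring_size: int, n_conv_layers: int) -> bool:
    """True if the backbone cycle is long enough for the awareness range."""
    cycle = ring_size * unit.backbone_length
    if cycle <= 2 * n_conv_layers:
        warnings.warn(
            f"backbone cycle of {cycle} atoms does not exceed twice the "
            f"awareness range ({n_conv_layers} layers); the cyclic graph no "
            "longer emulates an infinite chain",
            stacklevel=2,
        )
        return False
    return True


def normalized_adjacency(graph: MolecularGraph) -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops.

    Â = D̃^{-1/2} (A + I) D̃^{-1/2}, the propagation operator of the
    convolution; symmetric with entries in [0, 1].
    """
    n = graph.n_nodes
    A = np.zeros((n, n))
    if graph.edges.size:
        A[graph.edges[:, 0], graph.edges[:, 1]] = 1.0
        A[graph.edges[:, 1], graph.edges[:, 0]] = 1.0
    A += np.eye(n)
    d = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


def graph_to_csv(graph: MolecularGraph, prefix: str) -> tuple:
    """Debug export: ``<prefix>_nodes.csv``, ``<prefix>_edges.csv`` and an
    adjacency dump ``<prefix>_adjacency.txt``; returns the three paths."""
    import pandas as pd

    node_path = f"{prefix}_nodes.csv"
    edge_path = f"{prefix}_edges.csv"
    adj_path = f"{prefix}_adjacency.txt"
    nodes = pd.DataFrame(
        {
            "node": np.arange(graph.n_nodes),
            "unit_index": graph.unit_index,
            "atom_index": graph.atom_index,
        }
    )
    feats = pd.DataFrame(
        graph.H0, columns=[f"f{j}" for j in range(graph.H0.shape[1])]
    )
    pd.concat([nodes, feats], axis=1).to_csv(node_path, index=False)
    pd.DataFrame(graph.edges, columns=["source", "target"]).to_csv(
        edge_path, index=False
    )
    np.savetxt(adj_path, normalized_adjacency(graph), fmt="%.12g")
    return node_path, edge_path, adj_path
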