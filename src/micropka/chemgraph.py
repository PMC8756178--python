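"""Structure standardization, graph featurization and ionizable-site rules.

A molecule enters as SMILES or an SDF block, is standardized (salt
stripping, charge neutralization where valence allows, canonical SMILES),
and becomes a :class:`MoleculeGraph`: heavy atoms as nodes with fixed-length
one-hot feature vectors, bonds as undirected edges, hydrogens folded into
per-atom counts.

Ionizable sites follow two rules:

* acidic: any non-carbon atom bearing at least one hydrogen,
* basic: any nitrogen atom with no positive formal charge.

C-H acidity is deliberately unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StructureError",
    "MoleculeRecord",
    "MoleculeGraph",
    "SiteAnnotation",
    "FeatureConfig",
    "standardize_structure",
    "standardize_with_flag",
    "build_graph",
    "enumerate_acidic_sites",
    "enumerate_basic_sites",
    "annotate_sites",
    "sites_for_mode",
]


class StructureError(ValueError):
    """Raised for unparseable or empty chemical structures."""

    def __init__(self, message: str, structure: str = ""):
        super().__init__(message)
        self.structure = structure


# ---------------------------------------------------------------------------
# feature schema


_ELEMENTS = ["C", "N", "O", "S", "F", "Cl", "Br", "I", "P"]
_DEGREES = [0, 1, 2, 3, 4, 5]
_CHARGES = [-1, 0, 1]
_HYBRID = ["SP", "SP2", "SP3"]
_NUM_H = [0, 1, 2, 3, 4]
_CHIRAL = ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW"]
_BOND_TYPES = ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC"]
_BOND_STEREO = ["STEREONONE", "STEREOZ", "STEREOE"]


@dataclass(frozen=True)
class FeatureConfig:
    """Schema of 8 atom descriptors and 4 bond descriptors.

    Each categorical descriptor is one-hot encoded with a trailing "other"
    bucket where the category list is open-ended; boolean descriptors take a
    single slot.  The schema is fixed per model and serialized with it, so
    encodings are reproducible.
    """

    atom_feature_schema: tuple = (
        ("element", tuple(_ELEMENTS)),          # + other
        ("degree", tuple(_DEGREES)),            # + other
        ("formal_charge", tuple(_CHARGES)),     # + other
        ("hybridization", tuple(_HYBRID)),      # + other
        ("aromatic", None),                     # flag
        ("total_h", tuple(_NUM_H)),             # + other
        ("in_ring", None),                      # flag
        ("chirality", tuple(_CHIRAL)),          # + other
    )
    bond_feature_schema: tuple = (
        ("bond_type", tuple(_BOND_TYPES)),      # exhaustive for kekulized input
        ("conjugated", None),
        ("in_ring", None),
        ("stereo", tuple(_BOND_STEREO)),        # + other
    )

    def __post_init__(self):
        if len(self.atom_feature_schema) != 8 or len(self.bond_feature_schema) != 4:
            raise ValueError("schema must list 8 atom and 4 bond descriptors")

    @property
    def atom_dim(self) -> int:
        return sum(
            1 if cats is None else len(cats) + 1
            for _, cats in self.atom_feature_schema
        )

    @property
    def bond_dim(self) -> int:
        n = 0
        for name, cats in self.bond_feature_schema:
            if cats is None:
                n += 1
            elif name == "bond_type":
                n += len(cats)
            else:
                n += len(cats) + 1
        return n

    def to_dict(self) -> dict:
        return {
            "atom_feature_schema": [[n, list(c) if c else None] for n, c in self.atom_feature_schema],
            "bond_feature_schema": [[n, list(c) if c else None] for n, c in self.bond_feature_schema],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            atom_feature_schema=tuple((n, tuple(c) if c else None) for n, c in d["atom_feature_schema"]),
            bond_feature_schema=tuple((n, tuple(c) if c else None) for n, c in d["bond_feature_schema"]),
        )


def _one_hot(value, categories) -> list[float]:
    v = [0.0] * (len(categories) + 1)
    try:
        v[categories.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


# ---------------------------------------------------------------------------
# records and graphs


@dataclass
class MoleculeRecord:
    """One input molecule with optional macro-pKa labels (pKa units)."""

    record_id: str
    raw_structure: str
    standardized_smiles: str
    acidic_label: Optional[float] = None
    basic_label: Optional[float] = None
    non_neutralizable: bool = False

    def label(self, mode: str) -> Optional[float]:
        return self.acidic_label if mode == "acidic" else self.basic_label


@dataclass
class MoleculeGraph:
    """Heavy-atom graph with per-atom / per-bond feature vectors.

    Atom order follows the canonical SMILES written by the standardizer, so
    site indices are stable across serialization.  ``mol`` retains the RDKit
    molecule for substructure work (fingerprints, distance matrices).
    """

    smiles: str
    elements: list[str]
    atom_features: np.ndarray
    bonds: list[tuple[int, int]]
    bond_features: np.ndarray
    hydrogen_counts: np.ndarray
    formal_charges: np.ndarray
    mol: Chem.Mol = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


@dataclass(frozen=True)
class SiteAnnotation:
    """Acidic site set P and basic site set Q (0-based atom indices)."""

    acidic_sites: frozenset
    basic_sites: frozenset


# ---------------------------------------------------------------------------
# standardization


def _parse(raw: str) -> Chem.Mol:
    if "\n" in raw.strip("\n") or raw.rstrip().endswith("M  END"):
        mol = Chem.MolFromMolBlock(raw)
    else:
        mol = Chem.MolFromSmiles(raw.strip())
    if mol is None:
        raise StructureError(f"could not parse structure: {raw!r}", raw)
    return mol


_UNCHARGER = rdMolStandardize.Uncharger()
_FRAGMENT = rdMolStandardize.LargestFragmentChooser()


def standardize_with_flag(raw: str) -> tuple[str, bool]:
    """Standardize and report whether residual formal charge remains.

    Salts are stripped to the largest covalent fragment, then charges are
    neutralized by adding or removing protons wherever valence allows.
    Charges that cannot be neutralized this way (e.g. quaternary nitrogen)
    are kept and flagged.  Output is canonical SMILES; the map is idempotent.
    """
    mol = _parse(raw)
    if mol.GetNumHeavyAtoms() == 0:
        raise StructureError("empty molecule", raw)
    mol = _FRAGMENT.choose(mol)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise StructureError("empty molecule after salt stripping", raw)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    net_charge = sum(a.GetFormalCharge() for a in mol.GetAtoms())
    return Chem.MolToSmiles(mol), net_charge != 0


def standardize_structure(raw: str) -> str:
    """Canonical, salt-free, neutralized-where-possible SMILES of ``raw``."""
    return standardize_with_flag(raw)[0]


# ---------------------------------------------------------------------------
# graph building


def build_graph(smiles: str, config: FeatureConfig | None = None) -> MoleculeGraph:
    """Featurize a standardized SMILES into a :class:`MoleculeGraph`."""
    config = config or FeatureConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"invalid SMILES: {smiles!r}", smiles)
    mol = Chem.RemoveHs(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise StructureError("molecule has no heavy atoms", smiles)

    elements, feats, h_counts, charges = [], [], [], []
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        h_counts.append(atom.GetTotalNumHs())
        charges.append(atom.GetFormalCharge())
        row: list[float] = []
        for name, cats in config.atom_feature_schema:
            if name == "element":
                row += _one_hot(atom.GetSymbol(), cats)
            elif name == "degree":
                row += _one_hot(atom.GetDegree(), cats)
            elif name == "formal_charge":
                row += _one_hot(atom.GetFormalCharge(), cats)
            elif name == "hybridization":
                row += _one_hot(str(atom.GetHybridization()), cats)
            elif name == "aromatic":
                row.append(1.0 if atom.GetIsAromatic() else 0.0)
            elif name == "total_h":
                row += _one_hot(atom.GetTotalNumHs(), cats)
            elif name == "in_ring":
                row.append(1.0 if atom.IsInRing() else 0.0)
            elif name == "chirality":
                row += _one_hot(str(atom.GetChiralTag()), cats)
            else:  # pragma: no cover - schema is fixed
                raise ValueError(f"unknown atom descriptor {name!r}")
        feats.append(row)

    bonds, bfeats = [], []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        row = []
        for name, cats in config.bond_feature_schema:
            if name == "bond_type":
                v = [0.0] * len(cats)
                bt = str(bond.GetBondType())
                if bt in cats:
                    v[cats.index(bt)] = 1.0
                row += v
            elif name == "conjugated":
                row.append(1.0 if bond.GetIsConjugated() else 0.0)
            elif name == "in_ring":
                row.append(1.0 if bond.IsInRing() else 0.0)
            elif name == "stereo":
                row += _one_hot(str(bond.GetStereo()), cats)
            else:  # pragma: no cover
                raise ValueError(f"unknown bond descriptor {name!r}")
        bfeats.append(row)

    return MoleculeGraph(
        smiles=smiles,
        elements=elements,
        atom_features=np.asarray(feats, dtype=np.float64),
        bonds=bonds,
        bond_features=np.asarray(bfeats, dtype=np.float64).reshape(len(bonds), config.bond_dim),
        hydrogen_counts=np.asarray(h_counts, dtype=np.int64),
        formal_charges=np.asarray(charges, dtype=np.int64),
        mol=mol,
    )


# ---------------------------------------------------------------------------
# site rules


def enumerate_acidic_sites(graph: MoleculeGraph) -> frozenset:
    """P = non-carbon atoms carrying at least one hydrogen."""
    return frozenset(
        i
        for i in range(graph.n_atoms)
        if graph.elements[i] != "C" and graph.hydrogen_counts[i] >= 1
    )


def enumerate_basic_sites(graph: MoleculeGraph) -> frozenset:
    """Q = nitrogen atoms with no positive formal charge."""
    return frozenset(
        i
        for i in range(graph.n_atoms)
        if graph.elements[i] == "N" and graph.formal_charges[i] <= 0
    )


def annotate_sites(graph: MoleculeGraph) -> SiteAnnotation:
    return SiteAnnotation(
        acidic_sites=enumerate_acidic_sites(graph),
        basic_sites=enumerate_basic_sites(graph),
    )


def sites_for_mode(graph: MoleculeGraph, mode: str) -> frozenset:
    if mode == "acidic":
        return enumerate_acidic_sites(graph)
    if mode == "basic":
        return enumerate_basic_sites(graph)
    raise ValueError(f"mode must be 'acidic' or 'basic', got {mode!r}")
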