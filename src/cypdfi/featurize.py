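"""Compound featurization: substructure sets and molecular graphs.

Two modalities are derived from every SMILES string:

* a :class:`SubstructureSet` — the on-bit indices of the compound's binary
  1024-bit radius-2 circular (Morgan/ECFP4) fingerprint, together with the
  bit -> atom-environment provenance needed to map attention weights back
  onto atoms;
* a :class:`MolecularGraph` — the heavy-atom graph with 9 categorical atom
  feature channels and 3 categorical bond feature channels.

Feature vocabularies are fixed and versioned (``VOCAB_VERSION``) so that
saved model checkpoints remain loadable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

VOCAB_VERSION = "1"
N_BITS = 1024
FP_RADIUS = 2

__all__ = [
    "FeaturizationError",
    "CompoundRole",
    "CompoundRecord",
    "SubstructureSet",
    "MolecularGraph",
    "canonicalize_smiles",
    "compute_substructures",
    "build_molecular_graph",
    "map_bits_to_atoms",
    "VOCAB_VERSION",
    "N_BITS",
    "FP_RADIUS",
    "NODE_VOCAB_SIZES",
    "EDGE_VOCAB_SIZES",
]


class FeaturizationError(ValueError):
    """Raised when a SMILES string cannot be featurized."""

    def __init__(self, message: str, smiles: str | None = None):
        self.smiles = smiles
        super().__init__(f"{message}" + (f" (SMILES: {smiles!r})" if smiles is not None else ""))


class CompoundRole(str, Enum):
    DRUG = "drug"
    FOOD = "food"


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    smiles: str
    role: CompoundRole = CompoundRole.DRUG


@dataclass(frozen=True)
class SubstructureSet:
    """On-bits of the 1024-bit radius-2 fingerprint plus provenance.

    ``atom_environments`` maps each bit to the list of (center atom index,
    radius) circular environments that set it.
    """

    bits: tuple[int, ...]
    atom_environments: dict[int, tuple[tuple[int, int], ...]] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.bits)

    def __post_init__(self):
        if len(self.bits) == 0:
            raise FeaturizationError("empty substructure set")
        if list(self.bits) != sorted(set(self.bits)):
            raise ValueError("bits must be strictly increasing")
        if self.bits[0] < 0 or self.bits[-1] >= N_BITS:
            raise ValueError(f"bits must lie in [0, {N_BITS - 1}]")


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph with categorical node and edge feature codes."""

    node_features: np.ndarray  # (n_atoms, 9) int codes
    edge_index: np.ndarray  # (2, n_directed_edges) int
    edge_features: np.ndarray  # (n_directed_edges, 3) int codes

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


# ---------------------------------------------------------------------------
# feature vocabularies (versioned; indices are what the model embeds)
# ---------------------------------------------------------------------------

_CHIRALITY = [
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
]
_HYBRIDIZATION = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
    Chem.HybridizationType.S,
]
_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
_BOND_STEREO = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOANY,
]

# channel order: atomic number, chirality, degree, formal charge, H count,
# radical electrons, hybridization, aromaticity, ring membership
NODE_VOCAB_SIZES = (119, len(_CHIRALITY) + 1, 12, 12, 10, 6, len(_HYBRIDIZATION) + 1, 2, 2)
# channel order: bond type, stereo, conjugation
EDGE_VOCAB_SIZES = (len(_BOND_TYPES) + 1, len(_BOND_STEREO) + 1, 2)


def _code(value, vocab, misc_index):
    try:
        return vocab.index(value)
    except ValueError:
        return misc_index


def _range_code(value: int, lo: int, hi: int) -> int:
    """Map integers in [lo, hi] to [0, hi - lo]; out-of-range to the last code."""
    if lo <= value <= hi:
        return value - lo
    return hi - lo + 1


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise FeaturizationError("empty SMILES string", smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError("unparseable SMILES", smiles)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Canonical SMILES of the largest organic fragment.

    Multi-fragment inputs (salts, solvates) are reduced to the fragment with
    the most heavy atoms (ties: more carbons, then lexicographically smallest
    canonical SMILES); the reduction is logged.
    """
    mol = _parse(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        def keyfun(m):
            n_c = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 6)
            return (m.GetNumHeavyAtoms(), n_c, Chem.MolToSmiles(m))

        best = max(frags, key=keyfun)
        logger.info(
            "multi-fragment SMILES %r reduced to largest fragment %r",
            smiles,
            Chem.MolToSmiles(best),
        )
        mol = best
    return Chem.MolToSmiles(mol)


_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=N_BITS)


def compute_substructures(smiles: str) -> SubstructureSet:
    """On-bits of the binary 1024-bit radius-2 fingerprint with provenance."""
    can = canonicalize_smiles(smiles)
    mol = Chem.MolFromSmiles(can)
    if mol.GetNumHeavyAtoms() == 0:
        raise FeaturizationError("molecule has no heavy atoms", smiles)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    _fp_generator.GetFingerprint(mol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    bits = tuple(sorted(info))
    envs = {b: tuple(info[b]) for b in bits}
    return SubstructureSet(bits=bits, atom_environments=envs)


def build_molecular_graph(smiles: str) -> MolecularGraph:
    """Heavy-atom graph; each bond contributes two directed edges."""
    can = canonicalize_smiles(smiles)
    mol = Chem.MolFromSmiles(can)
    if mol.GetNumHeavyAtoms() == 0:
        raise FeaturizationError("molecule has no heavy atoms", smiles)
    nodes = np.zeros((mol.GetNumAtoms(), 9), dtype=np.int64)
    for i, atom in enumerate(mol.GetAtoms()):
        nodes[i] = (
            _range_code(atom.GetAtomicNum(), 1, 117),
            _code(atom.GetChiralTag(), _CHIRALITY, len(_CHIRALITY)),
            _range_code(atom.GetTotalDegree(), 0, 10),
            _range_code(atom.GetFormalCharge(), -5, 5),
            _range_code(atom.GetTotalNumHs(), 0, 8),
            _range_code(atom.GetNumRadicalElectrons(), 0, 4),
            _code(atom.GetHybridization(), _HYBRIDIZATION, len(_HYBRIDIZATION)),
            int(atom.GetIsAromatic()),
            int(atom.IsInRing()),
        )
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        codes = (
            _code(bond.GetBondType(), _BOND_TYPES, len(_BOND_TYPES)),
            _code(bond.GetStereo(), _BOND_STEREO, len(_BOND_STEREO)),
            int(bond.GetIsConjugated()),
        )
        src.extend((u, v))
        dst.extend((v, u))
        efeat.extend((codes, codes))
    edge_index = np.asarray([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = (
        np.asarray(efeat, dtype=np.int64).reshape(-1, 3) if efeat else np.zeros((0, 3), dtype=np.int64)
    )
    return MolecularGraph(node_features=nodes, edge_index=edge_index, edge_features=edge_features)


def map_bits_to_atoms(s: SubstructureSet, smiles: str, bits: list[int]) -> dict[int, set[int]]:
    """Atoms covered by each requested bit's circular environments.

    Each environment contributes its center atom plus every atom reachable
    within the environment radius.
    """
    can = canonicalize_smiles(smiles)
    mol = Chem.MolFromSmiles(can)
    n_atoms = mol.GetNumAtoms()
    result: dict[int, set[int]] = {}
    for bit in bits:
        if bit not in s.atom_environments:
            raise KeyError(f"bit {bit} is not present in this compound's substructure set")
        atoms: set[int] = set()
        for center, radius in s.atom_environments[bit]:
            if center >= n_atoms:
                raise ValueError(f"environment center {center} outside molecule")
            if radius == 0:
                atoms.add(center)
                continue
            bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
            atoms.add(center)
            for bid in bond_ids:
                b = mol.GetBondWithIdx(bid)
                atoms.add(b.GetBeginAtomIdx())
                atoms.add(b.GetEndAtomIdx())
        result[bit] = atoms
    return result
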