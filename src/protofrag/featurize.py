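"""SMILES → attributed graph featurization.

Heavy-atom graphs only: hydrogens enter as a total-H count feature rather
than as explicit nodes, the common convention for molecular property
prediction.  The vocabulary below is the package default; every list is
configurable and the feature dimensions d1/d2 are derived from the config,
so synthetic graph generators can emit vectors from the same scheme without
going through a chemistry toolkit.

Atom features: element one-hot (fixed list + "other" bucket), degree
one-hot, formal charge, hybridization one-hot, aromatic flag, total-H
one-hot, chirality tag one-hot.  Bond features: bond-type one-hot,
conjugation flag, ring flag, stereo one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .graphs import MolecularGraph

RDLogger.DisableLog("rdApp.*")  # rdkit warns loudly on odd but parsable SMILES

__all__ = ["FeatureConfig", "SmilesParseError", "EmptyMoleculeError",
           "featurize_smiles", "atom_feature_vector", "bond_feature_vector"]


class SmilesParseError(ValueError):
    pass


class EmptyMoleculeError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    elements: tuple = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    max_degree: int = 5
    hybridizations: tuple = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
    max_num_h: int = 4
    chirality_tags: tuple = ("CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW",
                             "CHI_TETRAHEDRAL_CCW", "CHI_OTHER")
    bond_types: tuple = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
    stereo_tags: tuple = ("STEREONONE", "STEREOANY", "STEREOZ", "STEREOE",
                          "STEREOCIS", "STEREOTRANS")

    @property
    def atom_dim(self) -> int:
        return (len(self.elements) + 1 + (self.max_degree + 1) + 1
                + len(self.hybridizations) + 1 + 1 + (self.max_num_h + 1)
                + len(self.chirality_tags))

    @property
    def bond_dim(self) -> int:
        return len(self.bond_types) + 1 + 1 + 1 + len(self.stereo_tags)


def _one_hot(value, choices, other_bucket: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if other_bucket:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def atom_feature_vector(cfg: FeatureConfig, element: str, degree: int,
                        formal_charge: int = 0, hybridization: str = "SP3",
                        aromatic: bool = False, num_h: int = 0,
                        chirality: str = "CHI_UNSPECIFIED") -> np.ndarray:
    """Feature vector from categorical atom attributes (toolkit-free path)."""
    vec = _one_hot(element, cfg.elements)
    vec += _one_hot(min(degree, cfg.max_degree), range(cfg.max_degree + 1),
                    other_bucket=False)
    vec.append(float(formal_charge))
    vec += _one_hot(hybridization, cfg.hybridizations)
    vec.append(1.0 if aromatic else 0.0)
    vec += _one_hot(min(num_h, cfg.max_num_h), range(cfg.max_num_h + 1),
                    other_bucket=False)
    vec += _one_hot(chirality, cfg.chirality_tags, other_bucket=False)
    out = np.asarray(vec, dtype=np.float64)
    assert out.shape[0] == cfg.atom_dim
    return out


def bond_feature_vector(cfg: FeatureConfig, bond_type: str = "SINGLE",
                        conjugated: bool = False, in_ring: bool = False,
                        stereo: str = "STEREONONE") -> np.ndarray:
    vec = _one_hot(bond_type, cfg.bond_types)
    vec.append(1.0 if conjugated else 0.0)
    vec.append(1.0 if in_ring else 0.0)
    vec += _one_hot(stereo, cfg.stereo_tags, other_bucket=False)
    out = np.asarray(vec, dtype=np.float64)
    assert out.shape[0] == cfg.bond_dim
    return out


def featurize_smiles(smiles: str, feature_config: FeatureConfig | None = None,
                     mol_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph` over heavy atoms.

    Raises :class:`SmilesParseError` for unparsable input and
    :class:`EmptyMoleculeError` when no heavy atoms remain.
    """
    cfg = feature_config or FeatureConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError(f"SMILES yields no heavy atoms: {smiles!r}")

    X = np.stack([
        atom_feature_vector(
            cfg,
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            hybridization=str(a.GetHybridization()),
            aromatic=a.GetIsAromatic(),
            num_h=a.GetTotalNumHs(),
            chirality=str(a.GetChiralTag()),
        )
        for a in mol.GetAtoms()
    ])

    edges, efeats = [], []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        edges.append((min(u, v), max(u, v)))
        efeats.append(bond_feature_vector(
            cfg,
            bond_type=str(b.GetBondType()),
            conjugated=b.GetIsConjugated(),
            in_ring=b.IsInRing(),
            stereo=str(b.GetStereo()),
        ))
    E = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    EF = (np.stack(efeats) if efeats
          else np.zeros((0, cfg.bond_dim), dtype=np.float64))
    return MolecularGraph(node_features=X, edge_index=E, edge_features=EF,
                          mol_id=mol_id if mol_id is not None else smiles)
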