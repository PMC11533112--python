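"""Table loading and deterministic dataset splitting.

Supports the two split strategies standard in molecular property
prediction: uniform random, and scaffold splitting, which groups molecules
by their Bemis–Murcko core so that structurally similar molecules never
straddle the train/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .featurize import FeatureConfig, SmilesParseError, EmptyMoleculeError, featurize_smiles
from .graphs import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "SchemaError", "EmptyDatasetError",
           "load_labeled_table", "split_dataset", "bemis_murcko_scaffold"]


class SchemaError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Ratios, strategy ("random" | "scaffold") and seed for a 3-way split."""

    ratios: tuple = (0.8, 0.1, 0.1)
    strategy: str = "random"
    seed: int = 0

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three nonnegative numbers")
        if abs(sum(self.ratios) - 1.0) > 1e-8:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")
        if self.strategy not in ("random", "scaffold"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")


def load_labeled_table(path, smiles_column: str = "smiles",
                       label_columns: list[str] | None = None,
                       task_type: str = "classification",
                       feature_config: FeatureConfig | None = None,
                       ) -> tuple[LabeledDataset, list[dict]]:
    """Read a CSV/TSV of SMILES (+ optional label columns) into a dataset.

    Returns ``(dataset, skipped)`` where ``skipped`` reports rows whose
    SMILES failed to parse (they are logged, not fatal).  Blank label cells
    become masked entries, never dropped rows.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    label_columns = list(label_columns or [])
    missing = [c for c in [smiles_column, *label_columns] if c not in df.columns]
    if missing:
        raise SchemaError(f"columns not found in {path}: {missing}")
    for c in label_columns:
        vals = pd.to_numeric(df[c], errors="coerce")
        if df[c].notna().sum() and vals.isna().sum() > df[c].isna().sum():
            raise SchemaError(f"label column {c!r} contains non-numeric entries")
        df[c] = vals

    cfg = feature_config or FeatureConfig()
    graphs, skipped = [], []
    for i, row in df.iterrows():
        smi = row[smiles_column]
        try:
            g = featurize_smiles(str(smi), cfg, mol_id=str(smi))
        except (SmilesParseError, EmptyMoleculeError) as err:
            skipped.append({"row": int(i), "smiles": smi, "reason": str(err)})
            continue
        if label_columns:
            y = np.array([row[c] for c in label_columns], dtype=np.float64)
            g.labels = y
            g.label_mask = ~np.isnan(y)
        graphs.append(g)
    if skipped:
        logger.warning("skipped %d unparsable rows out of %d", len(skipped), len(df))
    if not graphs:
        raise EmptyDatasetError(f"no parsable SMILES rows in {path}")
    return LabeledDataset(graphs, label_columns, task_type), skipped


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis–Murcko scaffold SMILES ("" for acyclic molecules)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return ""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol, includeChirality=False)


def _target_sizes(n: int, ratios) -> list[int]:
    # floor valid/test, remainder to train (rounding toward train)
    n_valid = int(n * ratios[1])
    n_test = int(n * ratios[2])
    return [n - n_valid - n_test, n_valid, n_test]


def split_dataset(ds: LabeledDataset, spec: SplitSpec
                  ) -> tuple[list[int], list[int], list[int]]:
    """Disjoint, exhaustive train/valid/test index lists.

    Random: a seeded permutation cut at the ratio boundaries.  Scaffold:
    scaffold groups sorted by (size desc, scaffold string) and greedily
    assigned to the subset with the most remaining capacity; one scaffold
    never spans two subsets.  Deterministic for fixed inputs and seed.
    """
    n = len(ds)
    if n == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    sizes = _target_sizes(n, spec.ratios)

    if spec.strategy == "random":
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(n)
        a, b = sizes[0], sizes[0] + sizes[1]
        return (sorted(perm[:a].tolist()), sorted(perm[a:b].tolist()),
                sorted(perm[b:].tolist()))

    groups: dict[str, list[int]] = {}
    for i, g in enumerate(ds.graphs):
        groups.setdefault(bemis_murcko_scaffold(g.mol_id), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    subsets: list[list[int]] = [[], [], []]
    for _, idxs in ordered:
        remaining = [sizes[j] - len(subsets[j]) for j in range(3)]
        j = int(np.argmax(remaining))
        subsets[j].extend(idxs)
    return tuple(sorted(s) for s in subsets)
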