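"""Reading labeled molecule tables, graph featurization and scaffold splits.

Datasets are delimited text files (CSV/TSV) with one SMILES column and one
or more label columns; the MoleculeNet CSV layout is accepted unchanged.
Missing label cells are stored as 0 with ``observed=False`` so that loss
masking is explicit rather than hidden in NaN propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConfigurationError, DataError, FeaturizationError, SplitError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

# Fixed categorical vocabularies for the featurization; versioned with the
# package because principal gradients are only comparable across datasets
# featurized identically.
FEATURE_VOCAB_VERSION = "1"
NUM_ATOM_TYPES = 119  # atomic numbers 1..118, index z-1; 118 = unknown/other
CHIRALITY_TAGS = (
    Chem.rdchem.ChiralType.CHI_UNSPECIFIED,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CCW,
)
NUM_CHIRALITY_TAGS = 4  # the three above + "other"
BOND_TYPES = (
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
)
NUM_BOND_TYPES = 4
BOND_DIRECTIONS = (
    Chem.rdchem.BondDir.NONE,
    Chem.rdchem.BondDir.ENDUPRIGHT,
    Chem.rdchem.BondDir.ENDDOWNRIGHT,
)
NUM_BOND_DIRECTIONS = 3


@dataclass(frozen=True)
class TaskSpec:
    """What kind of prediction problem a dataset poses."""

    task_type: str  # "classification" | "regression"
    n_subtasks: int
    name: str = "task"

    def __post_init__(self):
        if self.task_type not in ("classification", "regression"):
            raise ConfigurationError(f"unknown task_type {self.task_type!r}")
        if self.n_subtasks < 1:
            raise ConfigurationError("n_subtasks must be positive")


@dataclass
class MoleculeRecord:
    """One molecule with a per-subtask label vector and observed mask."""

    smiles: str
    labels: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.labels.shape != self.observed.shape:
            raise DataError("labels and observed mask must have equal length")


@dataclass
class MolecularGraph:
    """Featurized 2D molecular graph.

    ``node_features`` is (n_atoms, 2): atomic-number index and chirality
    index.  ``edge_features`` is (n_arcs, 2): bond-type index and bond-
    direction index.  Every bond is stored as two directed arcs, so
    ``edge_src``/``edge_dst`` have length 2 * n_bonds.
    """

    node_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_features: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_arcs(self) -> int:
        return self.edge_src.shape[0]


def canonical_smiles(smiles: str) -> str | None:
    """Canonical form of *smiles*, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def featurize(record: MoleculeRecord | str) -> MolecularGraph:
    """Turn a SMILES (or record) into a :class:`MolecularGraph`.

    Deterministic: the same SMILES always yields byte-identical arrays.
    """
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise FeaturizationError(smiles)
    node_feat = np.empty((mol.GetNumAtoms(), 2), dtype=np.int64)
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        zi = z - 1 if 1 <= z <= 118 else NUM_ATOM_TYPES - 1
        tag = atom.GetChiralTag()
        ci = CHIRALITY_TAGS.index(tag) if tag in CHIRALITY_TAGS else NUM_CHIRALITY_TAGS - 1
        node_feat[atom.GetIdx()] = (zi, ci)
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        ti = BOND_TYPES.index(bt) if bt in BOND_TYPES else 0
        bd = bond.GetBondDir()
        di = BOND_DIRECTIONS.index(bd) if bd in BOND_DIRECTIONS else 0
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
        efeat += [(ti, di), (ti, di)]
    return MolecularGraph(
        node_features=node_feat,
        edge_src=np.asarray(src, dtype=np.int64),
        edge_dst=np.asarray(dst, dtype=np.int64),
        edge_features=np.asarray(efeat, dtype=np.int64).reshape(-1, 2),
    )


def read_molecule_table(
    path,
    smiles_column: str = "smiles",
    label_columns: list[str] | None = None,
    task_type: str = "classification",
    name: str | None = None,
) -> tuple[list[MoleculeRecord], TaskSpec]:
    """Load a delimited molecule table into records plus a task spec.

    Rows whose SMILES does not parse are dropped (and counted in the log);
    blank/NaN label cells become ``observed=False`` with a 0 placeholder.
    SMILES are canonicalized at load so round-trips are well defined.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if smiles_column not in df.columns:
        raise ConfigurationError(f"SMILES column {smiles_column!r} not in {list(df.columns)}")
    if label_columns is None:
        label_columns = [c for c in df.columns if c != smiles_column]
    missing = [c for c in label_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"label columns not found: {missing}")
    records: list[MoleculeRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        can = canonical_smiles(str(row[smiles_column]))
        if can is None:
            n_rejected += 1
            continue
        raw = pd.to_numeric(row[label_columns], errors="coerce").to_numpy(dtype=np.float64)
        observed = np.isfinite(raw)
        labels = np.where(observed, raw, 0.0)
        records.append(MoleculeRecord(smiles=can, labels=labels, observed=observed))
    if n_rejected:
        logger.info("dropped %d rows with unparseable SMILES from %s", n_rejected, path)
    if not records:
        raise DataError(f"no parseable rows in {path}")
    spec = TaskSpec(
        task_type=task_type,
        n_subtasks=len(label_columns),
        name=name or str(path),
    )
    return records, spec


def write_molecule_table(path, records: list[MoleculeRecord], label_names: list[str] | None = None,
                         smiles_column: str = "smiles") -> None:
    """Write records as a CSV that :func:`read_molecule_table` round-trips."""
    n_sub = len(records[0].labels)
    label_names = label_names or [f"y{i}" for i in range(n_sub)]
    data = {smiles_column: [r.smiles for r in records]}
    for j, col in enumerate(label_names):
        data[col] = [r.labels[j] if r.observed[j] else np.nan for r in records]
    pd.DataFrame(data).to_csv(path, index=False)


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=False)


def scaffold_split(
    records: list[MoleculeRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    allow_random_fallback: bool = False,
) -> tuple[list[int], list[int], list[int]]:
    """Deterministic Bemis-Murcko scaffold split into train/valid/test.

    Molecules sharing a scaffold never straddle partitions.  Scaffold groups
    are sorted by (descending size, lexicographically smallest member SMILES)
    and assigned greedily: to train until the train quota is met, then to
    validation, then to test.  The seed only breaks exact ties, so splits are
    reproducible across runs and platforms.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ConfigurationError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ConfigurationError(f"ratios must sum to 1, got {sum(ratios)}")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(murcko_scaffold(rec.smiles), []).append(i)
    if len(groups) < 3:
        if not allow_random_fallback:
            raise SplitError(
                f"only {len(groups)} scaffold group(s); scaffold split impossible "
                "(pass allow_random_fallback=True for a random split)"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        n = len(records)
        n_train = int(round(ratios[0] * n))
        n_valid = int(round(ratios[1] * n))
        return (
            sorted(order[:n_train].tolist()),
            sorted(order[n_train:n_train + n_valid].tolist()),
            sorted(order[n_train + n_valid:].tolist()),
        )
    keyed = []
    for scaf, idx in groups.items():
        smallest = min(records[i].smiles for i in idx)
        keyed.append((-len(idx), smallest, scaf, idx))
    rng = np.random.default_rng(seed)
    rng.shuffle(keyed)  # only reorders exact (size, smiles) ties
    keyed.sort(key=lambda t: (t[0], t[1]))
    n = len(records)
    train_quota = ratios[0] * n
    valid_quota = (ratios[0] + ratios[1]) * n
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for _, _, _, idx in keyed:
        if len(train) < train_quota:
            train.extend(idx)
        elif len(train) + len(valid) < valid_quota:
            valid.extend(idx)
        else:
            test.extend(idx)
    if not valid or not test:
        raise SplitError("scaffold granularity too coarse to fill all partitions")
    return sorted(train), sorted(valid), sorted(test)


def write_split(path, records, train, valid, test) -> None:
    """Persist a split as three-column text: index, partition, scaffold."""
    rows = []
    for part, idx in (("train", train), ("valid", valid), ("test", test)):
        for i in idx:
            rows.append((i, part, murcko_scaffold(records[i].smiles)))
    rows.sort()
    pd.DataFrame(rows, columns=["index", "partition", "scaffold"]).to_csv(path, index=False)
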