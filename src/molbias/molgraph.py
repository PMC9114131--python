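"""Molecular-graph data model, vocabularies, encodings and dataset I/O.

A molecule is a connected labeled graph: typed atoms as nodes and typed
bonds (single / double / triple / aromatic) as undirected edges stored
once with ``u < v``. Scalar properties (the regression target plus any
auxiliary columns such as a HOMO-LUMO-gap-like quantity) live in a
:class:`PropertyTable` keyed by molecule id.

Two on-disk formats are supported: a native JSON-lines dialect (one
molecule per line, plus a leading ``_meta`` header carrying the
vocabularies) used throughout the test fixtures, and CSV files of SMILES
strings with numeric property columns for real datasets (parsed with
RDKit; explicit hydrogens are added so that atom counts match the
all-atom convention of small-molecule benchmark sets).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

BOND_TYPES = ("single", "double", "triple", "aromatic")

__all__ = [
    "BOND_TYPES",
    "MolecularGraph",
    "PropertyTable",
    "Dataset",
    "validate_graph",
    "encode_atoms",
    "decode_atoms",
    "read_jsonl",
    "write_jsonl",
    "read_smiles_csv",
]


@dataclass
class MolecularGraph:
    """A typed, undirected, connected molecular graph.

    ``nodes`` holds atom-type codes (strings from the dataset's atom
    vocabulary); ``edges`` holds ``(u, v, bond_type)`` with ``u < v``.
    """

    id: str
    nodes: list
    edges: list

    @property
    def n_atoms(self) -> int:
        return len(self.nodes)

    @property
    def n_bonds(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int):
        for a, b, _ in self.edges:
            if a == v:
                yield b
            elif b == v:
                yield a


class PropertyTable:
    """Per-molecule scalar properties: id -> {property name -> value}."""

    def __init__(self, values: dict | None = None):
        self._values: dict[str, dict[str, float]] = {k: dict(v) for k, v in (values or {}).items()}

    def get(self, mol_id: str, name: str) -> float:
        return self._values[mol_id][name]

    def set(self, mol_id: str, name: str, value: float):
        if not np.isfinite(value):
            raise ValueError(f"non-finite property {name!r} for molecule {mol_id!r}")
        self._values.setdefault(mol_id, {})[name] = float(value)

    def row(self, mol_id: str) -> dict:
        return dict(self._values.get(mol_id, {}))

    def column(self, name: str, ids) -> np.ndarray:
        return np.array([self._values[i][name] for i in ids], dtype=float)

    def names(self) -> list:
        names: set[str] = set()
        for row in self._values.values():
            names.update(row)
        return sorted(names)

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._values

    def __eq__(self, other) -> bool:
        return isinstance(other, PropertyTable) and self._values == other._values


@dataclass
class Dataset:
    """Graphs + properties + the vocabularies covering their codes."""

    graphs: list
    properties: PropertyTable = field(default_factory=PropertyTable)
    atom_vocab: tuple = ()
    bond_vocab: tuple = BOND_TYPES

    def __post_init__(self):
        ids = [g.id for g in self.graphs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids in dataset")
        self._by_id = {g.id: g for g in self.graphs}

    def __len__(self) -> int:
        return len(self.graphs)

    def graph(self, mol_id: str) -> MolecularGraph:
        return self._by_id[mol_id]

    def ids(self) -> list:
        return [g.id for g in self.graphs]

    def subset(self, ids) -> "Dataset":
        return Dataset(
            graphs=[self._by_id[i] for i in ids],
            properties=self.properties,
            atom_vocab=self.atom_vocab,
            bond_vocab=self.bond_vocab,
        )

    def target(self, name: str) -> np.ndarray:
        return self.properties.column(name, self.ids())


def validate_graph(g: MolecularGraph) -> list:
    """Return one human-readable description per violated invariant.

    An empty list means the graph is well-formed: at least one node, all
    edge endpoints in range, no self-loops or duplicate edges, known bond
    types, and a single connected component.
    """
    violations = []
    n = len(g.nodes)
    if n < 1:
        violations.append("graph has no nodes")
        return violations
    seen = set()
    adj: dict[int, list] = {v: [] for v in range(n)}
    for e in g.edges:
        u, v, bond = e
        if not (0 <= u < n and 0 <= v < n):
            violations.append(f"edge endpoint out of range: ({u}, {v})")
            continue
        if u == v:
            violations.append(f"self-loop at node {u}")
            continue
        if not u < v:
            violations.append(f"edge ({u}, {v}) not stored with u < v")
        key = (min(u, v), max(u, v))
        if key in seen:
            violations.append(f"duplicate edge {key}")
        seen.add(key)
        if bond not in BOND_TYPES:
            violations.append(f"unknown bond type {bond!r} on edge {key}")
        adj[u].append(v)
        adj[v].append(u)
    # connectivity by BFS from node 0
    if n > 1:
        reached = {0}
        frontier = [0]
        while frontier:
            nxt = []
            for v in frontier:
                for u in adj[v]:
                    if u not in reached:
                        reached.add(u)
                        nxt.append(u)
            frontier = nxt
        if len(reached) < n:
            violations.append("graph not connected")
    return violations


def encode_atoms(g: MolecularGraph, vocab) -> np.ndarray:
    """One-hot encode atom types: row ``v`` is the indicator of node v's type."""
    index = {code: i for i, code in enumerate(vocab)}
    out = np.zeros((len(g.nodes), len(vocab)), dtype=np.float64)
    for row, code in enumerate(g.nodes):
        try:
            out[row, index[code]] = 1.0
        except KeyError:
            raise KeyError(f"atom code {code!r} not in vocabulary {tuple(vocab)}") from None
    return out


def decode_atoms(features: np.ndarray, vocab) -> list:
    """Inverse of :func:`encode_atoms` on valid one-hot input."""
    return [vocab[j] for j in np.argmax(features, axis=1)]


# --------------------------------------------------------------------- JSONL
def write_jsonl(ds: Dataset, path):
    with open(path, "w") as fh:
        meta = {"_meta": {"atom_vocab": list(ds.atom_vocab), "bond_vocab": list(ds.bond_vocab)}}
        fh.write(json.dumps(meta, sort_keys=True) + "\n")
        for g in ds.graphs:
            rec = {
                "id": g.id,
                "nodes": list(g.nodes),
                "edges": [[int(u), int(v), b] for (u, v, b) in g.edges],
                "properties": ds.properties.row(g.id),
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_jsonl(path) -> Dataset:
    graphs = []
    props = PropertyTable()
    atom_vocab: tuple = ()
    bond_vocab: tuple = BOND_TYPES
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            if "_meta" in rec:
                atom_vocab = tuple(rec["_meta"].get("atom_vocab", ()))
                bond_vocab = tuple(rec["_meta"].get("bond_vocab", BOND_TYPES))
                continue
            g = MolecularGraph(
                id=rec["id"],
                nodes=list(rec["nodes"]),
                edges=[(int(u), int(v), b) for u, v, b in rec["edges"]],
            )
            graphs.append(g)
            for name, value in rec.get("properties", {}).items():
                props.set(g.id, name, value)
    if not atom_vocab:
        atom_vocab = tuple(sorted({c for g in graphs for c in g.nodes}))
    return Dataset(graphs=graphs, properties=props, atom_vocab=atom_vocab, bond_vocab=bond_vocab)


# ---------------------------------------------------------------------- SMILES
_RDKIT_BOND = {"SINGLE": "single", "DOUBLE": "double", "TRIPLE": "triple", "AROMATIC": "aromatic"}


def read_smiles_csv(path, target_column: str, aux_columns=(), smiles_column: str = "smiles") -> Dataset:
    """Load a SMILES CSV into a :class:`Dataset` (explicit hydrogens added).

    Rows whose SMILES fails to parse are skipped; the skip count is logged.
    Raises if required columns are missing or no row parses.
    """
    import pandas as pd

    try:
        from rdkit import Chem
    except ImportError as err:  # pragma: no cover - rdkit is an optional extra
        raise ImportError("read_smiles_csv requires rdkit (install molbias[chem])") from err

    frame = pd.read_csv(path)
    needed = [smiles_column, target_column, *aux_columns]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise KeyError(f"missing columns in {path}: {missing}")

    graphs = []
    props = PropertyTable()
    atom_codes: set[str] = set()
    skipped = 0
    for row_idx, row in frame.iterrows():
        mol = Chem.MolFromSmiles(str(row[smiles_column]))
        if mol is None:
            skipped += 1
            continue
        mol = Chem.AddHs(mol)
        nodes = [atom.GetSymbol() for atom in mol.GetAtoms()]
        edges = []
        for bond in mol.GetBonds():
            u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            u, v = min(u, v), max(u, v)
            edges.append((u, v, _RDKIT_BOND.get(str(bond.GetBondType()), "single")))
        gid = f"row{row_idx}"
        graphs.append(MolecularGraph(id=gid, nodes=nodes, edges=sorted(edges)))
        atom_codes.update(nodes)
        props.set(gid, target_column, float(row[target_column]))
        for col in aux_columns:
            props.set(gid, col, float(row[col]))
    if not graphs:
        raise ValueError(f"no parseable SMILES rows in {path}")
    if skipped:
        logger.warning("skipped %d unparseable SMILES rows in %s", skipped, path)
    ds = Dataset(graphs=graphs, properties=props, atom_vocab=tuple(sorted(atom_codes)))
    ds.skipped_rows = skipped
    return ds
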