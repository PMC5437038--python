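"""Structure and ensemble I/O.

Reads single- and multi-MODEL PDB files into lightweight snapshot objects,
resolves atom selections with a small selection mini-language, and writes
product-distribution reports as JSON plus a flat CSV table.

Selection mini-language
-----------------------
Boolean expressions over five atom properties::

    chain <id> [<id> ...]       e.g.  chain A B
    resname <name> [...]        e.g.  resname LNR HOH
    resid <n | a:b> [...]       e.g.  resid 10 12 100:120
    name <atom name> [...]      e.g.  name CA CB
    element <symbol> [...]      e.g.  element Fe

combined with ``and``, ``or``, ``not`` and parentheses; ``and`` binds
tighter than ``or``.  Multiple values after one keyword are an implicit
``or``.  Example: ``name CA and chain A``.

Policy choices: alternate locations keep the blank or ``A`` conformer and
drop the rest; hydrogens are parsed and retained; coordinates are in Å and
residue numbering follows the file (PDB convention).
"""

from __future__ import annotations

import csv
import glob as _glob
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Snapshot",
    "TrajectoryEnsemble",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "write_ensemble_pdb",
    "select_atoms",
    "annotate",
    "annotate_ensemble",
    "write_report",
    "read_report",
]

# Bond-length window (Å) accepted between consecutive pentadiene carbons.
PENTADIENE_BOND_MIN = 1.2
PENTADIENE_BOND_MAX = 1.8

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_WATER = {"HOH", "WAT", "H2O", "DOD"}


@dataclass(eq=False)
class AtomRecord:
    """One atom of one model: identity, residue context and position (Å)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    model_index: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def is_protein(self) -> bool:
        return self.residue_name in _STANDARD_AA

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER


@dataclass
class Snapshot:
    """One coordinate frame, optionally annotated with the substrate
    pentadiene carbons (C9..C13, in chain order) and the catalytic iron."""

    atoms: list[AtomRecord]
    pentadiene_ids: tuple[int, ...] | None = None
    iron_id: int | None = None
    label: str = ""
    _index: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._reindex()
        if self.pentadiene_ids is not None or self.iron_id is not None:
            self.validate_annotations()

    def _reindex(self) -> None:
        self._index = {}
        for i, atom in enumerate(self.atoms):
            if atom.serial in self._index:
                raise ValueError(f"duplicate atom serial {atom.serial} within model")
            self._index[atom.serial] = i

    def atom(self, serial: int) -> AtomRecord:
        try:
            return self.atoms[self._index[serial]]
        except KeyError:
            raise KeyError(f"no atom with serial {serial}") from None

    def position(self, serial: int) -> np.ndarray:
        return self.atom(serial).position

    def coordinates(self) -> np.ndarray:
        """All atom positions, shape (n_atoms, 3), file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def pentadiene_positions(self) -> np.ndarray:
        if self.pentadiene_ids is None:
            raise ValueError("snapshot has no pentadiene annotation")
        return np.array([self.position(s) for s in self.pentadiene_ids])

    def iron_position(self) -> np.ndarray:
        if self.iron_id is None:
            raise ValueError("snapshot has no iron annotation")
        return self.position(self.iron_id)

    def substrate_residues(self) -> set[tuple[str, int]]:
        """(chain, resid) keys of residues holding pentadiene atoms."""
        if self.pentadiene_ids is None:
            return set()
        return {
            (self.atom(s).chain_id, self.atom(s).residue_number)
            for s in self.pentadiene_ids
        }

    def validate_annotations(self) -> None:
        if self.pentadiene_ids is not None:
            ids = tuple(self.pentadiene_ids)
            if len(ids) != 5 or len(set(ids)) != 5:
                raise ValueError("pentadiene_ids must be 5 distinct atom serials")
            pos = np.array([self.position(s) for s in ids])
            bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            if np.any(bonds < PENTADIENE_BOND_MIN) or np.any(bonds > PENTADIENE_BOND_MAX):
                raise ValueError(
                    "consecutive pentadiene carbons must lie "
                    f"{PENTADIENE_BOND_MIN}-{PENTADIENE_BOND_MAX} Å apart; got {bonds}"
                )
        if self.iron_id is not None:
            self.atom(self.iron_id)

    def topology_key(self) -> tuple[tuple[int, str], ...]:
        return tuple((a.serial, a.name) for a in self.atoms)


@dataclass
class TrajectoryEnsemble:
    """Ordered snapshots sharing one atom topology (one MD replicate)."""

    snapshots: list[Snapshot]
    replicate_label: str = ""

    def __post_init__(self) -> None:
        if not self.snapshots:
            raise ValueError("ensemble must contain at least one snapshot")
        key = self.snapshots[0].topology_key()
        for i, snap in enumerate(self.snapshots[1:], start=1):
            if snap.topology_key() != key:
                raise ValueError(f"snapshot {i} topology differs from snapshot 0")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)


# ---------------------------------------------------------------------------
# PDB reading / writing (via gemmi)
# ---------------------------------------------------------------------------

def _model_to_snapshot(model: gemmi.Model, model_index: int, label: str) -> Snapshot:
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # keep blank/'A' conformer only
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        chain_id=chain.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        model_index=model_index,
                    )
                )
    if not atoms:
        raise ValueError(f"model {model_index} of {label!r} contains zero atoms")
    return Snapshot(atoms=atoms, label=f"{label}#{model_index}")


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as PDB: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")
    return structure


def read_structure(path: str | Path, model: int | None = None) -> Snapshot:
    """Read one model of a PDB file.

    ``model`` is the 1-based position of the MODEL block; ``None`` reads the
    first model.  ATOM and HETATM records are both parsed; altlocs other
    than blank/'A' are dropped.
    """
    structure = _read_gemmi(path)
    index = 0 if model is None else model - 1
    if index < 0 or index >= len(structure):
        raise ValueError(
            f"{path}: requested model {model} but file has {len(structure)} model(s)"
        )
    return _model_to_snapshot(structure[index], index, Path(path).stem)


def read_trajectory(path: str | Path | Sequence[str | Path]) -> TrajectoryEnsemble:
    """Read a snapshot ensemble.

    Accepts one multi-model PDB, a glob pattern, or an explicit ordered list
    of single-model PDB paths.  Topology consistency across models is
    enforced by :class:`TrajectoryEnsemble`.
    """
    if isinstance(path, (list, tuple)):
        files = [Path(p) for p in path]
        label = files[0].stem if files else ""
    else:
        text = str(path)
        if _glob.has_magic(text):
            files = [Path(p) for p in sorted(_glob.glob(text))]
            if not files:
                raise FileNotFoundError(f"pattern {text!r} matched no files")
            label = text
        else:
            structure = _read_gemmi(text)
            label = Path(text).stem
            snaps = [
                _model_to_snapshot(structure[i], i, label)
                for i in range(len(structure))
            ]
            return TrajectoryEnsemble(snapshots=snaps, replicate_label=label)
    snaps = []
    for i, f in enumerate(files):
        snap = read_structure(f)
        snap.label = f"{label}#{i}"
        for atom in snap.atoms:
            atom.model_index = i
        snaps.append(snap)
    return TrajectoryEnsemble(snapshots=snaps, replicate_label=label)


def write_ensemble_pdb(ensemble: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (coordinates at the
    format's 1e-3 Å precision)."""
    structure = gemmi.Structure()
    structure.name = ensemble.replicate_label or "ensemble"
    for snap in ensemble:
        model = gemmi.Model(len(structure) + 1)
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple[str, int, str], gemmi.Residue] = {}
        for atom in snap.atoms:
            chain = chains.get(atom.chain_id)
            if chain is None:
                chain = gemmi.Chain(atom.chain_id)
                chains[atom.chain_id] = chain
                model.add_chain(chain)
                chain = model[len(model) - 1]
                chains[atom.chain_id] = chain
            key = (atom.chain_id, atom.residue_number, atom.residue_name)
            residue = residues.get(key)
            if residue is None:
                residue = gemmi.Residue()
                residue.name = atom.residue_name
                residue.seqid = gemmi.SeqId(atom.residue_number, " ")
                residue.het_flag = "A" if atom.residue_name in _STANDARD_AA else "H"
                chain.add_residue(residue)
                residue = chain[len(chain) - 1]
                residues[key] = residue
            gatom = gemmi.Atom()
            gatom.name = atom.name
            gatom.serial = atom.serial
            gatom.element = gemmi.Element(atom.element)
            gatom.pos = gemmi.Position(*atom.position)
            gatom.occ = 1.0
            residue.add_atom(gatom)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def annotate(
    snapshot: Snapshot, pentadiene_ids: Sequence[int], iron_id: int
) -> Snapshot:
    """Return a copy of ``snapshot`` with validated substrate annotations."""
    return replace(
        snapshot,
        atoms=snapshot.atoms,
        pentadiene_ids=tuple(pentadiene_ids),
        iron_id=iron_id,
    )


def annotate_ensemble(
    ensemble: TrajectoryEnsemble,
    pentadiene_spec: str,
    iron_spec: str,
) -> TrajectoryEnsemble:
    """Annotate every snapshot via selection expressions.

    ``pentadiene_spec`` must select exactly 5 atoms (C9..C13, ascending
    serial order is assumed to follow the chain) and ``iron_spec`` exactly 1.
    """
    annotated = []
    for snap in ensemble:
        penta = select_atoms(snap, pentadiene_spec)
        iron = select_atoms(snap, iron_spec)
        if len(penta) != 5:
            raise ValueError(
                f"pentadiene selection {pentadiene_spec!r} matched {len(penta)} atoms, need 5"
            )
        if len(iron) != 1:
            raise ValueError(
                f"iron selection {iron_spec!r} matched {len(iron)} atoms, need 1"
            )
        annotated.append(annotate(snap, penta, iron[0]))
    return TrajectoryEnsemble(annotated, ensemble.replicate_label)


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

class SelectionError(ValueError):
    """Raised for malformed selection expressions."""


_KEYWORDS = {"chain", "resname", "resid", "name", "element"}
_OPERATORS = {"and", "or", "not", "(", ")"}
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _Parser:
    """Recursive descent over: expr := term (or term)*; term := factor
    (and factor)*; factor := not factor | (expr) | predicate."""

    def __init__(self, expression: str):
        self.tokens = _TOKEN_RE.findall(expression)
        self.pos = 0
        if not self.tokens:
            raise SelectionError("empty selection expression")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        token = self.peek()
        if token is None:
            raise SelectionError("unexpected end of expression")
        self.pos += 1
        return token

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing token {self.peek()!r}")
        return node

    def expr(self):
        node = self.term()
        while self.peek() == "or":
            self.take()
            rhs = self.term()
            node = ("or", node, rhs)
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "and":
            self.take()
            rhs = self.factor()
            node = ("and", node, rhs)
        return node

    def factor(self):
        token = self.peek()
        if token == "not":
            self.take()
            return ("not", self.factor())
        if token == "(":
            self.take()
            node = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return node
        return self.predicate()

    def predicate(self):
        keyword = self.take()
        if keyword not in _KEYWORDS:
            raise SelectionError(f"unknown keyword {keyword!r}")
        values = []
        while (token := self.peek()) is not None and token not in _OPERATORS and token not in _KEYWORDS:
            values.append(self.take())
        if not values:
            raise SelectionError(f"keyword {keyword!r} needs at least one value")
        return (keyword, values)


def _resid_match(value_tokens: list[str], resid: int) -> bool:
    for token in value_tokens:
        if ":" in token:
            lo, _, hi = token.partition(":")
            try:
                if int(lo) <= resid <= int(hi):
                    return True
            except ValueError as exc:
                raise SelectionError(f"bad resid range {token!r}") from exc
        else:
            try:
                if resid == int(token):
                    return True
            except ValueError as exc:
                raise SelectionError(f"bad resid value {token!r}") from exc
    return False


def _eval_node(node, atom: AtomRecord) -> bool:
    op = node[0]
    if op == "and":
        return _eval_node(node[1], atom) and _eval_node(node[2], atom)
    if op == "or":
        return _eval_node(node[1], atom) or _eval_node(node[2], atom)
    if op == "not":
        return not _eval_node(node[1], atom)
    keyword, values = node
    if keyword == "chain":
        return atom.chain_id in values
    if keyword == "resname":
        return atom.residue_name in values
    if keyword == "name":
        return atom.name in values
    if keyword == "element":
        return atom.element.capitalize() in {v.capitalize() for v in values}
    if keyword == "resid":
        return _resid_match(values, atom.residue_number)
    raise SelectionError(f"unknown predicate {keyword!r}")  # pragma: no cover


def select_atoms(snapshot: Snapshot, expression: str) -> list[int]:
    """Evaluate a selection expression; returns serials in ascending order
    (stable under any reordering of the atom records)."""
    tree = _Parser(expression).parse()
    return sorted(a.serial for a in snapshot.atoms if _eval_node(tree, a))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _dist_to_dict(dist) -> dict:
    return {
        "fractions": {k: float(v) for k, v in dist.fractions.items()},
        "n_snapshots_contributing": int(dist.n_snapshots_contributing),
    }


def write_report(
    results: Mapping[str, Sequence],
    path: str | Path,
    comparison=None,
) -> None:
    """Write product-distribution results for one or more enzymes.

    ``results`` maps an enzyme label to its replicate
    :class:`~loxshield.product_model.ProductDistribution` objects.  Two
    files are produced: ``<path>.json`` (full report, including the
    replicate mean and optional comparison statistics) and ``<path>.csv``
    (one row per replicate plus one mean row per enzyme).
    """
    from .product_model import average_replicates

    path = Path(path)
    report: dict = {"enzymes": {}}
    rows: list[dict] = []
    for enzyme in results:
        replicates = list(results[enzyme])
        entry: dict = {"replicates": [_dist_to_dict(d) for d in replicates]}
        if replicates:
            mean = average_replicates(replicates)
            entry["mean"] = _dist_to_dict(mean)
        report["enzymes"][enzyme] = entry
        for i, dist in enumerate(replicates):
            rows.append(_csv_row(enzyme, f"rep{i + 1}", dist))
        if replicates:
            rows.append(_csv_row(enzyme, "mean", mean))
    if comparison is not None:
        report["comparison"] = {
            "rmsd": float(comparison.rmsd),
            "maxd": float(comparison.maxd),
            "per_product_deviations": {
                f"{enzyme}/{product}": float(v)
                for (enzyme, product), v in comparison.per_product_deviations.items()
            },
        }
    json_path = path.with_suffix(".json")
    csv_path = path.with_suffix(".csv")
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    labels = sorted({key for row in rows for key in row if key.startswith("frac_")})
    with open(csv_path, "w", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=["enzyme", "replicate", *labels, "n_snapshots"]
        )
        writer.writeheader()
        writer.writerows(rows)


def _csv_row(enzyme: str, replicate: str, dist) -> dict:
    row = {"enzyme": enzyme, "replicate": replicate,
           "n_snapshots": dist.n_snapshots_contributing}
    for label, value in dist.fractions.items():
        row[f"frac_{label}"] = repr(float(value))
    return row


def read_report(path: str | Path) -> dict:
    """Read back the JSON half of a report written by :func:`write_report`."""
    return json.loads(Path(path).with_suffix(".json").read_text())
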