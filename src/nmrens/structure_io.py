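"""Multi-model PDB ensembles and coordinate selections.

An NMR structure deposit is an ordered set of conformers (MODEL/ENDMDL
blocks) sharing a single atom topology.  This module reads and writes such
ensembles and resolves residue-range/atom-class selections into coordinate
matrices with an atom ordering that is identical across conformers, which is
what every downstream RMSD and geometry computation relies on.

Parsing and serialisation go through :mod:`gemmi`; the in-memory containers
are plain dataclasses so that the numerical modules never touch a parser
object.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Conformer",
    "Ensemble",
    "Selection",
    "read_ensemble",
    "write_ensemble",
    "select_coords",
]

#: Atom names counted as "backbone" (heavy) without the carbonyl oxygen.
BACKBONE_N_CA_C = ("N", "CA", "C")
#: Backbone including the carbonyl oxygen — the common PROCHECK/NMR convention.
BACKBONE_WITH_O = ("N", "CA", "C", "O")

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    """One atom of one conformer, author numbering, coordinates in Å."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain: str
    res_seq: int
    coords: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    def key(self) -> tuple[str, int, str]:
        """Topology identity: (chain, residue number, atom name)."""
        return (self.chain, self.res_seq, self.name)


@dataclass
class Conformer:
    model_id: int
    atoms: list[Atom]

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """Ordered conformers sharing one topology.

    ``sequence`` maps author residue number to three-letter residue name for
    the (single) chain the ensemble was read from.
    """

    conformers: list[Conformer]
    sequence: dict[int, str] = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.conformers)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.conformers)


@dataclass(frozen=True)
class Selection:
    """Residue ranges (inclusive, author numbering) plus an atom class.

    ``atom_class`` is one of ``all_heavy``, ``backbone`` (N, CA, C, O),
    ``backbone_no_O`` (N, CA, C), ``CA``, ``SG``, or a tuple of atom names.
    """

    residue_ranges: tuple[tuple[int, int], ...]
    atom_class: str | tuple[str, ...] = "all_heavy"

    def __post_init__(self) -> None:
        if not self.residue_ranges:
            raise ValueError("Selection needs at least one residue range")
        for start, end in self.residue_ranges:
            if end < start:
                raise ValueError(f"Inverted residue range {start}-{end}")

    @classmethod
    def from_string(cls, ranges: str, atom_class: str | tuple[str, ...] = "all_heavy") -> "Selection":
        """Parse ``"175-196,208-217"`` (single numbers allowed) into a Selection."""
        parsed = []
        for part in ranges.split(","):
            part = part.strip()
            if "-" in part[1:]:  # allow negative start, not expected in practice
                lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                parsed.append((int(lo), int(hi)))
            else:
                parsed.append((int(part), int(part)))
        return cls(tuple(parsed), atom_class)

    def contains(self, res_seq: int) -> bool:
        return any(lo <= res_seq <= hi for lo, hi in self.residue_ranges)

    def wants_atom(self, atom: Atom) -> bool:
        if not self.contains(atom.res_seq):
            return False
        cls = self.atom_class
        if isinstance(cls, tuple):
            return atom.name in cls
        if cls == "all_heavy":
            return not atom.is_hydrogen
        if cls == "backbone":
            return atom.name in BACKBONE_WITH_O
        if cls == "backbone_no_O":
            return atom.name in BACKBONE_N_CA_C
        if cls in ("CA", "SG"):
            return atom.name == cls
        raise ValueError(f"Unknown atom class {cls!r}")


class TopologyError(ValueError):
    """Models of one ensemble disagree on their atom set."""


def _convert_model(model: gemmi.Model, model_id: int, chain_name: str | None) -> tuple[Conformer, dict[int, str]]:
    atoms: list[Atom] = []
    sequence: dict[int, str] = {}
    for chain in model:
        if chain_name is not None and chain.name != chain_name:
            continue
        for residue in chain:
            sequence[residue.seqid.num] = residue.name
            for at in residue:
                if at.altloc not in ("", "A", "\0"):
                    continue  # keep blank or 'A' only
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        alt_loc="" if at.altloc in ("", "\0") else at.altloc,
                        res_name=residue.name,
                        chain=chain.name,
                        res_seq=residue.seqid.num,
                        coords=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )
        if chain_name is None:
            chain_name = chain.name  # default: first chain only
    return Conformer(model_id=model_id, atoms=atoms), sequence


def read_ensemble(pdb_text: str, chain: str | None = None) -> Ensemble:
    """Parse a (multi-)model PDB into an :class:`Ensemble`.

    Heterogens (e.g. the Zn ions of a zinc finger) are kept; alternate
    locations other than blank/'A' are dropped; hydrogens are retained and
    filtered later by the ``all_heavy`` atom class.  All models must share an
    identical (chain, res_seq, atom name) topology.

    Raises
    ------
    TopologyError
        If two models disagree on their atom set (the first differing atom is
        named) or if the file contains no atoms.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    structure.setup_entities()
    if len(structure) == 0:
        raise TopologyError("no MODEL blocks and no ATOM records in input")
    conformers: list[Conformer] = []
    sequence: dict[int, str] = {}
    for i, model in enumerate(structure):
        model_id = model.num if model.num > 0 else i + 1
        conf, seq = _convert_model(model, model_id, chain)
        conformers.append(conf)
        if not sequence:
            sequence = seq
    if not conformers or not conformers[0].atoms:
        raise TopologyError("input contains zero ATOM records")
    reference = [a.key() for a in conformers[0].atoms]
    ref_set = set(reference)
    for conf in conformers[1:]:
        keys = [a.key() for a in conf.atoms]
        if keys != reference:
            diff = set(keys).symmetric_difference(ref_set)
            first = sorted(diff)[0] if diff else keys[0]
            raise TopologyError(
                f"model {conf.model_id} topology differs from model "
                f"{conformers[0].model_id}: first differing atom {first}"
            )
    return Ensemble(conformers=conformers, sequence=sequence)


def read_ensemble_file(path: str, chain: str | None = None) -> Ensemble:
    with open(path) as fh:
        return read_ensemble(fh.read(), chain=chain)


def write_ensemble(ensemble: Ensemble) -> str:
    """Serialise an ensemble to standard PDB text (MODEL/ENDMDL, 3-decimal Å)."""
    if not ensemble.conformers:
        raise ValueError("cannot write an ensemble with no conformers")
    for conf in ensemble.conformers:
        for a in conf.atoms:
            if a.res_seq > 9999:
                raise ValueError(f"residue number {a.res_seq} exceeds PDB format limit 9999")
    structure = gemmi.Structure()
    structure.name = "ensemble"
    for conf in ensemble.conformers:
        model = gemmi.Model(conf.model_id)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in conf.atoms:
            chain = chain_map.get(a.chain)
            if chain is None:
                chain = gemmi.Chain(a.chain or "A")
                chain_map[a.chain] = chain
            if len(chain) == 0 or chain[-1].seqid.num != a.res_seq:
                residue = gemmi.Residue()
                residue.name = a.res_name
                residue.seqid = gemmi.SeqId(a.res_seq, " ")
                residue.het_flag = "H" if a.res_name in ("ZN", "HOH") else "A"
                chain.add_residue(residue)
            residue = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.altloc = a.alt_loc or "\0"
            atom.serial = a.serial
            atom.pos = gemmi.Position(*a.coords)
            residue.add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    buf = io.StringIO()
    buf.write(structure.make_pdb_string())
    return buf.getvalue()


def select_coords(
    ensemble: Ensemble, selection: Selection
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Resolve a selection into an (n_models, n_atoms, 3) array plus labels.

    Atom ordering follows the first conformer's atom order and is identical
    across conformers (guaranteed by the ensemble topology invariant).
    Labels are ``(res_seq, atom_name)`` pairs.
    """
    first = ensemble.conformers[0]
    index = [i for i, a in enumerate(first.atoms) if selection.wants_atom(a)]
    if not index:
        raise ValueError(
            f"selection resolved to zero atoms (ranges "
            f"{selection.residue_ranges}, atoms {selection.atom_class!r})"
        )
    labels = [(first.atoms[i].res_seq, first.atoms[i].name) for i in index]
    coords = np.empty((ensemble.n_models, len(index), 3), dtype=float)
    for m, conf in enumerate(ensemble.conformers):
        for j, i in enumerate(index):
            coords[m, j] = conf.atoms[i].coords
    return coords, labels
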