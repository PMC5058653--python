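"""Multi-model PDB input/output and atom bookkeeping.

A conformational ensemble is stored as an :class:`Ensemble` of
:class:`Conformer` frames sharing one topology.  The module enforces a
heavy-atom-only contract: hydrogens (and waters) are dropped at parse time,
so every downstream "all atoms" quantity means all heavy atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger("ensemble_mimic")

# Bondi van der Waals radii (A), keyed by element symbol.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Base class for structural-input errors."""


class TopologyError(StructureError):
    """Models of one ensemble do not share an identical topology."""


class EmptyInputError(StructureError):
    """A file or ensemble contained no usable models/atoms."""


class EmptySelectionError(StructureError):
    """An atom selection resolved to zero atoms."""


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive 1-based residue-number range, e.g. ``ResidueRange(7, 13)``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"invalid range: start {self.start} > end {self.end}")

    def __contains__(self, residue_number: int) -> bool:
        return self.start <= residue_number <= self.end

    def __iter__(self):
        return iter(range(self.start, self.end + 1))

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element, residue identity and coordinates (A)."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    coords: np.ndarray
    vdw_radius: float


class Conformer:
    """One structural model: parallel per-atom arrays plus a topology key.

    Parameters are parallel sequences over atoms, in file order.  Residue
    numbers must be non-decreasing; coordinates finite; radii positive.
    """

    __slots__ = ("atom_names", "elements", "residue_names",
                 "residue_numbers", "coords", "vdw_radii", "_topology_key")

    def __init__(self, atom_names, elements, residue_names,
                 residue_numbers, coords, vdw_radii):
        self.atom_names = list(atom_names)
        self.elements = list(elements)
        self.residue_names = list(residue_names)
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.vdw_radii = np.asarray(vdw_radii, dtype=float)
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.residue_names)
                == self.residue_numbers.size == self.coords.shape[0]
                == self.vdw_radii.size == n):
            raise StructureError("conformer field lengths disagree")
        if n == 0:
            raise EmptyInputError("conformer has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if np.any(np.diff(self.residue_numbers) < 0):
            raise StructureError("residue numbers must be non-decreasing")
        if np.any(self.vdw_radii <= 0):
            raise StructureError("van der Waals radii must be positive")
        self._topology_key = tuple(
            zip(map(int, self.residue_numbers), self.residue_names, self.atom_names)
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def topology_key(self):
        """Ordered tuple of (residue_number, residue_name, atom_name)."""
        return self._topology_key

    @property
    def atoms(self):
        return [
            AtomRecord(self.atom_names[i], self.elements[i],
                       self.residue_names[i], int(self.residue_numbers[i]),
                       self.coords[i].copy(), float(self.vdw_radii[i]))
            for i in range(self.n_atoms)
        ]

    def with_coords(self, coords: np.ndarray) -> "Conformer":
        """Copy sharing all metadata but with new coordinates."""
        return Conformer(self.atom_names, self.elements, self.residue_names,
                         self.residue_numbers, coords, self.vdw_radii)

    def residue_number_list(self):
        """Distinct residue numbers in chain order."""
        seen, out = set(), []
        for r in self.residue_numbers:
            if int(r) not in seen:
                seen.add(int(r))
                out.append(int(r))
        return out


@dataclass
class Ensemble:
    """A list of conformers sharing one topology (an MD-trajectory stand-in)."""

    frames: list
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptyInputError("ensemble must contain at least one frame")
        key = self.frames[0].topology_key
        for i, frame in enumerate(self.frames[1:], start=2):
            if frame.topology_key != key:
                raise TopologyError(
                    f"frame {i} topology differs from frame 1 "
                    f"(ensemble '{self.label}')"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack."""
        return np.stack([f.coords for f in self.frames])

    def with_coords(self, coords: np.ndarray, label=None) -> "Ensemble":
        template = self.frames[0]
        return Ensemble([template.with_coords(c) for c in coords],
                        label=self.label if label is None else label)


def _vdw_for(element: str) -> float:
    element = element.upper().strip()
    if element not in VDW_RADII:
        logger.warning("unknown element %r: using default vdW radius %.2f A",
                       element, DEFAULT_VDW_RADIUS)
        return DEFAULT_VDW_RADIUS
    return VDW_RADII[element]


def read_pdb_models(path) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    Hydrogens and waters are dropped; only altloc ' '/'A' atoms are kept;
    if several chains are present the first is used (with a warning).
    All models must share an identical topology.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ensemble", str(path))

    frames = []
    for model in structure:
        chains = list(model)
        if not chains:
            continue
        if len(chains) > 1:
            logger.warning("model %s has %d chains; using chain %r only",
                           model.id, len(chains), chains[0].id)
        chain = chains[0]
        names, elements, res_names, res_numbers, coords, radii = \
            [], [], [], [], [], []
        for residue in chain:
            if residue.get_resname().strip() == "HOH":
                continue
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                element = (atom.element or "").upper().strip()
                if element in ("H", "D"):
                    continue
                names.append(atom.get_name().strip())
                elements.append(element)
                res_names.append(residue.get_resname().strip())
                res_numbers.append(residue.get_id()[1])
                coords.append(atom.get_coord())
                radii.append(_vdw_for(element))
        if names:
            frames.append(Conformer(names, elements, res_names,
                                    res_numbers, coords, radii))
    if not frames:
        raise EmptyInputError(f"no models with atoms found in {path}")

    key = frames[0].topology_key
    for i, frame in enumerate(frames[1:], start=2):
        if frame.topology_key != key:
            raise TopologyError(
                f"{path}: model {i} topology differs from model 1"
            )
    return Ensemble(frames, label=str(path))


def write_pdb_models(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a multi-model PDB (fixed-width %8.3f coords)."""
    lines = []
    for imodel, frame in enumerate(ensemble.frames, start=1):
        lines.append(f"MODEL     {imodel:4d}")
        serial = 1
        for i in range(frame.n_atoms):
            name = frame.atom_names[i]
            # PDB columns 13-16: short names are offset by one space
            name_field = name if len(name) == 4 else f" {name:<3s}"
            x, y, z = frame.coords[i]
            lines.append(
                f"ATOM  {serial:5d} {name_field}{frame.residue_names[i]:>4s} "
                f"A{int(frame.residue_numbers[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {frame.elements[i]:>2s}"
            )
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def extract_sequence(conformer: Conformer) -> str:
    """One-letter sequence: one character per distinct residue number."""
    letters = []
    seen = set()
    for i, rnum in enumerate(conformer.residue_numbers):
        rnum = int(rnum)
        if rnum in seen:
            continue
        seen.add(rnum)
        rname = conformer.residue_names[i]
        if rname not in THREE_TO_ONE:
            logger.warning("unknown residue name %r at %d: using 'X'",
                           rname, rnum)
            letters.append("X")
        else:
            letters.append(THREE_TO_ONE[rname])
    return "".join(letters)


def select_atoms(conformer: Conformer, selection: str,
                 residues: ResidueRange | None = None) -> np.ndarray:
    """Resolve a selection keyword to an ordered atom-index array.

    ``backbone`` = {N, CA, C, O}; ``calpha`` = {CA}; ``sidechain`` = heavy
    atoms outside the backbone; ``all`` = every heavy atom.  ``residues``
    restricts to a 1-based inclusive residue range.
    """
    if selection not in ("all", "backbone", "calpha", "sidechain"):
        raise StructureError(f"unsupported selection keyword {selection!r}")
    idx = []
    for i in range(conformer.n_atoms):
        if residues is not None and int(conformer.residue_numbers[i]) not in residues:
            continue
        name = conformer.atom_names[i]
        if selection == "all":
            idx.append(i)
        elif selection == "backbone" and name in BACKBONE_ATOM_NAMES:
            idx.append(i)
        elif selection == "calpha" and name == "CA":
            idx.append(i)
        elif selection == "sidechain" and name not in BACKBONE_ATOM_NAMES:
            idx.append(i)
    if not idx:
        raise EmptySelectionError(
            f"selection {selection!r}"
            + (f" over residues {residues}" if residues else "")
            + " matched no atoms"
        )
    return np.asarray(idx, dtype=int)


def detect_missing_residues(conformer: Conformer,
                            expected_sequence: str) -> list:
    """Report maximal ranges of expected residue positions absent in the model.

    Positions are 1..len(expected_sequence); nothing is rebuilt.
    """
    n = len(expected_sequence)
    present = {int(r) for r in conformer.residue_numbers}
    if present and max(present) > n:
        raise StructureError(
            f"conformer contains residue {max(present)} beyond expected "
            f"sequence length {n}"
        )
    missing = sorted(set(range(1, n + 1)) - present)
    ranges = []
    for pos in missing:
        if ranges and pos == ranges[-1][1] + 1:
            ranges[-1][1] = pos
        else:
            ranges.append([pos, pos])
    return [ResidueRange(a, b) for a, b in ranges]
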