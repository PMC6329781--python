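"""Multi-model PDB input/output and atom bookkeeping.

A trajectory is represented as a sequence of frames that share a single
topology: the same atoms in the same order in every frame.  The reference
on-disk format is the multi-model PDB (one ``MODEL``/``ENDMDL`` pair per
saved frame), which every major MD package can export and which remains
human-readable.  Residue numbering is taken verbatim from the file and
never re-indexed, so selections such as "residues 72-74 of chain A" refer
to the author numbering of the deposited structure.

Frame-to-time mapping is ``time_ps = model_index * frame_interval_ps``
with the first frame at t = 0; the saving interval (default 10 ps) is a
property of the run configuration, not of the file format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Residue names recognised as water by default.
WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "TIP3", "TIP3P", "WAT"})

#: Residue names recognised as monatomic ions (excluded from both the
#: protein and the water partitions).
ION_RESIDUE_NAMES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "SOD", "CLA", "POT", "CAL", "NA+", "CL-"}
)


class ParseError(ValueError):
    """A structure file could not be parsed (message names the line)."""


class TopologyError(ValueError):
    """Frames of one trajectory do not share a single topology."""


@dataclass(slots=True)
class AtomRecord:
    """One atom of one frame, as printed in the source file."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_seq: int
    position: np.ndarray
    element: str = ""
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")
        self.name = self.name.strip()


@dataclass(slots=True)
class Frame:
    """A single saved configuration (one PDB MODEL)."""

    model_index: int
    atoms: list[AtomRecord]
    box: np.ndarray | None = None

    def coordinates(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array."""
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass(slots=True)
class WaterMolecule:
    """A rigid 3-site water: one oxygen and two hydrogens, in Angstrom."""

    oxygen: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    residue_seq: int = 0

    def __post_init__(self) -> None:
        self.oxygen = np.asarray(self.oxygen, dtype=float)
        self.h1 = np.asarray(self.h1, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)

    def sites(self) -> np.ndarray:
        """The three interaction sites as a (3, 3) array, oxygen first."""
        return np.stack([self.oxygen, self.h1, self.h2])

    def translated(self, shift: np.ndarray) -> "WaterMolecule":
        shift = np.asarray(shift, dtype=float)
        return WaterMolecule(
            self.oxygen + shift, self.h1 + shift, self.h2 + shift, self.residue_seq
        )


@dataclass
class SystemCondition:
    """Metadata describing the simulated system a trajectory came from."""

    label: str = ""
    temperature_K: float = 300.0
    ph_class: str = "neutral"  # "neutral" or "low"
    variant: str = "WT"

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")


@dataclass
class Trajectory:
    """An ordered sequence of frames sharing one topology."""

    frames: list[Frame]
    frame_interval_ps: float = 10.0
    condition: SystemCondition | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def time_ps(self, frame_index: int) -> float:
        """Simulation time of a frame, with the first frame at t = 0."""
        return self.frames[frame_index].model_index * self.frame_interval_ps

    def coordinate_array(self) -> np.ndarray:
        """Coordinates of every frame as an (n_frames, n_atoms, 3) array."""
        return np.array([f.coordinates() for f in self.frames])


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:21].strip()
        chain_id = line[21]
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    return AtomRecord(
        serial=serial,
        name=name,
        residue_name=residue_name,
        chain_id=chain_id,
        residue_seq=residue_seq,
        position=np.array([x, y, z]),
        element=element,
        altloc=altloc,
        occupancy=occupancy,
    )


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy alternate conformer (first on tie)."""
    kept: list[AtomRecord] = []
    by_key: dict[tuple, int] = {}
    for atom in atoms:
        if not atom.altloc:
            kept.append(atom)
            continue
        key = (atom.chain_id, atom.residue_seq, atom.residue_name, atom.name)
        if key in by_key:
            if atom.occupancy > kept[by_key[key]].occupancy:
                kept[by_key[key]] = atom
        else:
            by_key[key] = len(kept)
            kept.append(atom)
    return kept


def read_multimodel_pdb(
    path,
    frame_interval_ps: float = 10.0,
    condition: SystemCondition | None = None,
) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    Each ``MODEL``/``ENDMDL`` pair becomes one frame; a file without MODEL
    records yields a single frame with ``model_index`` 0.  Atom order is
    preserved exactly as printed.  An orthorhombic ``CRYST1`` record, when
    present, is stored as the periodic box of every frame.

    Raises
    ------
    ParseError
        If an ATOM/HETATM record cannot be parsed (message names the line).
    TopologyError
        If models disagree on the number of atoms.
    """
    frames: list[Frame] = []
    box: np.ndarray | None = None
    current: list[AtomRecord] | None = None
    saw_model = False

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record == "CRYST1":
                try:
                    box = np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33])]
                    )
                except ValueError as exc:
                    raise ParseError(f"malformed CRYST1 record at line {lineno}") from exc
            elif record == "MODEL ":
                saw_model = True
                current = []
            elif record == "ENDMDL":
                if current is not None:
                    frames.append(Frame(len(frames), _dedupe_altlocs(current), box))
                current = None
            elif record in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model:
                        # coordinates outside MODEL blocks in a multi-model
                        # file: tolerate by opening an implicit model
                        current = []
                    else:
                        current = []
                current.append(_parse_atom_line(line, lineno))

    if current:
        frames.append(Frame(len(frames), _dedupe_altlocs(current), box))
    if not frames:
        raise ParseError(f"no coordinates found in {path}")

    n0 = len(frames[0].atoms)
    for frame in frames[1:]:
        if len(frame.atoms) != n0:
            raise TopologyError(
                f"model {frame.model_index + 1} has {len(frame.atoms)} atoms, "
                f"expected {n0}"
            )
    return Trajectory(frames, frame_interval_ps=frame_interval_ps, condition=condition)


def _format_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14 by convention.
    return name if len(name) >= 4 else f" {name:<3}"


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a standard multi-model PDB (3-decimal coords)."""
    if not traj.frames:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w") as handle:
        box = traj.frames[0].box
        if box is not None:
            handle.write(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n"
            )
        for i, frame in enumerate(traj.frames):
            handle.write(f"MODEL     {i + 1:4d}\n")
            for j, atom in enumerate(frame.atoms, start=1):
                x, y, z = atom.position
                handle.write(
                    f"ATOM  {j % 100000:5d} {_format_atom_name(atom.name)}"
                    f"{atom.altloc or ' '}{atom.residue_name:>3} {atom.chain_id}"
                    f"{atom.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element:>2}\n"
                )
            handle.write("ENDMDL\n")
        handle.write("END\n")


def select_residues(
    frame: Frame, chain: str, residue_seqs: Iterable[int]
) -> list[AtomRecord]:
    """All atoms of the given chain whose residue number is in the set.

    Original atom order is preserved; an empty result is allowed.
    """
    wanted = set(residue_seqs)
    return [
        a for a in frame.atoms if a.chain_id == chain and a.residue_seq in wanted
    ]


def split_protein_water(
    frame: Frame,
    water_residue_names: frozenset[str] = WATER_RESIDUE_NAMES,
    ion_residue_names: frozenset[str] = ION_RESIDUE_NAMES,
) -> tuple[list[AtomRecord], list[WaterMolecule]]:
    """Partition a frame into protein atoms and rigid 3-site waters.

    Waters are identified by residue name and grouped by
    (chain, residue number); each group must contain exactly one oxygen and
    two hydrogens because the pair-energy model needs all three sites.
    Monatomic ions are dropped from both partitions.
    """
    protein: list[AtomRecord] = []
    groups: dict[tuple[str, int], list[AtomRecord]] = {}
    order: list[tuple[str, int]] = []
    for atom in frame.atoms:
        if atom.residue_name in water_residue_names:
            key = (atom.chain_id, atom.residue_seq)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(atom)
        elif atom.residue_name in ion_residue_names:
            continue
        else:
            protein.append(atom)

    waters: list[WaterMolecule] = []
    for key in order:
        atoms = groups[key]
        oxygens = [a for a in atoms if a.element == "O" or a.name.startswith("O")]
        hydrogens = [a for a in atoms if a.element == "H" or a.name.startswith("H")]
        if len(oxygens) != 1 or len(hydrogens) != 2:
            raise ValueError(
                f"water residue {key[1]} (chain {key[0]!r}) has "
                f"{len(oxygens)} oxygen(s) and {len(hydrogens)} hydrogen(s); "
                f"a rigid 3-site water requires exactly 1 and 2"
            )
        waters.append(
            WaterMolecule(
                oxygens[0].position,
                hydrogens[0].position,
                hydrogens[1].position,
                residue_seq=key[1],
            )
        )
    return protein, waters
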