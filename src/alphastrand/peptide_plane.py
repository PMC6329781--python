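"""Peptide-plane flip events and rigid-body frame superposition.

A peptide-plane flip is a rotation of a CO-NH unit that carries a residue
between the right-handed (alpha_R) and left-handed (alpha_L) helical
quadrants; flipping back and forth is the proposed route between
alpha-sheet and beta-sheet geometries.  Flips are detected on the label
series (quadrant crossings of consecutive frames) rather than on carbonyl
vectors, which matches the dihedral-based bookkeeping used for strand
detection; the carbonyl rotation angle is available separately as a
descriptive quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .dihedral_analysis import Label, StrandTimeSeries
from .trajectory_io import Frame, Trajectory, write_multimodel_pdb


@dataclass(frozen=True)
class FlipEvent:
    """One label transition of a residue between ALPHA_R and ALPHA_L."""

    residue_seq: int
    residue_pair: tuple[int, int]  # peptide bond (i, i+1) carrying the plane
    frame_from: int
    frame_to: int
    direction: str  # "R_to_L" or "L_to_R"


@dataclass
class Superposition:
    """Least-squares rigid-body fit of one frame onto another."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float  # Angstrom, after the transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map mobile-frame coordinates onto the reference frame."""
        return np.asarray(coords, dtype=float) @ self.rotation + self.translation


def detect_flips(
    labels: Sequence[Label], residue_seq: int = 0, gap: int = 0
) -> list[FlipEvent]:
    """Flip events in one residue's label series over frames.

    An event is a transition between ALPHA_R and ALPHA_L (either order)
    across at most ``gap`` intervening non-helical frames (default 0:
    strictly consecutive frames).  Direction is recorded from the earlier
    helical label.
    """
    events: list[FlipEvent] = []
    last_label: Label | None = None
    last_frame = -1
    for f, label in enumerate(labels):
        if label not in (Label.ALPHA_R, Label.ALPHA_L):
            continue
        if (
            last_label is not None
            and label != last_label
            and f - last_frame - 1 <= gap
        ):
            events.append(
                FlipEvent(
                    residue_seq=residue_seq,
                    residue_pair=(residue_seq, residue_seq + 1),
                    frame_from=last_frame,
                    frame_to=f,
                    direction="R_to_L" if last_label is Label.ALPHA_R else "L_to_R",
                )
            )
        last_label = label
        last_frame = f
    return events


def co_vector_angle(
    frame_a: Frame, frame_b: Frame, residue_seq: int, chain: str = "A"
) -> float:
    """Angle (degrees) between a residue's C->O carbonyl vector in two frames.

    Purely descriptive: flip bookkeeping is label-based, but the carbonyl
    rotation gives an intuitive geometric magnitude for an event.
    """

    def co(frame: Frame) -> np.ndarray:
        c = o = None
        for atom in frame.atoms:
            if atom.chain_id == chain and atom.residue_seq == residue_seq:
                if atom.name == "C":
                    c = atom.position
                elif atom.name == "O":
                    o = atom.position
        if c is None or o is None:
            raise ValueError(f"residue {residue_seq} lacks C or O in chain {chain!r}")
        return o - c

    v1, v2 = co(frame_a), co(frame_b)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def superpose(
    frame_a: Frame, frame_b: Frame, atom_indices: Sequence[int]
) -> Superposition:
    """Optimal rigid superposition of frame_b onto frame_a.

    ``atom_indices`` select the paired atoms (same topology positions in
    both frames); at least three are required.  Collinear selections give
    a degenerate fit: a warning is raised and the least-squares solution
    is still returned.
    """
    if len(atom_indices) < 3:
        raise ValueError("superposition requires at least 3 paired atoms")
    ref = np.array([frame_a.atoms[i].position for i in atom_indices])
    mob = np.array([frame_b.atoms[i].position for i in atom_indices])

    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        warnings.warn("collinear atom selection: superposition is degenerate",
                      stacklevel=2)

    sup = SVDSuperimposer()
    sup.set(ref, mob)
    sup.run()
    rot, tran = sup.get_rotran()
    return Superposition(rotation=rot, translation=tran, rmsd=float(sup.get_rms()))


def backbone_indices(
    frame: Frame,
    chain: str,
    region: tuple[int, int],
    names: tuple[str, ...] = ("N", "CA", "C"),
) -> list[int]:
    """Indices of region backbone atoms, in frame order."""
    lo, hi = region
    wanted = set(names)
    return [
        i
        for i, a in enumerate(frame.atoms)
        if a.chain_id == chain and lo <= a.residue_seq <= hi and a.name in wanted
    ]


def first_strand_snapshot(
    traj: Trajectory,
    series: StrandTimeSeries,
    chain: str = "A",
    path=None,
) -> tuple[Frame, Frame, Superposition]:
    """Initial frame, first strand frame, and their region superposition.

    The first frame in which the region strand is present is rigidly
    fitted onto frame 0 using the region backbone N/CA/C atoms, the
    standard way of visualising which peptide plane rotated.  When
    ``path`` is given, a 2-model PDB (initial + aligned strand frame) is
    written for inspection.
    """
    present = np.asarray(series.present, dtype=bool)
    if not present.any():
        raise ValueError("the region never adopts the strand conformation")
    first = int(np.argmax(present))
    initial = traj.frames[0]
    strand = traj.frames[first]
    indices = backbone_indices(initial, chain, series.region)
    fit = superpose(initial, strand, indices)
    if path is not None:
        import copy

        aligned = copy.deepcopy(strand)
        for atom in aligned.atoms:
            atom.position = fit.apply(atom.position)
        aligned.model_index = 1
        initial_copy = copy.deepcopy(initial)
        initial_copy.model_index = 0
        write_multimodel_pdb(
            Trajectory([initial_copy, aligned], traj.frame_interval_ps), path
        )
    return initial, strand, fit
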