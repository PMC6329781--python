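"""Backbone dihedral angles, quadrant conformation labels and strand runs.

The central objects here are the phi/psi backbone torsions and a coarse
Ramachandran classification into quadrants: a residue is labelled
``ALPHA_R`` (right-handed helical) when -180 < phi < 0 and -180 < psi < 0,
``ALPHA_L`` (left-handed helical) when 0 < phi < 180 and 0 < psi < 180, and
``OTHER`` for any mixed-sign combination (the beta and polyproline regions
fall here).  Boundary values (phi or psi exactly 0 or +/-180) are classified
``OTHER``: the inequalities are strict, and the boundary set has measure
zero for real trajectories.

An *alpha-strand* is a run of at least three consecutive residues whose
labels strictly alternate between ALPHA_R and ALPHA_L (patterns such as
aR-aL-aR or aL-aR-aL-aR).  Alternation is the defining property: a repeated
label or any non-helical label terminates a run.  From per-frame strand
segments the module derives, for a target residue region, a per-frame
presence mask, the occupancy (percentage of frames with the whole region
simultaneously inside one alternating run), and the first-appearance time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Frame, Trajectory


class UndefinedTorsionError(ValueError):
    """Torsion is geometrically undefined (collinear bonded atoms)."""


class Label(Enum):
    """Quadrant conformation label of one residue in one frame."""

    ALPHA_R = "alpha_R"
    ALPHA_L = "alpha_L"
    OTHER = "other"
    UNDEFINED = "undefined"


# Integer codes used internally for vectorised work.
CODE_ALPHA_R, CODE_ALPHA_L, CODE_OTHER, CODE_UNDEFINED = 0, 1, 2, 3
_LABEL_BY_CODE = (Label.ALPHA_R, Label.ALPHA_L, Label.OTHER, Label.UNDEFINED)

#: Cap residues that carry backbone atoms for their neighbours but are not
#: themselves classified (e.g. an acetylated N-terminus).
CAP_RESIDUE_NAMES = frozenset({"ACE", "NME", "NMA"})


@dataclass(frozen=True)
class DihedralPair:
    """Backbone (phi, psi) of one residue, degrees in (-180, 180].

    Either angle may be ``None``: the first residue of a chain has no phi
    and the last has no psi (unless a cap residue supplies the missing
    neighbour atom).
    """

    phi_deg: float | None
    psi_deg: float | None

    @property
    def defined(self) -> bool:
        return self.phi_deg is not None and self.psi_deg is not None


@dataclass(frozen=True)
class StrandSegment:
    """A maximal alternating alpha_R/alpha_L run in one frame."""

    frame_index: int
    start_residue: int
    length: int
    pattern: tuple[Label, ...]

    @property
    def end_residue(self) -> int:
        return self.start_residue + self.length - 1

    def covers(self, region: tuple[int, int]) -> bool:
        return self.start_residue <= region[0] and self.end_residue >= region[1]


@dataclass
class StrandTimeSeries:
    """Per-frame strand presence of a residue region, plus the segments."""

    region: tuple[int, int]
    present: np.ndarray  # boolean, one entry per frame
    segments: list[StrandSegment] = field(default_factory=list)


@dataclass
class OccupancyResult:
    """Occupancy and first-appearance statistics for one region."""

    region: tuple[int, int]
    occupancy_percent: float
    n_frames: int
    first_appearance_ps: float | None


def dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Signed torsion angle(s) in degrees, (-180, 180], for point arrays.

    Inputs broadcast over leading dimensions; the last axis is xyz.  The
    sign follows the IUPAC convention (positive clockwise looking from
    p2 towards p3).  Degenerate (collinear) inputs yield NaN.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b2u = b2 / b2n
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
        angle = np.degrees(np.arctan2(y, x))
    scale = np.linalg.norm(b1, axis=-1) * np.linalg.norm(b2, axis=-1)
    scale2 = np.linalg.norm(b2, axis=-1) * np.linalg.norm(b3, axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) <= 1e-9 * np.maximum(scale, 1e-30)) | (
        np.linalg.norm(n2, axis=-1) <= 1e-9 * np.maximum(scale2, 1e-30)
    )
    angle = np.where(bad, np.nan, angle)
    # map -180 into the half-open convention (-180, 180]
    return np.where(angle <= -180.0, angle + 360.0, angle)


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points in degrees, range (-180, 180].

    Raises :class:`UndefinedTorsionError` when either atom triple is
    collinear (or consecutive points coincide), which leaves the torsion
    geometrically undefined.
    """
    value = float(dihedral_batch(p1, p2, p3, p4))
    if np.isnan(value):
        raise UndefinedTorsionError(
            "torsion undefined: collinear or coincident consecutive points"
        )
    return value


def classify_codes(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Vectorised quadrant classification on angle arrays (degrees).

    NaN in either angle yields the UNDEFINED code; values exactly on a
    quadrant boundary (0 or +/-180) are OTHER because the defining
    inequalities are strict.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    codes = np.full(np.broadcast(phi, psi).shape, CODE_OTHER, dtype=np.int8)
    is_r = (phi > -180.0) & (phi < 0.0) & (psi > -180.0) & (psi < 0.0)
    is_l = (phi > 0.0) & (phi < 180.0) & (psi > 0.0) & (psi < 180.0)
    codes[is_r] = CODE_ALPHA_R
    codes[is_l] = CODE_ALPHA_L
    codes[np.isnan(phi) | np.isnan(psi)] = CODE_UNDEFINED
    return codes


def classify(pair: DihedralPair | None) -> Label:
    """Quadrant label of one (phi, psi) pair.

    (-, -) -> ALPHA_R; (+, +) -> ALPHA_L; mixed signs or exact boundary
    values -> OTHER; missing angles -> UNDEFINED.
    """
    if pair is None or not pair.defined:
        return Label.UNDEFINED
    code = classify_codes(np.float64(pair.phi_deg), np.float64(pair.psi_deg))
    return _LABEL_BY_CODE[int(code)]


def _collect_chain_residues(frame: Frame, chain: str):
    """Ordered {residue_seq: {atom_name: position}} plus residue names."""
    atoms_by_res: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    for atom in frame.atoms:
        if atom.chain_id != chain:
            continue
        res = atoms_by_res.setdefault(atom.residue_seq, {})
        if atom.name not in res:
            res[atom.name] = atom.position
        names.setdefault(atom.residue_seq, atom.residue_name)
    return dict(sorted(atoms_by_res.items())), names


def assign_phi_psi(frame: Frame, chain: str = "A") -> dict[int, DihedralPair]:
    """Backbone (phi, psi) for every residue of a chain in one frame.

    phi of residue i needs the carbonyl C of residue i-1 and psi needs the
    amide N of residue i+1 (consecutive numbering required, so numbering
    gaps behave as chain breaks).  Cap residues such as ACE supply those
    neighbour atoms but receive no entry themselves.  A residue missing
    one of its own backbone atoms is reported with both angles undefined,
    with a warning rather than a fatal error.
    """
    residues, names = _collect_chain_residues(frame, chain)
    result: dict[int, DihedralPair] = {}
    for seq, atoms in residues.items():
        if names.get(seq, "") in CAP_RESIDUE_NAMES:
            continue
        if not all(k in atoms for k in ("N", "CA", "C")):
            warnings.warn(
                f"residue {seq} (chain {chain}) lacks backbone atoms; "
                f"dihedrals undefined",
                stacklevel=2,
            )
            result[seq] = DihedralPair(None, None)
            continue
        phi = psi = None
        prev_atoms = residues.get(seq - 1)
        if prev_atoms is not None and "C" in prev_atoms:
            try:
                phi = compute_dihedral(
                    prev_atoms["C"], atoms["N"], atoms["CA"], atoms["C"]
                )
            except UndefinedTorsionError:
                warnings.warn(f"phi undefined for residue {seq}", stacklevel=2)
        next_atoms = residues.get(seq + 1)
        if next_atoms is not None and "N" in next_atoms:
            try:
                psi = compute_dihedral(
                    atoms["N"], atoms["CA"], atoms["C"], next_atoms["N"]
                )
            except UndefinedTorsionError:
                warnings.warn(f"psi undefined for residue {seq}", stacklevel=2)
        result[seq] = DihedralPair(phi, psi)
    return result


def phi_psi_matrix(
    traj: Trajectory, chain: str = "A"
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Vectorised phi/psi over a whole trajectory.

    Returns ``(residue_seqs, phi, psi)`` where the angle arrays have shape
    (n_frames, n_residues) and NaN marks undefined torsions (chain ends,
    numbering gaps, missing atoms).  Uses the shared topology of the
    trajectory: the atom index map is built once from frame 0.
    """
    frame0 = traj.frames[0]
    index_of: dict[tuple[int, str], int] = {}
    res_names: dict[int, str] = {}
    seqs_seen: list[int] = []
    for i, atom in enumerate(frame0.atoms):
        if atom.chain_id != chain:
            continue
        key = (atom.residue_seq, atom.name)
        if key not in index_of:
            index_of[key] = i
        if atom.residue_seq not in res_names:
            res_names[atom.residue_seq] = atom.residue_name
            seqs_seen.append(atom.residue_seq)
    seqs = sorted(s for s in seqs_seen if res_names[s] not in CAP_RESIDUE_NAMES)

    coords = traj.coordinate_array()  # (F, N, 3)
    n_f = coords.shape[0]

    def gather(keys: list[tuple[int, str] | None]) -> np.ndarray:
        out = np.full((n_f, len(keys), 3), np.nan)
        for j, key in enumerate(keys):
            if key is not None and key in index_of:
                out[:, j, :] = coords[:, index_of[key], :]
        return out

    prev_c = gather([(s - 1, "C") for s in seqs])
    n = gather([(s, "N") for s in seqs])
    ca = gather([(s, "CA") for s in seqs])
    c = gather([(s, "C") for s in seqs])
    next_n = gather([(s + 1, "N") for s in seqs])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phi = dihedral_batch(prev_c, n, ca, c)
        psi = dihedral_batch(n, ca, c, next_n)
    return seqs, phi, psi


def detect_strands(
    labels: Sequence[Label],
    residue_seqs: Sequence[int] | None = None,
    frame_index: int = 0,
    min_length: int = 3,
) -> list[StrandSegment]:
    """Maximal alternating ALPHA_R/ALPHA_L runs of length >= ``min_length``.

    A run is broken by OTHER or UNDEFINED labels, by a repeated identical
    helical label, or by a gap in residue numbering.
    """
    if residue_seqs is None:
        residue_seqs = list(range(len(labels)))
    if len(residue_seqs) != len(labels):
        raise ValueError("labels and residue_seqs must have equal length")

    segments: list[StrandSegment] = []
    run_start = None  # index into labels
    prev_label: Label | None = None

    def flush(end_index: int) -> None:
        nonlocal run_start
        if run_start is not None and end_index - run_start + 1 >= min_length:
            segments.append(
                StrandSegment(
                    frame_index=frame_index,
                    start_residue=residue_seqs[run_start],
                    length=end_index - run_start + 1,
                    pattern=tuple(labels[run_start : end_index + 1]),
                )
            )
        run_start = None

    for i, label in enumerate(labels):
        helical = label in (Label.ALPHA_R, Label.ALPHA_L)
        contiguous = i == 0 or residue_seqs[i] == residue_seqs[i - 1] + 1
        if not helical or not contiguous:
            flush(i - 1)
            prev_label = label if (helical and not contiguous) else None
            if helical and not contiguous:
                run_start = i
            continue
        if run_start is None:
            run_start = i
        elif label == prev_label:  # repeated identical label breaks the run
            flush(i - 1)
            run_start = i
        prev_label = label
    flush(len(labels) - 1)
    return segments


def _labels_from_codes(codes: np.ndarray) -> list[Label]:
    return [_LABEL_BY_CODE[c] for c in codes]


def strand_presence(
    traj: Trajectory,
    chain: str,
    region: tuple[int, int],
    min_length: int = 3,
) -> StrandTimeSeries:
    """Per-frame presence of an alternating strand covering a region.

    ``present[f]`` is True iff some maximal alternating run at frame f
    spans every residue of ``region`` (a half-strand does not count: the
    region must sit inside a single run of length >= ``min_length``).
    """
    lo, hi = region
    seqs, phi, psi = phi_psi_matrix(traj, chain)
    seq_set = set(seqs)
    missing = [r for r in range(lo, hi + 1) if r not in seq_set]
    if missing:
        raise ValueError(f"region residues {missing} not found in chain {chain!r}")

    codes = classify_codes(phi, psi)
    present = np.zeros(traj.n_frames, dtype=bool)
    all_segments: list[StrandSegment] = []
    for f in range(traj.n_frames):
        segments = detect_strands(
            _labels_from_codes(codes[f]), seqs, frame_index=f, min_length=min_length
        )
        for seg in segments:
            if seg.covers(region):
                present[f] = True
        all_segments.extend(segments)
    return StrandTimeSeries(region=region, present=present, segments=all_segments)


def occupancy(series: StrandTimeSeries, traj: Trajectory) -> OccupancyResult:
    """Occupancy (%) and first-appearance time of the region's strand.

    The denominator is all frames of the trajectory, including frames with
    undefined dihedrals (counted as absent).  First appearance is
    ``frame_interval_ps * index of first present frame`` or ``None`` when
    the strand never appears.
    """
    n = len(series.present)
    if n == 0 or traj.n_frames == 0:
        raise ValueError("occupancy of an empty trajectory is undefined")
    n_present = int(np.count_nonzero(series.present))
    first_idx = int(np.argmax(series.present)) if n_present else None
    return OccupancyResult(
        region=series.region,
        occupancy_percent=100.0 * n_present / n,
        n_frames=n,
        first_appearance_ps=(
            None if first_idx is None else first_idx * traj.frame_interval_ps
        ),
    )


@dataclass
class RamachandranSeries:
    """Tabular phi/psi time series for a region, plus per-residue summary."""

    table: pd.DataFrame  # columns: residue, frame, time_ps, phi_deg, psi_deg, label
    residue_summary: pd.DataFrame  # initial label, visited labels, first transition


def ramachandran_series(
    traj: Trajectory, chain: str, region: tuple[int, int]
) -> RamachandranSeries:
    """Per-residue (phi, psi, label) time series over a residue region.

    The summary reports, per residue, the label at the first frame of the
    run, the set of labels visited during the trajectory and the frame of
    the first change away from the initial label (or -1 if none), which is
    how Ramachandran transition plots are annotated.
    """
    lo, hi = region
    seqs, phi, psi = phi_psi_matrix(traj, chain)
    cols = [j for j, s in enumerate(seqs) if lo <= s <= hi]
    codes = classify_codes(phi[:, cols], psi[:, cols])

    rows = []
    for jj, j in enumerate(cols):
        for f in range(traj.n_frames):
            rows.append(
                (
                    seqs[j],
                    f,
                    traj.time_ps(f),
                    phi[f, j],
                    psi[f, j],
                    _LABEL_BY_CODE[codes[f, jj]].value,
                )
            )
    table = pd.DataFrame(
        rows, columns=["residue", "frame", "time_ps", "phi_deg", "psi_deg", "label"]
    )

    summary_rows = []
    for jj, j in enumerate(cols):
        series = codes[:, jj]
        initial = _LABEL_BY_CODE[series[0]].value
        visited = sorted({_LABEL_BY_CODE[c].value for c in series})
        changed = np.nonzero(series != series[0])[0]
        summary_rows.append(
            (seqs[j], initial, "|".join(visited), int(changed[0]) if changed.size else -1)
        )
    residue_summary = pd.DataFrame(
        summary_rows,
        columns=["residue", "initial_label", "visited_labels", "first_transition_frame"],
    )
    return RamachandranSeries(table=table, residue_summary=residue_summary)
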