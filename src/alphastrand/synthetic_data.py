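"""Ground-truth synthetic inputs for every stage of the pipeline.

Real 20-ns MD trajectories of the 140-residue protein are too large to
ship and the analyses here only ever see backbone dihedrals and water
coordinates, so the generator emulates exactly those observables:

* per-residue conformational-state time series from independent Markov
  chains over canonical Ramachandran basins, with *planted* alternating
  alpha_R/alpha_L episodes forced onto a chosen residue region at known
  frames -- the union of episodes is the exact ground-truth presence mask;
* backbone Cartesian coordinates rebuilt from those dihedrals by standard
  internal-to-Cartesian chain extension (NeRF) with fixed ideal bond
  geometry and trans peptide bonds, so recomputing phi/psi from the
  coordinates recovers the requested angles to numerical precision;
* water boxes containing hydrogen-bonded three-water rings planted at
  known positions, validated against the TIP3P pair-energy criterion at
  generation time, over a background of waters kept too far apart to bond.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from . import dihedral_analysis as da
from .trajectory_io import AtomRecord, Frame, Trajectory, WaterMolecule, write_multimodel_pdb
from .twn_analysis import DEFAULT_TIP3P, TIP3PParameters, pair_energy


class PackingError(RuntimeError):
    """The requested water box could not be packed within bounded retries."""


# ---------------------------------------------------------------------------
# conformational states and Markov label trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformationalState:
    """A Ramachandran basin: mean (phi, psi) and an angular spread."""

    name: str
    mean_phi_deg: float
    mean_psi_deg: float
    angular_spread_deg: float


#: Canonical basin centres; the two helical states sit well inside their
#: quadrants so that moderate angular noise rarely crosses a boundary.
DEFAULT_STATES: tuple[ConformationalState, ...] = (
    ConformationalState("ALPHA_R_STATE", -60.0, -45.0, 10.0),
    ConformationalState("ALPHA_L_STATE", 60.0, 45.0, 10.0),
    ConformationalState("BETA_STATE", -120.0, 130.0, 15.0),
    ConformationalState("PPII_STATE", -75.0, 150.0, 15.0),
)

STATE_ALPHA_R, STATE_ALPHA_L, STATE_BETA, STATE_PPII = range(4)


def _default_transition_matrix(n_states: int = 4, stay: float = 0.97) -> np.ndarray:
    off = (1.0 - stay) / (n_states - 1)
    matrix = np.full((n_states, n_states), off)
    np.fill_diagonal(matrix, stay)
    return matrix


@dataclass
class SyntheticTrajectorySpec:
    """Study conditions for a synthetic dihedral trajectory.

    Defaults mirror the analysed simulations: a 140-residue chain saved
    every 10 ps for 2000 frames (20 ns), with the strand region at
    residues 72-74 and planted alternating episodes totalling 300 frames
    (15% occupancy), the first starting at frame 146 (1460 ps).
    """

    n_residues: int = 140
    n_frames: int = 2000
    frame_interval_ps: float = 10.0
    transition_matrix: np.ndarray = field(default_factory=_default_transition_matrix)
    planted_region: tuple[int, int] = (72, 74)
    planted_episodes: tuple[tuple[int, int], ...] = (
        (146, 246),
        (600, 700),
        (1200, 1300),
    )  # half-open [start, end) frame ranges
    first_residue_seq: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.ndim != 2 or (
            self.transition_matrix.shape[0] != self.transition_matrix.shape[1]
        ):
            raise ValueError("transition matrix must be square")
        if np.any(self.transition_matrix < 0) or not np.allclose(
            self.transition_matrix.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")
        for start, end in self.planted_episodes:
            if not (0 <= start < end <= self.n_frames):
                raise ValueError(f"episode ({start}, {end}) outside [0, n_frames)")
        lo, hi = self.planted_region
        if not (
            self.first_residue_seq
            <= lo
            <= hi
            < self.first_residue_seq + self.n_residues
        ):
            raise ValueError("planted region outside the residue range")

    @property
    def region_rows(self) -> range:
        lo, hi = self.planted_region
        off = self.first_residue_seq
        return range(lo - off, hi - off + 1)

    def truth_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_frames, dtype=bool)
        for start, end in self.planted_episodes:
            mask[start:end] = True
        return mask


def simulate_labels(
    spec: SyntheticTrajectorySpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Markov state labels (n_residues x n_frames) and the truth mask.

    Each residue runs an independent Markov chain over the states.  Inside
    planted episodes the region rows are overwritten with the alternating
    aR-aL-aR... pattern; outside them, any accidental full-region
    alternation produced by the background chains is broken (the middle
    region residue is set to the beta state) so the ground-truth presence
    mask is exactly the union of the planted episodes.
    """
    rng = np.random.default_rng(spec.seed)
    n_states = spec.transition_matrix.shape[0]
    cumulative = np.cumsum(spec.transition_matrix, axis=1)

    labels = np.empty((spec.n_residues, spec.n_frames), dtype=np.int8)
    state = rng.integers(0, n_states, size=spec.n_residues)
    labels[:, 0] = state
    for t in range(1, spec.n_frames):
        u = rng.random(spec.n_residues)
        state = (u[:, None] > cumulative[state]).sum(axis=1)
        labels[:, t] = state

    rows = list(spec.region_rows)
    pattern = np.array(
        [STATE_ALPHA_R if i % 2 == 0 else STATE_ALPHA_L for i in range(len(rows))],
        dtype=np.int8,
    )
    mask = spec.truth_mask()
    labels[np.ix_(rows, np.nonzero(mask)[0])] = pattern[:, None]

    # break accidental alternation outside the planted episodes
    region = labels[rows][:, ~mask]
    helical = (region == STATE_ALPHA_R) | (region == STATE_ALPHA_L)
    alternating = helical.all(axis=0) & (np.diff(region, axis=0) != 0).all(axis=0)
    if alternating.any():
        cols = np.nonzero(~mask)[0][alternating]
        labels[rows[len(rows) // 2], cols] = STATE_BETA
    return labels, mask


@dataclass
class SampledDihedrals:
    """Dihedral time series sampled from a state-label matrix."""

    phi: np.ndarray  # (n_residues, n_frames), degrees in (-180, 180]
    psi: np.ndarray
    quadrant_violation_rate: float  # fraction of helical-state samples
    # whose noisy angles left the state's quadrant


def _wrap_angle(x: np.ndarray) -> np.ndarray:
    wrapped = x - 360.0 * np.floor((x + 180.0) / 360.0)
    return np.where(wrapped == -180.0, 180.0, wrapped)


def sample_dihedrals(
    labels: np.ndarray,
    states: Sequence[ConformationalState] = DEFAULT_STATES,
    seed: int = 0,
    spread_scale: float = 1.0,
) -> SampledDihedrals:
    """Draw (phi, psi) around each state's mean with wrapped Gaussian noise.

    ``spread_scale`` rescales every state's angular spread (0 gives the
    means exactly).  The reported violation rate is measured on the
    helical states only: the fraction of their samples that classify
    outside the intended quadrant.
    """
    rng = np.random.default_rng(seed)
    means_phi = np.array([s.mean_phi_deg for s in states])
    means_psi = np.array([s.mean_psi_deg for s in states])
    spreads = np.array([s.angular_spread_deg for s in states]) * spread_scale

    phi = means_phi[labels] + spreads[labels] * rng.standard_normal(labels.shape)
    psi = means_psi[labels] + spreads[labels] * rng.standard_normal(labels.shape)
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)

    codes = da.classify_codes(phi, psi)
    helical_r = labels == STATE_ALPHA_R
    helical_l = labels == STATE_ALPHA_L
    n_helical = int(helical_r.sum() + helical_l.sum())
    if n_helical:
        violations = int(
            (codes[helical_r] != da.CODE_ALPHA_R).sum()
            + (codes[helical_l] != da.CODE_ALPHA_L).sum()
        )
        rate = violations / n_helical
    else:
        rate = 0.0
    return SampledDihedrals(phi=phi, psi=psi, quadrant_violation_rate=rate)


# ---------------------------------------------------------------------------
# internal-to-Cartesian backbone construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackboneGeometry:
    """Fixed ideal backbone geometry (Angstrom / degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    omega_deg: float = 180.0  # trans peptide planes


DEFAULT_GEOMETRY = BackboneGeometry()


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg) -> np.ndarray:
    """NeRF atom placement: d such that |cd| = bond, angle(b,c,d) and
    torsion(a,b,c,d) take the requested values.  Batched over leading axes.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(np.asarray(torsion_deg, dtype=float))
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n_hat, bc_hat)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cos_p, sin_p = np.cos(phi)[..., None], np.sin(phi)[..., None]
    d = bond * (-cos_t * bc_hat + sin_t * (cos_p * m + sin_p * n_hat))
    return c + d


def build_backbone_batch(
    phi: np.ndarray,
    psi: np.ndarray,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Backbones for a batch of dihedral sequences.

    ``phi`` and ``psi`` have shape (..., n_residues); the result has shape
    (..., n_residues, 4, 3) with atoms ordered N, CA, C, O.  phi of the
    first residue is unused (there is no preceding carbonyl); psi of the
    last residue only orients its carbonyl oxygen.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have the same shape")
    n_res = phi.shape[-1]
    if n_res < 2:
        raise ValueError("a backbone needs at least 2 residues")
    batch = phi.shape[:-1]
    g = geometry

    n = np.empty(batch + (n_res, 3))
    ca = np.empty_like(n)
    c = np.empty_like(n)

    # first residue in a fixed local frame
    n[..., 0, :] = 0.0
    ca[..., 0, :] = np.array([g.n_ca, 0.0, 0.0])
    theta = np.radians(g.ang_n_ca_c)
    c[..., 0, :] = ca[..., 0, :] + g.ca_c * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )

    for i in range(1, n_res):
        n[..., i, :] = _place(
            n[..., i - 1, :], ca[..., i - 1, :], c[..., i - 1, :],
            g.c_n, g.ang_ca_c_n, psi[..., i - 1],
        )
        ca[..., i, :] = _place(
            ca[..., i - 1, :], c[..., i - 1, :], n[..., i, :],
            g.n_ca, g.ang_c_n_ca, g.omega_deg,
        )
        c[..., i, :] = _place(
            c[..., i - 1, :], n[..., i, :], ca[..., i, :],
            g.ca_c, g.ang_n_ca_c, phi[..., i],
        )

    # carbonyl O in the peptide plane: torsion(N, CA, C, O) = psi - 180
    o = _place(n, ca, c, g.c_o, g.ang_ca_c_o, psi - 180.0)
    return np.stack([n, ca, c, o], axis=-2)


def build_backbone(
    dihedrals: Sequence[tuple[float, float]] | np.ndarray,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> np.ndarray:
    """Backbone coordinates (n_residues, 4, 3) for one (phi, psi) sequence."""
    arr = np.asarray(dihedrals, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("dihedrals must be a sequence of (phi, psi) pairs")
    return build_backbone_batch(arr[:, 0], arr[:, 1], geometry)


_BACKBONE_ATOMS = ("N", "CA", "C", "O")
_ELEMENTS = ("N", "C", "C", "O")


def frame_from_backbone(
    coords: np.ndarray,
    residue_names: Sequence[str] | None = None,
    first_residue_seq: int = 1,
    chain: str = "A",
    model_index: int = 0,
    box: np.ndarray | None = None,
) -> Frame:
    """Wrap (n_residues, 4, 3) backbone coordinates in a :class:`Frame`."""
    n_res = coords.shape[0]
    if residue_names is None:
        residue_names = ["ALA"] * n_res
    atoms: list[AtomRecord] = []
    serial = 1
    for r in range(n_res):
        for k, name in enumerate(_BACKBONE_ATOMS):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name=residue_names[r],
                    chain_id=chain,
                    residue_seq=first_residue_seq + r,
                    position=coords[r, k],
                    element=_ELEMENTS[k],
                )
            )
            serial += 1
    return Frame(model_index=model_index, atoms=atoms, box=box)


def default_residue_names(spec: SyntheticTrajectorySpec) -> list[str]:
    """ALA background with the Thr-Gly-Val(-Thr) motif at the region."""
    names = ["ALA"] * spec.n_residues
    motif = ("THR", "GLY", "VAL", "THR")
    lo, _ = spec.planted_region
    for k, row in enumerate(spec.region_rows):
        names[row] = motif[k % 4]
    return names


# ---------------------------------------------------------------------------
# water boxes with planted hydrogen-bonded trimers
# ---------------------------------------------------------------------------


@dataclass
class WaterBoxSpec:
    """A water box: planted three-water rings plus an inert background.

    ``n_waters`` counts the background waters; each entry of
    ``planted_trimers`` is the centre of one ring of three mutually
    hydrogen-bonded waters (O-O 2.75 A).  Background oxygens are kept at
    least ``min_separation`` (default 5 A) from every other oxygen, which
    together with generation-time energy validation guarantees they form
    no hydrogen bonds.
    """

    n_waters: int = 0
    box: np.ndarray = field(default_factory=lambda: np.array([40.0, 40.0, 40.0]))
    planted_trimers: tuple = ()
    min_separation: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)


def make_water(position: np.ndarray, rng: np.random.Generator) -> WaterMolecule:
    """A randomly oriented rigid TIP3P water at the given oxygen position."""
    rot = Rotation.random(rng=rng).as_matrix()
    half = np.radians(104.52 / 2.0)
    h_local = 0.9572 * np.array(
        [[np.sin(half), np.cos(half), 0.0], [-np.sin(half), np.cos(half), 0.0]]
    )
    h = h_local @ rot.T + position
    return WaterMolecule(np.asarray(position, dtype=float), h[0], h[1])


def make_trimer(
    center: np.ndarray,
    rng: np.random.Generator,
    oo_distance: float = 2.758,
    params: TIP3PParameters = DEFAULT_TIP3P,
    max_tries: int = 200,
) -> list[WaterMolecule]:
    """Three mutually hydrogen-bonded waters on a ring around ``center``.

    The oxygens sit on an equilateral triangle of side ``oo_distance`` in
    a randomly oriented plane.  Each water donates one O-H towards the
    next oxygen, rotated 14.65 degrees outward in the ring plane, with the
    free hydrogen also in-plane; this is the planar C3-symmetric minimum
    of the cyclic TIP3P trimer (about -5.8 kcal/mol per pair at the
    default side length), found by numerical minimisation of the summed
    pair energies.  The construction is validated against the cutoff at
    generation time, perturbing the geometry if a non-default side length
    ever leaves a pair unbonded.
    """
    center = np.asarray(center, dtype=float)
    circumradius = oo_distance / np.sqrt(3.0)
    half = np.radians(104.52)
    delta0 = np.radians(14.65)  # in-plane outward offset of the donated O-H
    for attempt in range(max_tries):
        basis = Rotation.random(rng=rng).as_matrix()
        e1, e2, e3 = basis
        delta = delta0 if attempt == 0 else delta0 + rng.normal(0.0, 0.05)
        vertices = [
            center + circumradius * (np.cos(a) * e1 + np.sin(a) * e2)
            for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        ]
        waters = []
        for k in range(3):
            o = vertices[k]
            u = vertices[(k + 1) % 3] - o
            u /= np.linalg.norm(u)
            outward = o - center
            outward -= np.dot(outward, u) * u
            outward /= np.linalg.norm(outward)
            hdir = np.cos(delta) * u + np.sin(delta) * outward
            h1 = o + 0.9572 * hdir
            m = np.cross(e3, hdir)
            m /= np.linalg.norm(m)
            fdir = np.cos(half) * hdir - np.sin(half) * m
            h2 = o + 0.9572 * fdir
            waters.append(WaterMolecule(o, h1, h2))
        energies = [
            pair_energy(waters[i], waters[j], params)
            for i, j in ((0, 1), (1, 2), (0, 2))
        ]
        if all(e <= params.hbond_energy_cutoff for e in energies):
            return waters
    raise PackingError("could not orient a hydrogen-bonded trimer")


def generate_water_box(
    spec: WaterBoxSpec, params: TIP3PParameters = DEFAULT_TIP3P
) -> list[WaterMolecule]:
    """Planted trimers plus a validated inert background of waters.

    Background oxygens are rejection-sampled uniformly in the box to
    respect ``min_separation`` from every existing oxygen; each accepted
    background water is additionally checked to bond with nothing (pair
    energy above the cutoff against every prior water), re-drawing its
    position and orientation otherwise.  Raises :class:`PackingError`
    when the box cannot accommodate the request.
    """
    rng = np.random.default_rng(spec.seed)
    waters: list[WaterMolecule] = []
    for center in spec.planted_trimers:
        waters.extend(make_trimer(np.asarray(center, dtype=float), rng, params=params))

    def oxygen_array() -> np.ndarray:
        return np.array([w.oxygen for w in waters]).reshape(-1, 3)

    max_tries = 2000 * max(spec.n_waters, 1)
    placed = 0
    tries = 0
    while placed < spec.n_waters:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"placed only {placed}/{spec.n_waters} background waters"
            )
        position = rng.random(3) * spec.box
        oxygens = oxygen_array()
        if oxygens.size and np.min(
            np.linalg.norm(oxygens - position, axis=1)
        ) < spec.min_separation:
            continue
        candidate = make_water(position, rng)
        if any(
            pair_energy(candidate, w, params) <= params.hbond_energy_cutoff
            for w in waters
        ):
            continue
        waters.append(candidate)
        placed += 1
    for seq, water in enumerate(waters):
        water.residue_seq = seq + 1
    return waters


def water_atoms(
    waters: Sequence[WaterMolecule],
    chain: str = "W",
    first_residue_seq: int | None = None,
    first_serial: int = 1,
) -> list[AtomRecord]:
    """AtomRecords (O, H1, H2 per molecule) for embedding waters in a frame."""
    atoms: list[AtomRecord] = []
    serial = first_serial
    seqs = [w.residue_seq for w in waters]
    if first_residue_seq is None and len(set(seqs)) != len(seqs):
        first_residue_seq = 1  # unnumbered waters: assign sequentially
    for k, water in enumerate(waters):
        seq = water.residue_seq if first_residue_seq is None else first_residue_seq + k
        for name, element, pos in (
            ("O", "O", water.oxygen),
            ("H1", "H", water.h1),
            ("H2", "H", water.h2),
        ):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name="HOH",
                    chain_id=chain,
                    residue_seq=seq,
                    position=pos,
                    element=element,
                )
            )
            serial += 1
    return atoms


# ---------------------------------------------------------------------------
# end-to-end assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTrajectory:
    """A generated trajectory together with its ground truth."""

    trajectory: Trajectory
    truth_mask: np.ndarray  # per-frame planted presence
    labels: np.ndarray  # (n_residues, n_frames) state indices
    dihedrals: SampledDihedrals


def synthesize_trajectory(
    spec: SyntheticTrajectorySpec,
    states: Sequence[ConformationalState] = DEFAULT_STATES,
    spread_scale: float = 1.0,
    residue_names: Sequence[str] | None = None,
) -> SyntheticTrajectory:
    """Labels -> dihedrals -> backbone coordinates -> trajectory.

    With ``spread_scale=0`` the dihedrals equal the state means, so the
    analysis pipeline recovers the planted presence mask exactly.
    """
    labels, mask = simulate_labels(spec)
    sampled = sample_dihedrals(labels, states, seed=spec.seed + 1,
                               spread_scale=spread_scale)
    # build per-frame backbones: batch dimension = frames
    coords = build_backbone_batch(sampled.phi.T, sampled.psi.T)  # (F, R, 4, 3)
    names = list(residue_names) if residue_names else default_residue_names(spec)
    frames = [
        frame_from_backbone(
            coords[f],
            residue_names=names,
            first_residue_seq=spec.first_residue_seq,
            model_index=f,
        )
        for f in range(spec.n_frames)
    ]
    traj = Trajectory(frames, frame_interval_ps=spec.frame_interval_ps)
    return SyntheticTrajectory(
        trajectory=traj, truth_mask=mask, labels=labels, dihedrals=sampled
    )


def write_synthetic_trajectory(
    synthetic: SyntheticTrajectory, path, truth_path=None
) -> None:
    """Write the trajectory as multi-model PDB plus a truth sidecar table.

    The sidecar is a CSV with one row per frame (frame, present) so that
    recovery tests can compare the pipeline output against the planted
    ground truth without re-running the generator.
    """
    traj = synthetic.trajectory
    if len(synthetic.truth_mask) != traj.n_frames:
        raise ValueError("truth mask length does not match the trajectory")
    write_multimodel_pdb(traj, path)
    if truth_path is not None:
        with open(truth_path, "w") as handle:
            handle.write("frame,present\n")
            for f, present in enumerate(synthetic.truth_mask):
                handle.write(f"{f},{int(present)}\n")
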