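"""Topological water-network (TWN) analysis around selected residues.

Water-water interactions are scored with the rigid TIP3P pair potential:
nine site-site Coulomb terms plus a single oxygen-oxygen Lennard-Jones
term,

    v(a, b) = k * sum_ij q_i q_j / r_ij + A / r_oo^12 - C / r_oo^6

with A = 582,000 kcal A^12/mol, C = 595 kcal A^6/mol, q_O = -0.834 e,
q_H = +0.417 e and k = 332.0636 kcal A / (mol e^2).  Two waters count as
hydrogen bonded when their pair energy is at or below -2.25 kcal/mol, the
minimum of the pair-energy distribution of the potential.  The hydrogen
bond graph over all waters then defines the topological network; the motif
analysed here is the three-membered ring, i.e. a triangle of mutually
bonded waters.

Ring counts are taken inside spheres (default radii 15 and 20 A) centred
on the C-alpha of each residue of interest, and frames are stratified by
whether the residue region is in the alpha-strand conformation, so that
the water structure around the strand can be compared between the two
states.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dihedral_analysis import StrandTimeSeries
from .trajectory_io import Frame, Trajectory, WaterMolecule, split_protein_water

#: Conversion factor e^2 -> kcal*Angstrom/mol for Coulomb terms.
COULOMB_KCAL = 332.0636


class SingularGeometryError(ValueError):
    """Two interaction sites coincide; the pair energy diverges."""


@dataclass(frozen=True)
class TIP3PParameters:
    """TIP3P pair-potential parameters and the hydrogen-bond criterion."""

    A: float = 582000.0  # kcal A^12 / mol, O-O repulsion
    C: float = 595.0  # kcal A^6 / mol, O-O attraction
    q_O: float = -0.834  # e
    q_H: float = 0.417  # e
    coulomb_constant: float = COULOMB_KCAL  # kcal A / (mol e^2)
    hbond_energy_cutoff: float = -2.25  # kcal/mol, inclusive

    @property
    def charges(self) -> np.ndarray:
        return np.array([self.q_O, self.q_H, self.q_H])


DEFAULT_TIP3P = TIP3PParameters()


def _minimum_image(vec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return vec
    box = np.asarray(box, dtype=float)
    return vec - box * np.round(vec / box)


def pair_energy(
    a: WaterMolecule,
    b: WaterMolecule,
    params: TIP3PParameters = DEFAULT_TIP3P,
    box: np.ndarray | None = None,
) -> float:
    """TIP3P interaction energy of two waters in kcal/mol.

    Symmetric in its arguments.  Under periodic boundaries the second
    molecule is shifted rigidly by the minimum-image offset of the O-O
    separation, so the intramolecular geometry is preserved.
    """
    sa = a.sites()
    shift = _minimum_image(b.oxygen - a.oxygen, box) - (b.oxygen - a.oxygen)
    sb = b.sites() + shift
    diff = sb[None, :, :] - sa[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    if np.min(dist) < 1e-6:
        raise SingularGeometryError("coincident interaction sites between waters")
    q = params.charges
    coulomb = params.coulomb_constant * np.sum(np.outer(q, q) / dist)
    r_oo = dist[0, 0]
    lj = params.A / r_oo**12 - params.C / r_oo**6
    return float(coulomb + lj)


def pair_energy_matrix(
    waters: Sequence[WaterMolecule],
    params: TIP3PParameters = DEFAULT_TIP3P,
    box: np.ndarray | None = None,
) -> np.ndarray:
    """All-pairs TIP3P energies as a symmetric (n, n) array, diagonal 0."""
    n = len(waters)
    sites = np.array([w.sites() for w in waters])  # (n, 3, 3)
    if box is not None:
        d_oo = sites[None, :, 0, :] - sites[:, None, 0, :]
        shift = _minimum_image(d_oo, box) - d_oo  # (n, n, 3)
    else:
        shift = np.zeros((n, n, 3))
    # pairwise site-site distances: (n, n, 3 sites of a, 3 sites of b)
    diff = (
        sites[None, :, None, :, :]
        + shift[:, :, None, None, :]
        - sites[:, None, :, None, :]
    )
    dist = np.linalg.norm(diff, axis=-1)
    np.einsum("iikl->ikl", dist)[:] = np.inf  # mask self-interaction
    q = params.charges
    coulomb = params.coulomb_constant * np.sum(
        (q[:, None] * q[None, :])[None, None] / dist, axis=(-2, -1)
    )
    r_oo = dist[:, :, 0, 0]
    energy = coulomb + params.A / r_oo**12 - params.C / r_oo**6
    np.fill_diagonal(energy, 0.0)
    return energy


def build_hbond_graph(
    waters: Sequence[WaterMolecule],
    params: TIP3PParameters = DEFAULT_TIP3P,
    prefilter_oo: float | None = 6.0,
    box: np.ndarray | None = None,
) -> nx.Graph:
    """Hydrogen-bond graph: edge iff pair energy <= the cutoff.

    Nodes are water indices (into ``waters``); every edge carries its
    ``pair_energy`` attribute.  ``prefilter_oo`` skips pairs whose O-O
    distance exceeds the given radius; at 6 A this is a pure optimisation,
    since the TIP3P pair energy cannot reach -2.25 kcal/mol beyond it
    (worst-case dipole-dipole attraction is under 1 kcal/mol at 6 A).
    Pass ``None`` to evaluate all pairs.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(waters)))
    if len(waters) < 2:
        return graph

    if prefilter_oo is None:
        energies = pair_energy_matrix(waters, params, box)
        idx_i, idx_j = np.nonzero(
            np.triu(energies <= params.hbond_energy_cutoff, k=1)
        )
        for i, j in zip(idx_i, idx_j):
            graph.add_edge(int(i), int(j), pair_energy=float(energies[i, j]))
        return graph

    oxygens = np.array([w.oxygen for w in waters])
    if box is not None:
        boxarr = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(oxygens, boxarr), boxsize=boxarr)
    else:
        tree = cKDTree(oxygens)
    for i, j in tree.query_pairs(prefilter_oo):
        e = pair_energy(waters[i], waters[j], params, box)
        if e <= params.hbond_energy_cutoff:
            graph.add_edge(int(i), int(j), pair_energy=e)
    return graph


def count_three_rings(graph: nx.Graph) -> int:
    """Number of three-membered rings (triangles) in the graph."""
    return sum(nx.triangles(graph).values()) // 3


def residue_center(frame: Frame, residue_seq: int, chain: str = "A") -> np.ndarray:
    """C-alpha position of a residue (the conventional residue point)."""
    for atom in frame.atoms:
        if (
            atom.chain_id == chain
            and atom.residue_seq == residue_seq
            and atom.name == "CA"
        ):
            return atom.position
    raise ValueError(f"residue {residue_seq} (chain {chain!r}) has no CA atom")


def rings_near_residue(
    frame: Frame,
    waters: Sequence[WaterMolecule],
    residue_seq: int,
    radius: float,
    params: TIP3PParameters = DEFAULT_TIP3P,
    chain: str = "A",
    graph: nx.Graph | None = None,
    membership: str = "all_in",
    box: np.ndarray | None = None,
) -> int:
    """Three-ring count inside a sphere around a residue's C-alpha.

    The default ``membership='all_in'`` first selects the waters whose
    oxygen lies within ``radius`` of the C-alpha and counts triangles among
    them only (rings straddling the sphere boundary are excluded).  Since
    edge existence depends only on the two waters involved, this equals
    counting triangles of the full graph whose three oxygens all lie in the
    sphere.  ``membership='any_in'`` instead counts triangles of the full
    graph with at least one oxygen in the sphere (straddling rings
    included), for sensitivity analysis.

    A prebuilt ``graph`` over all ``waters`` may be supplied to avoid
    recomputing energies; otherwise one is built on demand.
    """
    center = residue_center(frame, residue_seq, chain)
    oxygens = np.array([w.oxygen for w in waters]).reshape(-1, 3)
    d = np.linalg.norm(_minimum_image(oxygens - center, box), axis=-1)
    inside = set(np.nonzero(d <= radius)[0].tolist())
    if graph is None:
        graph = build_hbond_graph(waters, params, box=box)
    if membership == "all_in":
        return count_three_rings(graph.subgraph(inside))
    if membership == "any_in":
        count = 0
        for i, j, k in _iter_triangles(graph):
            if i in inside or j in inside or k in inside:
                count += 1
        return count
    raise ValueError(f"unknown membership mode {membership!r}")


def _iter_triangles(graph: nx.Graph):
    # each triangle yielded once, via its lexicographically lowest edge
    for i, j in graph.edges():
        for k in set(graph[i]) & set(graph[j]):
            if k > max(i, j):
                yield (min(i, j), max(i, j), k)


@dataclass
class TWNTable:
    """Per-frame ring counts plus the stratified summary of interest.

    ``records`` has one row per (frame, residue, radius) with the ring
    count and whether the frame is a strand frame.  ``summary`` aggregates
    to per-residue means and their total N per (stratum, radius); a
    stratum with zero frames is simply absent from the summary.
    """

    records: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        recs = self.records.copy()
        recs["stratum"] = np.where(recs["strand_frame"], "strand", "non_strand")
        means = (
            recs.groupby(["stratum", "radius", "residue"])["ring_count"]
            .mean()
            .unstack("residue")
        )
        means["total"] = means.sum(axis=1)
        return means

    def total(self, radius: float, stratum: str) -> float:
        row = self.summary().loc[(stratum, radius)]
        return float(row["total"])


def twn_summary(
    traj: Trajectory,
    series: StrandTimeSeries,
    residues: Sequence[int],
    radii: Sequence[float] = (15.0, 20.0),
    params: TIP3PParameters = DEFAULT_TIP3P,
    chain: str = "A",
    prefilter_oo: float | None = 6.0,
    use_box: bool = True,
) -> TWNTable:
    """Stratified three-ring counts around residues over a trajectory.

    For each frame the waters are extracted, the hydrogen-bond graph is
    built once, and triangles are counted inside each (residue, radius)
    sphere.  Frames are stratified by ``series.present`` (strand versus
    non-strand), and the summary reports per-residue mean counts whose row
    sums give the total average number of three-membered rings N.
    """
    if len(series.present) != traj.n_frames:
        raise ValueError("strand series is not aligned with the trajectory")
    rows = []
    for f, frame in enumerate(traj.frames):
        box = frame.box if use_box else None
        _, waters = split_protein_water(frame)
        graph = build_hbond_graph(waters, params, prefilter_oo=prefilter_oo, box=box)
        strand = bool(series.present[f])
        for radius in radii:
            for residue in residues:
                count = rings_near_residue(
                    frame,
                    waters,
                    residue,
                    radius,
                    params=params,
                    chain=chain,
                    graph=graph,
                    box=box,
                )
                rows.append((f, residue, float(radius), count, strand))
    records = pd.DataFrame(
        rows, columns=["frame", "residue", "radius", "ring_count", "strand_frame"]
    )
    return TWNTable(records=records)
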