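"""TIP3P pair energies, hydrogen-bond graphs and water-ring counting."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alphastrand.dihedral_analysis import StrandTimeSeries
from alphastrand.synthetic_data import (
    WaterBoxSpec,
    generate_water_box,
    make_trimer,
    make_water,
    water_atoms,
)
from alphastrand.trajectory_io import Trajectory, WaterMolecule
from alphastrand.twn_analysis import (
    DEFAULT_TIP3P,
    SingularGeometryError,
    TIP3PParameters,
    TWNTable,
    build_hbond_graph,
    count_three_rings,
    pair_energy,
    pair_energy_matrix,
    rings_near_residue,
    twn_summary,
)

from conftest import peptide_frame


def oracle_pair_energy(a, b, params=DEFAULT_TIP3P):
    """Term-by-term evaluation: nine Coulomb terms plus one O-O LJ term."""
    sites_a = [a.oxygen, a.h1, a.h2]
    sites_b = [b.oxygen, b.h1, b.h2]
    charges = [params.q_O, params.q_H, params.q_H]
    total = 0.0
    for qi, pi in zip(charges, sites_a):
        for qj, pj in zip(charges, sites_b):
            r = float(np.sqrt(sum((x - y) ** 2 for x, y in zip(pi, pj))))
            total += params.coulomb_constant * qi * qj / r
    r_oo = float(np.linalg.norm(np.asarray(a.oxygen) - np.asarray(b.oxygen)))
    return total + params.A / r_oo**12 - params.C / r_oo**6


def linear_dimer(r_oo=2.75):
    """Ideal linear hydrogen-bonded dimer: donor O-H aimed at acceptor O."""
    half = np.radians(104.52 / 2.0)
    donor = WaterMolecule(
        np.zeros(3),
        np.array([0.9572, 0.0, 0.0]),
        0.9572 * np.array([np.cos(np.radians(104.52)), np.sin(np.radians(104.52)), 0.0]),
    )
    acc_o = np.array([r_oo, 0.0, 0.0])
    acceptor = WaterMolecule(
        acc_o,
        acc_o + 0.9572 * np.array([np.cos(half), np.sin(half), 0.0]),
        acc_o + 0.9572 * np.array([np.cos(half), -np.sin(half), 0.0]),
    )
    return donor, acceptor


class TestPairEnergy:
    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(100):
            a = make_water(rng.random(3) * 10.0, rng)
            b = make_water(rng.random(3) * 10.0 + np.array([10.0, 0, 0]), rng)
            assert pair_energy(a, b) == pytest.approx(
                oracle_pair_energy(a, b), abs=1e-9
            )

    def test_symmetry(self, rng):
        a = make_water(np.array([0.0, 0.0, 0.0]), rng)
        b = make_water(np.array([3.0, 1.0, 0.5]), rng)
        assert pair_energy(a, b) == pytest.approx(pair_energy(b, a), abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        a = make_water(np.array([0.0, 0.0, 0.0]), rng)
        b = make_water(np.array([2.9, 0.4, -0.2]), rng)
        e0 = pair_energy(a, b)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 8
        moved = [
            WaterMolecule(w.oxygen @ rot + shift, w.h1 @ rot + shift, w.h2 @ rot + shift)
            for w in (a, b)
        ]
        assert pair_energy(*moved) == pytest.approx(e0, abs=1e-9)

    def test_long_range_limit(self, rng):
        a = make_water(np.zeros(3), rng)
        b = make_water(np.array([100.0, 0.0, 0.0]), rng)
        assert abs(pair_energy(a, b)) < 0.01

    def test_coincident_sites_singular(self, rng):
        a = make_water(np.zeros(3), rng)
        with pytest.raises(SingularGeometryError):
            pair_energy(a, a)

    def test_linear_dimer_is_hydrogen_bonded(self):
        donor, acceptor = linear_dimer(2.75)
        energy = pair_energy(donor, acceptor)
        assert energy <= DEFAULT_TIP3P.hbond_energy_cutoff
        assert energy == pytest.approx(oracle_pair_energy(donor, acceptor), abs=1e-9)

    def test_matrix_agrees_with_pairwise(self, rng):
        waters = [make_water(rng.random(3) * 8.0, rng) for _ in range(12)]
        matrix = pair_energy_matrix(waters)
        for i, j in combinations(range(12), 2):
            assert matrix[i, j] == pytest.approx(
                pair_energy(waters[i], waters[j]), abs=1e-9
            )


def brute_force_triangles(graph):
    return sum(
        1
        for trio in combinations(graph.nodes, 3)
        if graph.has_edge(trio[0], trio[1])
        and graph.has_edge(trio[1], trio[2])
        and graph.has_edge(trio[0], trio[2])
    )


class TestHBondGraph:
    def test_distant_pair_no_edge(self, rng):
        waters = [make_water(np.zeros(3), rng), make_water(np.array([50.0, 0, 0]), rng)]
        graph = build_hbond_graph(waters)
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 2

    def test_trimer_three_edges_one_ring(self, rng):
        waters = make_trimer(np.zeros(3), rng)
        graph = build_hbond_graph(waters)
        assert graph.number_of_edges() == 3
        assert count_three_rings(graph) == 1
        for _, _, data in graph.edges(data=True):
            assert data["pair_energy"] <= DEFAULT_TIP3P.hbond_energy_cutoff

    def test_edge_criterion_straddles_cutoff(self):
        """Edges track the -2.25 kcal/mol criterion exactly (inclusive)."""
        for r_oo, expect_edge in [(2.75, True), (4.5, False)]:
            waters = list(linear_dimer(r_oo))
            energy = pair_energy(*waters)
            graph = build_hbond_graph(waters)
            assert (energy <= DEFAULT_TIP3P.hbond_energy_cutoff) == expect_edge
            assert graph.has_edge(0, 1) == expect_edge

    def test_prefilter_equals_all_pairs(self, rng):
        for _ in range(10):
            waters = [make_water(rng.random(3) * 9.0, rng) for _ in range(30)]
            filtered = build_hbond_graph(waters, prefilter_oo=6.0)
            full = build_hbond_graph(waters, prefilter_oo=None)
            assert set(filtered.edges) == set(full.edges)


class TestTriangleCounting:
    def test_k3_and_k4(self):
        assert count_three_rings(nx.complete_graph(3)) == 1
        assert count_three_rings(nx.complete_graph(4)) == 4

    @given(st.integers(4, 30), st.floats(0.05, 0.5), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, n, p, seed):
        graph = nx.gnp_random_graph(n, p, seed=seed)
        assert count_three_rings(graph) == brute_force_triangles(graph)


class TestRingsNearResidue:
    def _frame_with_trimers(self, rng, inside, outside, radius_probe=15.0):
        """Protein tripeptide plus trimers at controlled distances from CA2."""
        frame = peptide_frame([(-60, -45)] * 3)
        ca = next(
            a.position for a in frame.atoms if a.residue_seq == 2 and a.name == "CA"
        )
        directions = [
            np.array(v, dtype=float)
            for v in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0),
                      (0, -1, 0), (0, 0, -1), (1, 1, 0)]
        ]
        waters = []
        for k, dist in enumerate(list(inside) + list(outside)):
            direction = directions[k] / np.linalg.norm(directions[k])
            waters.extend(make_trimer(ca + dist * direction, rng))
        frame.atoms.extend(water_atoms(waters))
        return frame, waters

    def test_planted_trimer_inside_then_outside(self, rng):
        frame, waters = self._frame_with_trimers(rng, inside=[5.0], outside=[])
        assert rings_near_residue(frame, waters, 2, radius=15.0) == 1
        assert rings_near_residue(frame, waters, 2, radius=3.0) == 0

    def test_counts_match_construction(self, rng):
        frame, waters = self._frame_with_trimers(
            rng, inside=[5.0, 8.0], outside=[25.0, 30.0]
        )
        assert rings_near_residue(frame, waters, 2, radius=15.0) == 2
        # brute force restricted to in-sphere oxygens
        ca = next(
            a.position for a in frame.atoms if a.residue_seq == 2 and a.name == "CA"
        )
        inside_idx = [
            i for i, w in enumerate(waters)
            if np.linalg.norm(w.oxygen - ca) <= 15.0
        ]
        graph = build_hbond_graph(waters)
        assert rings_near_residue(frame, waters, 2, radius=15.0) == brute_force_triangles(
            graph.subgraph(inside_idx)
        )

    def test_radius_monotonicity(self, rng):
        frame, waters = self._frame_with_trimers(
            rng, inside=[5.0, 12.0], outside=[17.0]
        )
        r15 = rings_near_residue(frame, waters, 2, radius=15.0)
        r20 = rings_near_residue(frame, waters, 2, radius=20.0)
        assert r20 >= r15

    def test_straddling_ring_modes(self):
        # place a trimer so that some but not all oxygens are in the sphere
        frame = peptide_frame([(-60, -45)] * 3)
        ca = next(
            a.position for a in frame.atoms if a.residue_seq == 2 and a.name == "CA"
        )
        waters = None
        for seed in range(50):  # deterministic search for a straddling pose
            candidate = make_trimer(
                ca + np.array([10.7, 0.0, 0.0]), np.random.default_rng(seed)
            )
            n_inside = sum(
                np.linalg.norm(w.oxygen - ca) <= 10.0 for w in candidate
            )
            if 1 <= n_inside <= 2:
                waters = candidate
                break
        assert waters is not None
        frame.atoms.extend(water_atoms(waters))
        graph = build_hbond_graph(waters)
        all_in = rings_near_residue(
            frame, waters, 2, radius=10.0, graph=graph, membership="all_in"
        )
        any_in = rings_near_residue(
            frame, waters, 2, radius=10.0, graph=graph, membership="any_in"
        )
        assert all_in == 0
        assert any_in == 1

    def test_missing_calpha_is_error(self, rng):
        frame, waters = self._frame_with_trimers(rng, inside=[5.0], outside=[])
        with pytest.raises(ValueError):
            rings_near_residue(frame, waters, 99, radius=15.0)


class TestTWNSummary:
    def test_single_frame_planted_counts(self, rng):
        frame = peptide_frame([(-60, -45), (60, 45), (-60, -45)])
        cas = {
            a.residue_seq: a.position
            for a in frame.atoms
            if a.name == "CA"
        }
        waters = []
        offsets = [np.array([8.0, 0, 0]), np.array([0, 8.0, 0]), np.array([0, 0, 8.0])]
        for seq, off in zip(sorted(cas), offsets):
            waters.extend(make_trimer(cas[seq] + off, rng))
        frame.atoms.extend(water_atoms(waters))
        traj = Trajectory([frame], frame_interval_ps=10.0)
        series = StrandTimeSeries(region=(1, 3), present=np.array([True]))
        table = twn_summary(traj, series, residues=[1, 2, 3], radii=[10.0])
        summary = table.summary()
        row = summary.loc[("strand", 10.0)]
        assert row["total"] == pytest.approx(row[[1, 2, 3]].sum())
        assert row["total"] >= 3  # each residue sees at least its own trimer

    def test_empty_stratum_absent_not_zero(self, rng):
        frame = peptide_frame([(-60, -45)] * 3)
        traj = Trajectory([frame], frame_interval_ps=10.0)
        series = StrandTimeSeries(region=(1, 3), present=np.array([False]))
        table = twn_summary(traj, series, residues=[2], radii=[15.0])
        summary = table.summary()
        assert "non_strand" in summary.index.get_level_values("stratum")
        assert "strand" not in summary.index.get_level_values("stratum")

    def test_misaligned_series_rejected(self, rng):
        frame = peptide_frame([(-60, -45)] * 3)
        traj = Trajectory([frame], frame_interval_ps=10.0)
        series = StrandTimeSeries(region=(1, 3), present=np.array([True, False]))
        with pytest.raises(ValueError):
            twn_summary(traj, series, residues=[2], radii=[15.0])


def engineered_table(per_residue_counts, n_frames, strand=True):
    """Records whose per-residue means are exactly counts/n_frames."""
    rows = []
    for residue, total in per_residue_counts.items():
        base, extra = divmod(total, n_frames)
        for f in range(n_frames):
            rows.append(
                (f, residue, 15.0, base + (1 if f < extra else 0), strand)
            )
    return TWNTable(
        records=pd.DataFrame(
            rows, columns=["frame", "residue", "radius", "ring_count", "strand_frame"]
        )
    )


class TestTableArithmetic:
    """Total N must equal the sum of per-residue means (row-sum identity)."""

    @pytest.mark.parametrize(
        "means,expected_total",
        [
            ({72: 15.20, 73: 14.75, 74: 14.52}, 44.47),
            ({72: 8.34, 73: 8.62, 74: 7.75, 75: 7.05}, 31.76),
        ],
    )
    def test_row_sum_identity(self, means, expected_total):
        n_frames = 100
        counts = {res: int(round(mean * n_frames)) for res, mean in means.items()}
        table = engineered_table(counts, n_frames, strand=False)
        summary = table.summary()
        row = summary.loc[("non_strand", 15.0)]
        for res, mean in means.items():
            assert row[res] == pytest.approx(mean, abs=1e-9)
        assert row["total"] == pytest.approx(expected_total, abs=0.01)
        assert table.total(15.0, "non_strand") == pytest.approx(
            sum(means.values()), abs=1e-9
        )
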