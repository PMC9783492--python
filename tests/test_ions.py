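"""Ion coordination statistics: minimum distances, contact frequency,
COM distance distributions, position mapping, stability check."""

import math

import numpy as np
import pytest

from efca.errors import TopologyError, WindowError
from efca.ions import (
    AnalysisWindow,
    com_distance_distribution,
    contact_frequency,
    map_alignment_positions,
    min_heavy_distance,
    stability_check,
)
from efca.sequence import MultipleAlignment
from efca.synthetic import TwoStateConfig, gen_two_state, make_probe_system, static_trajectory
from efca.trajectory import AtomRecord, RMSDSeries, Topology, Trajectory
from conftest import build_random_trajectory


def _frame_of(traj, i):
    return traj.frame(i)


# --- min heavy distance ----------------------------------------------------

def _two_atom_residue_system(res_positions, ion_positions, h_positions=()):
    atoms, coords = [], []
    idx = 0
    for pos in res_positions:
        atoms.append(AtomRecord(index=idx, name=f"C{idx}", element="C",
                                residue_number=1, residue_name="ALA"))
        coords.append(pos)
        idx += 1
    for pos in h_positions:
        atoms.append(AtomRecord(index=idx, name=f"H{idx}", element="H",
                                residue_number=1, residue_name="ALA"))
        coords.append(pos)
        idx += 1
    ions = []
    for pos in ion_positions:
        atoms.append(AtomRecord(index=idx, name="CA", element="CA",
                                residue_number=100 + idx, residue_name="CA"))
        coords.append(pos)
        ions.append(idx)
        idx += 1
    top = Topology(atoms, ion_indices=ions)
    coords = np.array(coords, dtype=float)
    return top, Trajectory(top, coords[None], np.array([0.0]))


def test_min_heavy_distance_simple():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(0, 0, 3)])
    assert min_heavy_distance(traj.frame(0), top, 1) == pytest.approx(3.0)


def test_min_heavy_distance_excludes_hydrogens():
    top, traj = _two_atom_residue_system([(2, 0, 0)], [(4, 0, 0)], h_positions=[(3, 0, 0)])
    assert min_heavy_distance(traj.frame(0), top, 1) == pytest.approx(2.0)


def test_min_heavy_distance_minimum_over_ions():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(4, 0, 0), (7, 0, 0)])
    assert min_heavy_distance(traj.frame(0), top, 1) == pytest.approx(4.0)


def test_min_heavy_distance_errors():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(4, 0, 0)])
    with pytest.raises(TopologyError):
        min_heavy_distance(traj.frame(0), top, 99)
    with pytest.raises(TopologyError):
        min_heavy_distance(traj.frame(0), top, 1, ion_indices=np.array([], dtype=int))


# --- analysis window -------------------------------------------------------

def test_window_full_span_of_grid_aligned_trajectory(probe_system):
    top, coords = probe_system
    traj = static_trajectory(top, coords, n_frames=5000, stride_ns=0.1)
    idx = AnalysisWindow(last_ns=500.0, stride_ns=0.1).frame_indices(traj)
    assert idx.size == 5000  # the paper arithmetic: 500 ns at 0.1 ns


def test_window_last_half(probe_system):
    top, coords = probe_system
    traj = static_trajectory(top, coords, n_frames=11, stride_ns=0.1)  # 0..1.0 ns
    idx = AnalysisWindow(last_ns=0.5, stride_ns=0.1).frame_indices(traj)
    assert list(traj.times[idx]) == pytest.approx([0.6, 0.7, 0.8, 0.9, 1.0])


def test_window_longer_than_trajectory_raises(probe_system):
    top, coords = probe_system
    traj = static_trajectory(top, coords, n_frames=11, stride_ns=0.1)
    with pytest.raises(WindowError):
        AnalysisWindow(last_ns=5.0, stride_ns=0.1).frame_indices(traj)
    with pytest.raises(WindowError):
        AnalysisWindow(last_ns=-1.0)


# --- contact frequency -----------------------------------------------------

def test_contact_frequency_always_within_cutoff():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(3, 0, 0)])
    coords = np.repeat(traj.coordinates, 10, axis=0)
    traj = Trajectory(top, coords, np.arange(10) * 0.1)
    table = contact_frequency(traj, AnalysisWindow(last_ns=1.0, stride_ns=0.1))
    assert table.frequency_of(1) == 1.0


def test_contact_frequency_outside_cutoff_default_5A():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(6, 0, 0)])
    coords = np.repeat(traj.coordinates, 10, axis=0)
    traj = Trajectory(top, coords, np.arange(10) * 0.1)
    table = contact_frequency(traj, AnalysisWindow(last_ns=1.0, stride_ns=0.1))
    assert table.cutoff_A == 5.0 and table.frequency_of(1) == 0.0


def _oracle_contact_frequency(trajs, window, cutoff):
    """Brute-force all-pairs oracle: python loops over frames, atoms, ions."""
    top = trajs[0].topology
    counts = {r: 0 for r in top.residue_numbers}
    total = 0
    for traj in trajs:
        for i in window.frame_indices(traj):
            total += 1
            for r in top.residue_numbers:
                best = math.inf
                for ai in top.residue_atoms[r]:
                    if not top.atoms[ai].is_heavy:
                        continue
                    for ii in top.ion_indices:
                        d = math.dist(traj.coordinates[i, ai], traj.coordinates[i, ii])
                        best = min(best, d)
                if best <= cutoff:
                    counts[r] += 1
    return {r: c / total for r, c in counts.items()}, total


def test_contact_frequency_matches_bruteforce_oracle():
    rng = np.random.default_rng(21)
    for trial in range(5):
        trajs = [build_random_trajectory(rng, n_residues=3, n_frames=20, n_ions=2)
                 for _ in range(2)]
        window = AnalysisWindow(last_ns=1.0, stride_ns=0.1)
        cutoff = float(rng.uniform(3, 12))
        table = contact_frequency(trajs, window, cutoff_A=cutoff)
        expected, total = _oracle_contact_frequency(trajs, window, cutoff)
        assert table.frames_counted == total
        for r, f in expected.items():
            assert table.frequency_of(r) == f  # exact


def test_contact_frequency_monotone_in_cutoff():
    rng = np.random.default_rng(22)
    traj = build_random_trajectory(rng, n_residues=4, n_frames=30)
    window = AnalysisWindow(last_ns=2.0, stride_ns=0.1)
    freqs = []
    for cutoff in [2.0, 4.0, 6.0, 8.0, 12.0]:
        t = contact_frequency(traj, window, cutoff_A=cutoff)
        freqs.append(t.table.frequency.to_numpy())
    for lo, hi in zip(freqs, freqs[1:]):
        assert np.all(hi >= lo)


def test_pooling_equals_averaging_for_equal_replicates():
    rng = np.random.default_rng(23)
    trajs = [build_random_trajectory(rng, n_residues=3, n_frames=20) for _ in range(3)]
    window = AnalysisWindow(last_ns=1.5, stride_ns=0.1)
    pooled = contact_frequency(trajs, window, cutoff_A=8.0)
    singles = [contact_frequency(t, window, cutoff_A=8.0) for t in trajs]
    for r in trajs[0].topology.residue_numbers:
        avg = np.mean([s.frequency_of(r) for s in singles])
        assert pooled.frequency_of(r) == pytest.approx(avg)


def test_total_time_metadata_arithmetic():
    rng = np.random.default_rng(24)
    trajs = [build_random_trajectory(rng, n_residues=2, n_frames=20) for _ in range(3)]
    table = contact_frequency(trajs, AnalysisWindow(last_ns=1.0, stride_ns=0.1))
    assert table.n_replicates == 3
    assert table.total_time_ns == pytest.approx(3 * 1.0)


def test_topology_mismatch_rejected():
    rng = np.random.default_rng(25)
    t1 = build_random_trajectory(rng, n_residues=2, n_frames=10)
    t2 = build_random_trajectory(rng, n_residues=3, n_frames=10)
    with pytest.raises(TopologyError):
        contact_frequency([t1, t2], AnalysisWindow(last_ns=0.5, stride_ns=0.1))


def test_two_state_recovery_exact():
    top, coords = make_probe_system()
    cfg = TwoStateConfig(p_bound=0.7, n_frames=500, seed=3)
    traj = gen_two_state(cfg, top, coords)
    table = contact_frequency(traj, AnalysisWindow(last_ns=50.0, stride_ns=0.1))
    assert table.frequency_of(1) == traj.metadata["bound_count"] / 500


# --- COM distance distribution --------------------------------------------

def test_com_distance_hand_case():
    top, traj = _two_atom_residue_system([(0, 0, 0), (2, 0, 0)], [(4, 0, 0)])
    coords = np.repeat(traj.coordinates, 5, axis=0)
    traj = Trajectory(top, coords, np.arange(5) * 0.1)
    dist = com_distance_distribution(traj, AnalysisWindow(last_ns=0.5, stride_ns=0.1))
    row = dist.summary.iloc[0]
    assert row["mean"] == pytest.approx(3.0)  # COM at (1,0,0), ion at (4,0,0)
    assert row["q1"] == row["median"] == row["q3"]  # static => zero dispersion
    assert not row["non_coordinating"]


def test_com_distance_non_coordinating_flag():
    top, traj = _two_atom_residue_system([(0, 0, 0)], [(10, 0, 0)])
    coords = np.repeat(traj.coordinates, 5, axis=0)
    traj = Trajectory(top, coords, np.arange(5) * 0.1)
    dist = com_distance_distribution(traj, AnalysisWindow(last_ns=0.5, stride_ns=0.1))
    assert bool(dist.summary.iloc[0]["non_coordinating"])  # mean 10 > 9 A


def _oracle_com_distances(traj, window, resnum):
    top = traj.topology
    out = []
    for i in window.frame_indices(traj):
        num = np.zeros(3)
        mass = 0.0
        for ai in top.residue_atoms[resnum]:
            a = top.atoms[ai]
            if not a.is_heavy:
                continue
            num += a.mass * traj.coordinates[i, ai]
            mass += a.mass
        com = num / mass
        out.append(min(math.dist(com, traj.coordinates[i, ii]) for ii in top.ion_indices))
    return np.array(out)


def test_com_distance_matches_bruteforce_oracle():
    rng = np.random.default_rng(26)
    traj = build_random_trajectory(rng, n_residues=3, n_frames=25, n_ions=2)
    window = AnalysisWindow(last_ns=2.0, stride_ns=0.1)
    dist = com_distance_distribution(traj, window)
    for resnum in traj.topology.residue_numbers:
        expected = _oracle_com_distances(traj, window, resnum)
        assert np.allclose(np.sort(dist.distances[resnum]), np.sort(expected))
        row = dist.summary[dist.summary.residue_number == resnum].iloc[0]
        assert row["median"] == pytest.approx(np.median(expected))
        q1, q3 = np.percentile(expected, [25, 75])
        assert row["q1"] == pytest.approx(q1) and row["q3"] == pytest.approx(q3)
        assert row["min"] <= row["q1"] <= row["median"] <= row["q3"] <= row["max"]


# --- alignment position map ------------------------------------------------

def test_position_map_gap_at_47_subtract_rule():
    row = "A" * 46 + "-" + "A" * 30  # 77 columns, gap at 47
    aln = MultipleAlignment(ids=("g",), rows=(row,))
    pm = map_alignment_positions(aln)
    assert pm.residue_for("g", 25) == 25
    assert pm.residue_for("g", 50) == 49
    assert pm.residue_for("g", 47) is None
    assert pm.gap_columns["g"] == (47,)


def test_position_map_gap_free_is_identity():
    aln = MultipleAlignment(ids=("a",), rows=("DKDGDG",))
    pm = map_alignment_positions(aln)
    assert [pm.residue_for("a", c) for c in range(1, 7)] == [1, 2, 3, 4, 5, 6]


def test_position_map_hand_case():
    aln = MultipleAlignment(ids=("a",), rows=("AB-C".replace("B", "C"),))
    pm = map_alignment_positions(aln)
    assert pm.residue_for("a", 1) == 1
    assert pm.residue_for("a", 2) == 2
    assert pm.residue_for("a", 3) is None
    assert pm.residue_for("a", 4) == 3
    assert pm.column_for("a", 3) == 4


def test_position_map_strictly_increasing_and_complete(fixture_set):
    pm = map_alignment_positions(fixture_set.alignment)
    for sid in fixture_set.alignment.ids:
        vals = [pm.residue_for(sid, c) for c in range(1, fixture_set.alignment.column_count + 1)]
        non_gap = [v for v in vals if v is not None]
        assert non_gap == sorted(non_gap)
        assert len(non_gap) == len(fixture_set.alignment.ungapped(sid))


# --- stability check -------------------------------------------------------

def test_stability_constant_series():
    s = RMSDSeries(times=np.arange(5) * 0.1, values=np.full(5, 1.3))
    fluct, stable = stability_check(s)
    assert fluct == 0.0 and stable


def test_stability_oscillating_series_unstable():
    s = RMSDSeries(times=np.arange(6) * 0.1, values=np.array([1.0, 2.5, 1.0, 2.5, 1.0, 2.5]))
    fluct, stable = stability_check(s)
    assert fluct == pytest.approx(1.5) and not stable  # default threshold 1 A


def test_stability_windowed():
    values = np.array([0.0, 5.0, 1.0, 1.2, 1.1, 1.3])
    s = RMSDSeries(times=np.arange(6) * 0.1, values=values)
    fluct, stable = stability_check(s, last_ns=0.3)
    assert fluct == pytest.approx(0.3) and stable


def test_stability_empty_window_raises():
    s = RMSDSeries(times=np.array([]), values=np.array([]))
    with pytest.raises(WindowError):
        stability_check(s)
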