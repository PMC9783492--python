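"""Per-residue Ca2+ coordination statistics from MD trajectories.

This is the analysis core: the fraction of sampled frames in which each
residue's minimum heavy-atom distance to any Ca2+ ion is within a cutoff
(5 A by default), the distribution of the distance between each residue's
centre of mass and the nearest ion, replicate pooling, a stability check on
RMSD series, and the alignment-column <-> model-residue position map used to
compare profiles across sequences with gaps.

Frames are sampled from the last ``last_ns`` of each replicate on a stride
grid (defaults: last 500 ns at 0.1 ns, i.e. 5000 frames per replicate) and
pooled across replicates, so the metadata arithmetic is
``total_time_ns = n_replicates * last_ns``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import TopologyError, WindowError
from .sequence import MultipleAlignment
from .trajectory import Frame, RMSDSeries, Topology, Trajectory

DEFAULT_CUTOFF_A = 5.0
NON_COORDINATING_MEAN_A = 9.0
DEFAULT_RMSD_FLUCTUATION_A = 1.0


@dataclass(frozen=True)
class AnalysisWindow:
    """Sampling window: the last ``last_ns`` of a trajectory at ``stride_ns``."""

    last_ns: float = 500.0
    stride_ns: float = 0.1

    def __post_init__(self) -> None:
        if self.last_ns <= 0 or self.stride_ns <= 0:
            raise WindowError("last_ns and stride_ns must be positive")

    def frame_indices(self, traj: Trajectory) -> np.ndarray:
        """Indices of the frames sampled by this window.

        Frames with time > t_end - last_ns are eligible, so a trajectory of
        n frames on the window's own stride contributes exactly
        last_ns/stride_ns frames.  Eligible frames are then matched to the
        stride grid by nearest sample time.  The window must not exceed the
        trajectory by more than one native stride.
        """
        span = traj.span_ns
        native = traj.stride_ns if traj.n_frames > 1 else self.stride_ns
        if self.last_ns > span + native + 1e-9:
            raise WindowError(
                f"window of {self.last_ns} ns exceeds trajectory span of {span:.6g} ns"
            )
        t_end = float(traj.times[-1])
        t_open = t_end - self.last_ns
        grid = t_open + self.stride_ns * np.arange(1, int(round(self.last_ns / self.stride_ns)) + 1)
        eligible = np.nonzero(traj.times > t_open + 1e-9)[0]
        if eligible.size == 0:
            raise WindowError("window selects no frames")
        # nearest eligible frame per grid point, deduplicated in time order
        times = traj.times[eligible]
        pos = np.clip(np.searchsorted(times, grid), 0, times.size - 1)
        pos_left = np.clip(pos - 1, 0, times.size - 1)
        choose_left = np.abs(times[pos_left] - grid) <= np.abs(times[pos] - grid)
        nearest = np.where(choose_left, pos_left, pos)
        return eligible[np.unique(nearest)]


def min_heavy_distance(frame: Frame, topology: Topology, residue_number: int,
                       ion_indices: np.ndarray | None = None) -> float:
    """Minimum distance (A) between a residue's heavy atoms and any ion."""
    ions = topology.ion_indices if ion_indices is None else np.asarray(ion_indices, dtype=int)
    if ions.size == 0:
        raise TopologyError("no ions in topology")
    heavy = topology.heavy_atoms_of(residue_number)
    d = frame.coordinates[heavy][:, None, :] - frame.coordinates[ions][None, :, :]
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def _pool_frames(trajs: list[Trajectory], window: AnalysisWindow) -> tuple[Topology, np.ndarray, int]:
    if not trajs:
        raise TopologyError("need at least one trajectory")
    top = trajs[0].topology
    for t in trajs[1:]:
        if not top.same_layout(t.topology):
            raise TopologyError("replicates have mismatching topologies")
    if top.ion_indices.size == 0:
        raise TopologyError("no Ca2+ ions in topology")
    pooled = [t.coordinates[window.frame_indices(t)] for t in trajs]
    coords = np.concatenate(pooled, axis=0)
    return top, coords, len(trajs)


@dataclass
class ContactFrequencyTable:
    """Per-residue Ca2+ contact frequency with its sampling metadata."""

    table: pd.DataFrame  # residue_number, residue_name, frequency, frames_within
    cutoff_A: float
    frames_counted: int
    n_replicates: int
    last_ns: float
    stride_ns: float

    @property
    def total_time_ns(self) -> float:
        return self.n_replicates * self.last_ns

    def frequency_of(self, residue_number: int) -> float:
        row = self.table.loc[self.table.residue_number == residue_number, "frequency"]
        return float(row.iloc[0])

    def max_normalized(self) -> pd.DataFrame:
        """Optional view with frequencies scaled to the most-visited residue."""
        out = self.table.copy()
        peak = out.frequency.max()
        out["frequency_norm"] = out.frequency / peak if peak > 0 else 0.0
        return out

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["frames_counted"] = self.frames_counted
        out["cutoff_A"] = self.cutoff_A
        out.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "cutoff_A": self.cutoff_A,
            "frames_counted": self.frames_counted,
            "n_replicates": self.n_replicates,
            "last_ns": self.last_ns,
            "stride_ns": self.stride_ns,
            "total_time_ns": self.total_time_ns,
        }


def contact_frequency(trajs: list[Trajectory] | Trajectory,
                      window: AnalysisWindow | None = None,
                      cutoff_A: float = DEFAULT_CUTOFF_A) -> ContactFrequencyTable:
    """Fraction of pooled frames with min heavy-atom distance to any ion <= cutoff.

    Replicates are aggregated by pooling their sampled frames (frame-weighted),
    so with equal-length replicates pooling coincides with averaging the
    per-replicate frequencies.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    window = window or AnalysisWindow()
    top, coords, n_rep = _pool_frames(trajs, window)
    ions = top.ion_indices
    rows = []
    for resnum in top.residue_numbers:
        heavy = top.heavy_atoms_of(resnum)
        d = coords[:, heavy, None, :] - coords[:, None, ions, :]
        min_d = np.sqrt((d ** 2).sum(axis=3)).reshape(coords.shape[0], -1).min(axis=1)
        within = int((min_d <= cutoff_A).sum())
        rows.append(
            {
                "residue_number": resnum,
                "residue_name": top.residue_names[resnum],
                "frequency": within / coords.shape[0],
                "frames_within": within,
            }
        )
    return ContactFrequencyTable(
        table=pd.DataFrame(rows),
        cutoff_A=cutoff_A,
        frames_counted=coords.shape[0],
        n_replicates=n_rep,
        last_ns=window.last_ns,
        stride_ns=window.stride_ns,
    )


@dataclass
class DistanceDistribution:
    """Per-residue COM-to-nearest-ion distances and boxplot summaries.

    Residues whose mean distance exceeds 9 A are flagged ``non_coordinating``
    (too far for a coordination state to be reached); the flag is reporting
    only and filters nothing.
    """

    distances: dict[int, np.ndarray]
    summary: pd.DataFrame  # residue_number, residue_name, min, q1, median, q3, max, mean, non_coordinating
    com_atoms: str = "heavy"

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def com_distance_distribution(trajs: list[Trajectory] | Trajectory,
                              window: AnalysisWindow | None = None,
                              residue_set: list[int] | None = None,
                              com_atoms: str = "heavy") -> DistanceDistribution:
    """Distance between each residue's centre of mass and the nearest Ca2+ ion.

    The COM is mass-weighted over the residue's heavy atoms by default
    (``com_atoms='all'`` includes hydrogens); the nearest ion is resolved per
    frame independently.  Quartiles use linear interpolation.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    window = window or AnalysisWindow()
    top, coords, _ = _pool_frames(trajs, window)
    ions = top.ion_indices
    residues = residue_set if residue_set is not None else top.residue_numbers
    distances: dict[int, np.ndarray] = {}
    rows = []
    for resnum in residues:
        if com_atoms == "heavy":
            idx = top.heavy_atoms_of(resnum)
        else:
            idx = top.residue_atoms.get(resnum)
            if idx is None:
                raise TopologyError(f"no residue numbered {resnum}")
        masses = top.masses[idx]
        com = (coords[:, idx, :] * masses[None, :, None]).sum(axis=1) / masses.sum()
        d = np.sqrt(((com[:, None, :] - coords[:, ions, :]) ** 2).sum(axis=2)).min(axis=1)
        distances[resnum] = d
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        mean = float(d.mean())
        rows.append(
            {
                "residue_number": resnum,
                "residue_name": top.residue_names[resnum],
                "min": float(d.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(d.max()),
                "mean": mean,
                "non_coordinating": mean > NON_COORDINATING_MEAN_A,
            }
        )
    return DistanceDistribution(distances=distances, summary=pd.DataFrame(rows), com_atoms=com_atoms)


@dataclass(frozen=True)
class PositionMap:
    """Alignment column <-> model residue number maps, one per sequence row.

    Residue numbers count non-gap columns, so a row with a single gap at
    column g maps column c to residue c for c < g and to residue c - 1 for
    c > g — the generic form of the subtract-one-after-the-gap rule.
    """

    ids: tuple[str, ...]
    column_to_residue: dict[str, dict[int, int]]
    gap_columns: dict[str, tuple[int, ...]]

    def residue_for(self, seq_id: str, column: int) -> int | None:
        """Model residue number at an alignment column (None on a gap)."""
        return self.column_to_residue[seq_id].get(column)

    def column_for(self, seq_id: str, residue_number: int) -> int:
        for col, res in self.column_to_residue[seq_id].items():
            if res == residue_number:
                return col
        raise KeyError(f"residue {residue_number} not mapped for {seq_id!r}")


def map_alignment_positions(alignment: MultipleAlignment) -> PositionMap:
    """Build the alignment-column <-> residue-number map for every row."""
    col_maps: dict[str, dict[int, int]] = {}
    gaps: dict[str, tuple[int, ...]] = {}
    for seq_id, row in zip(alignment.ids, alignment.rows):
        mapping: dict[int, int] = {}
        gap_cols = []
        count = 0
        for col, ch in enumerate(row, start=1):
            if ch == "-":
                gap_cols.append(col)
            else:
                count += 1
                mapping[col] = count
        col_maps[seq_id] = mapping
        gaps[seq_id] = tuple(gap_cols)
    return PositionMap(ids=alignment.ids, column_to_residue=col_maps, gap_columns=gaps)


def stability_check(series: RMSDSeries, last_ns: float | None = None,
                    threshold_A: float = DEFAULT_RMSD_FLUCTUATION_A) -> tuple[float, bool]:
    """Max RMSD fluctuation (max - min, A) in a window and a stability verdict.

    ``last_ns=None`` evaluates the full series; otherwise frames with
    time > t_end - last_ns are used.  A series is stable when the fluctuation
    does not exceed ``threshold_A`` (1 A by default).
    """
    values = np.asarray(series.values, dtype=float)
    times = np.asarray(series.times, dtype=float)
    if last_ns is not None:
        mask = times > times[-1] - last_ns - 1e-9
        values = values[mask]
    if values.size == 0:
        raise WindowError("stability window selects no frames")
    fluctuation = float(values.max() - values.min())
    return fluctuation, fluctuation <= threshold_A
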