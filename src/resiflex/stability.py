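"""Per-residue stability statistics and focal-distance ordering.

The residue-stability statistic: after best-fit alignment, the displacement
of residue *i* in frame *j* is the mean over its K_i heavy atoms of the
Euclidean distance to the matching atom of the reference structure,

    residue_dist(i, j) = (1/K_i) sum_k |A(i,j,k) - ref(i,k)| .

Per residue, the mean of residue_dist over the J frames (``stability_mean``)
and its sample standard deviation with a J-1 denominator (``stability_std``)
quantify stability: higher values mean a less stable residue.

To examine stability *around* a focal residue (T790 in the motivating
system), residues are re-indexed by their mean distance to the focal
residue: residue centers are unweighted heavy-atom centroids, the
center-to-center distance is averaged over frames, and residues are ranked
ascending, the focal residue itself at rank 0.  The cumulative average
stability at rank k is the running mean of the statistic over the first
k+1 ranked residues; its early window summarizes stability near the focal
site and supports ordering variant complexes from least to most stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ResidueLookupError, ResiflexError, TopologyError
from .model import StructureFrame, Trajectory

DEFAULT_FOCAL_RESIDUE = 790
DEFAULT_TRIM = (716, 976)
DEFAULT_K_WINDOW = 50


# ---------------------------------------------------------------------------
# elementary distances

def atom_distance(a1, a2) -> float:
    """Euclidean distance (Angstrom) between two 3-vectors."""
    a1 = np.asarray(a1, dtype=np.float64)
    a2 = np.asarray(a2, dtype=np.float64)
    if not (np.all(np.isfinite(a1)) and np.all(np.isfinite(a2))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a1 - a2))


def residue_distance(frame: StructureFrame, reference: StructureFrame,
                     residue_number: int) -> float:
    """Mean over the residue's atoms of the distance to the reference atom.

    Atoms are paired by atom_id (identical topology required).
    """
    if frame.topology != reference.topology:
        raise TopologyError("frame and reference have different topologies")
    top = frame.topology
    where = np.flatnonzero(top.residue_numbers == residue_number)
    if len(where) == 0:
        raise ResidueLookupError(
            f"residue {residue_number} not in topology "
            f"({top.residue_numbers[0]}-{top.residue_numbers[-1]})"
        )
    r = int(where[0])
    s = int(top.residue_starts[r])
    e = s + int(top.residue_sizes[r])
    d = np.linalg.norm(frame.coordinates[s:e] - reference.coordinates[s:e],
                       axis=1)
    return float(d.mean())


def _per_frame_residue_dist(traj: Trajectory,
                            reference: StructureFrame) -> np.ndarray:
    """(J, R) matrix of residue_dist via a segment reduction over atoms."""
    if reference.topology != traj.topology:
        raise TopologyError("reference does not share the trajectory topology")
    top = traj.topology
    d = np.linalg.norm(traj.coordinates - reference.coordinates[None], axis=2)
    sums = np.add.reduceat(d, top.residue_starts, axis=1)
    return sums / top.residue_sizes[None, :]


# ---------------------------------------------------------------------------
# result containers

@dataclass
class StabilityProfile:
    """Per-residue stability mean/std (Angstrom), keyed by residue number."""

    residue_numbers: np.ndarray
    residue_names: Tuple[str, ...]
    heavy_counts: np.ndarray
    mean: np.ndarray
    std: Optional[np.ndarray]  # None when J == 1 (undefined)
    n_frames: int

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if np.any(self.mean < 0):
            raise ResiflexError("stability_mean must be non-negative")
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=np.float64)
            if np.any(self.std < 0):
                raise ResiflexError("stability_std must be non-negative")

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def statistic(self, which: str) -> np.ndarray:
        if which == "mean":
            return self.mean
        if which == "std":
            if self.std is None:
                raise ResiflexError("stability_std undefined for J = 1")
            return self.std
        raise ValueError(f"statistic must be 'mean' or 'std', got {which!r}")

    def value_for(self, residue_number: int, which: str = "mean") -> float:
        where = np.flatnonzero(self.residue_numbers == residue_number)
        if len(where) == 0:
            raise ResidueLookupError(f"residue {residue_number} not in profile")
        return float(self.statistic(which)[where[0]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "residue_number": self.residue_numbers,
            "residue_name": list(self.residue_names),
            "K": self.heavy_counts,
            "stability_mean_A": self.mean,
        })
        df["stability_std_A"] = self.std if self.std is not None else np.nan
        return df


@dataclass
class FocalOrdering:
    """Residues ranked by mean distance to a focal residue (rank 0 = focal)."""

    focal_residue_number: int
    residue_numbers: np.ndarray   # in topology order
    dist_to_focal: np.ndarray     # Angstrom, same order
    n_frames: int
    rank_order: np.ndarray = field(init=False)  # residue_numbers by rank

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.dist_to_focal = np.asarray(self.dist_to_focal, dtype=np.float64)
        # ascending distance, ties broken by ascending residue_number
        order = np.lexsort((self.residue_numbers, self.dist_to_focal))
        self.rank_order = self.residue_numbers[order]

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def rank_of(self, residue_number: int) -> int:
        where = np.flatnonzero(self.rank_order == residue_number)
        if len(where) == 0:
            raise ResidueLookupError(f"residue {residue_number} not in ordering")
        return int(where[0])

    def dist_for(self, residue_number: int) -> float:
        where = np.flatnonzero(self.residue_numbers == residue_number)
        if len(where) == 0:
            raise ResidueLookupError(f"residue {residue_number} not in ordering")
        return float(self.dist_to_focal[where[0]])

    def restrict(self, residue_numbers: Iterable[int]) -> "FocalOrdering":
        keep = np.isin(self.residue_numbers, np.asarray(list(residue_numbers)))
        return FocalOrdering(self.focal_residue_number,
                             self.residue_numbers[keep],
                             self.dist_to_focal[keep], self.n_frames)


@dataclass
class CumulativeCurve:
    """Running average of a stability statistic over the focal ordering."""

    statistic: str               # "mean" or "std"
    values: np.ndarray           # c_0 .. c_{R-1}, Angstrom
    residue_numbers: np.ndarray  # residue at each rank position
    focal_residue_number: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)

    @property
    def n_residues(self) -> int:
        return len(self.values)

    def head_mean(self, k_window: int) -> float:
        if k_window < 1:
            raise ValueError("k_window must be >= 1")
        return float(self.values[:k_window].mean())


# ---------------------------------------------------------------------------
# profile / ordering / curve operations

def stability_profile(traj: Trajectory,
                      reference: StructureFrame) -> StabilityProfile:
    """Per-residue mean and (J-1)-denominator std of residue_dist over frames.

    The trajectory must already be aligned and hydrogen-free in the default
    pipeline; ``reference`` is normally ``average_structure(traj)``.  With a
    single frame the std is undefined and reported as None.
    """
    rd = _per_frame_residue_dist(traj, reference)
    top = traj.topology
    mean = rd.mean(axis=0)
    std = rd.std(axis=0, ddof=1) if traj.n_frames >= 2 else None
    return StabilityProfile(top.residue_numbers.copy(), top.residue_names,
                            top.residue_sizes.copy(), mean, std,
                            traj.n_frames)


def focal_ordering(traj: Trajectory,
                   focal_residue_number: int = DEFAULT_FOCAL_RESIDUE
                   ) -> FocalOrdering:
    """Mean distance of every residue center to the focal residue center.

    Residue centers are unweighted heavy-atom centroids computed per frame;
    the center-to-center distance is averaged over all frames.
    """
    top = traj.topology
    where = np.flatnonzero(top.residue_numbers == focal_residue_number)
    if len(where) == 0:
        avail = top.residue_numbers
        raise ResidueLookupError(
            f"focal residue {focal_residue_number} absent; available residues "
            f"{avail[0]}-{avail[-1]} ({len(avail)} present)"
        )
    f = int(where[0])
    sums = np.add.reduceat(traj.coordinates, top.residue_starts, axis=1)
    centers = sums / top.residue_sizes[None, :, None]       # (J, R, 3)
    delta = centers - centers[:, f:f + 1, :]
    dist = np.linalg.norm(delta, axis=2).mean(axis=0)       # (R,)
    return FocalOrdering(focal_residue_number, top.residue_numbers.copy(),
                         dist, traj.n_frames)


def trim_to_range(profile: StabilityProfile,
                  lo: int = DEFAULT_TRIM[0],
                  hi: int = DEFAULT_TRIM[1]) -> StabilityProfile:
    """Restrict a profile to residues with lo <= residue_number <= hi.

    The default 716-976 window drops the head and tail of the kinase domain,
    whose stability is dominated by terminal flopping rather than fold
    dynamics.  Trimming happens at the reporting stage only — fits and the
    average-structure reference always use the whole structure.
    """
    if lo > hi:
        raise ValueError(f"empty trim range {lo}..{hi}")
    keep = (profile.residue_numbers >= lo) & (profile.residue_numbers <= hi)
    if not keep.any():
        raise ResidueLookupError(
            f"no residues in range {lo}..{hi} "
            f"(profile spans {profile.residue_numbers[0]}-"
            f"{profile.residue_numbers[-1]})"
        )
    return StabilityProfile(
        profile.residue_numbers[keep],
        tuple(n for n, k in zip(profile.residue_names, keep) if k),
        profile.heavy_counts[keep],
        profile.mean[keep],
        None if profile.std is None else profile.std[keep],
        profile.n_frames,
    )


def cumulative_average(profile: StabilityProfile, ordering: FocalOrdering,
                       statistic: str = "mean") -> CumulativeCurve:
    """c_k = mean of the statistic over the k+1 residues closest to the focus.

    Profile and ordering must cover the same residue set (trim both first);
    rank 0 is the focal residue itself, so c_0 is its own stability value.
    """
    prof_set = set(profile.residue_numbers.tolist())
    ord_set = set(ordering.residue_numbers.tolist())
    if prof_set != ord_set:
        diff = sorted(prof_set ^ ord_set)
        raise ResiflexError(
            f"profile and ordering cover different residues; "
            f"symmetric difference {diff}"
        )
    s = profile.statistic(statistic)
    by_number = dict(zip(profile.residue_numbers.tolist(), s.tolist()))
    ranked = ordering.rank_order[np.isin(ordering.rank_order,
                                         profile.residue_numbers)]
    vals = np.asarray([by_number[int(r)] for r in ranked])
    cum = np.cumsum(vals) / np.arange(1, len(vals) + 1)
    return CumulativeCurve(statistic, cum, ranked,
                           ordering.focal_residue_number)


@dataclass
class MutantComparison:
    """Labels ordered least-stable first over an early curve window."""

    labels: List[str]            # descending head-window mean
    scores: Dict[str, float]     # head-window mean per label (Angstrom)
    k_window: int
    statistic: str
    ties: List[Tuple[str, ...]]  # groups of labels with equal scores

    @property
    def least_stable(self) -> str:
        return self.labels[0]


def compare_mutants(curves: Mapping[str, CumulativeCurve],
                    k_window: int = DEFAULT_K_WINDOW) -> MutantComparison:
    """Order variant complexes by mean cumulative stability near the focus.

    A higher mean of c_0..c_{k_window-1} means larger displacements around
    the focal residue, i.e. *lower* stability; that label sorts first.
    Exactly equal scores are reported as ties.
    """
    if not curves:
        raise ResiflexError("compare_mutants requires at least one curve")
    if k_window < 1:
        raise ValueError("k_window must be >= 1")
    stats = {c.statistic for c in curves.values()}
    if len(stats) > 1:
        raise ResiflexError(f"curves mix statistics {sorted(stats)}")
    n_min = min(c.n_residues for c in curves.values())
    if k_window > n_min:
        raise ResiflexError(
            f"k_window {k_window} exceeds shortest curve length {n_min}"
        )
    scores = {lab: c.head_mean(k_window) for lab, c in curves.items()}
    labels = sorted(scores, key=lambda lab: (-scores[lab], lab))
    groups: Dict[float, List[str]] = {}
    for lab in labels:
        groups.setdefault(scores[lab], []).append(lab)
    ties = [tuple(g) for g in groups.values() if len(g) > 1]
    return MutantComparison(labels, scores, k_window, stats.pop(), ties)


# ---------------------------------------------------------------------------
# convenience: the full default pipeline

def analyze_trajectory(traj: Trajectory,
                       original: Optional[StructureFrame] = None,
                       focal_residue_number: int = DEFAULT_FOCAL_RESIDUE,
                       trim: Optional[Tuple[int, int]] = DEFAULT_TRIM,
                       atom_mask: Optional[Iterable[int]] = None):
    """Run strip -> align -> average reference -> profile -> ordering -> curves.

    ``original`` is the structure every frame is best-fit to (default: the
    first frame).  Returns ``(profile, ordering, {"mean": curve, "std":
    curve})`` with profile and ordering trimmed to ``trim`` (pass None to
    keep all residues).
    """
    from .model import strip_hydrogens
    from .superpose import align_trajectory, average_structure

    traj = strip_hydrogens(traj)
    if original is None:
        original = traj.frame(0)
    elif original.topology != traj.topology:
        original = StructureFrame(
            traj.topology,
            original.coordinates[original.topology.heavy_atom_indices()],
        )
    aligned = align_trajectory(traj, original, atom_mask)
    reference = average_structure(aligned)
    profile = stability_profile(aligned, reference)
    ordering = focal_ordering(aligned, focal_residue_number)
    if trim is not None:
        profile = trim_to_range(profile, *trim)
        ordering = ordering.restrict(profile.residue_numbers)
    curves = {"mean": cumulative_average(profile, ordering, "mean")}
    if profile.std is not None:
        curves["std"] = cumulative_average(profile, ordering, "std")
    return profile, ordering, curves
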