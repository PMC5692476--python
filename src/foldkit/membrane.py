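"""Local vs bulk bilayer structure around a membrane protein.

Coarse-grained (MARTINI-style) bilayer snapshots are analyzed for two
observables that report how a membrane protein perturbs its annular
lipids:

* **Thickness** — the separation between the mean phosphate (PO4) z of
  the upper and lower leaflets, restricted to a lipid selection.
* **Acyl-chain order** — the second-Legendre bond order parameter
  S = 0.5 * (3 cos^2 theta - 1), with theta the angle between a chain
  bond and the bilayer normal (taken as z for these planar systems).
  Bonds are labeled G-1 (glycerol bead to first chain bead) and 1-2,
  2-3, 3-4 between consecutive chain beads, as chain length allows; the
  two acyl chains are pooled.

Lipids are selected either as *annular* (phosphate within a cutoff,
default 12 A, of any bead of a designated anchor residue — e.g. a residue
on the barrel's lateral-gate seam) or as *bulk* (phosphate farther than a
cutoff, default 30 A, from every protein bead).  Distances use the
minimum image in x/y only; the bilayer is periodic in the membrane plane
but not along the normal.

:func:`profile_trajectories` aggregates both observables over the
post-burn-in frames of replicate trajectories and reports mean +/- SD
across replicas, mirroring the standard multi-replica MD analysis layout
(e.g. five 3-us runs analyzed over their final 2.5 us).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDataError

__all__ = [
    "CGFrame",
    "Trajectory",
    "LipidSelection",
    "SelectionProfile",
    "MembraneProfile",
    "assign_leaflets",
    "select_lipids",
    "thickness",
    "order_parameters",
    "profile_trajectories",
    "BOND_LABELS",
]

log = logging.getLogger(__name__)

#: bond labels in chain order for the longest supported chain
BOND_LABELS = ("G-1", "1-2", "2-3", "3-4")


@dataclass(frozen=True)
class CGFrame:
    """One coarse-grained snapshot: lipids with role-labeled beads, protein, box.

    Positions are in Angstrom.  ``chain_a``/``chain_b`` have shape
    (n_lipids, chain_beads, 3) and both chains of every lipid have the
    same bead count (2, 3 or 4).  ``leaflet`` is +1 (upper) / -1 (lower)
    once :func:`assign_leaflets` has run, else None.
    """

    box: np.ndarray                      # (3,) orthorhombic box lengths, A
    lipid_resids: np.ndarray             # (n_lipids,)
    po4: np.ndarray                      # (n_lipids, 3)
    gl1: np.ndarray                      # (n_lipids, 3)
    gl2: np.ndarray                      # (n_lipids, 3)
    chain_a: np.ndarray                  # (n_lipids, chain_beads, 3)
    chain_b: np.ndarray                  # (n_lipids, chain_beads, 3)
    nc3: np.ndarray | None = None        # (n_lipids, 3) headgroup choline
    protein_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    protein_resids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    protein_resnames: np.ndarray | None = None
    leaflet: np.ndarray | None = None

    def __post_init__(self):
        if self.chain_a.shape != self.chain_b.shape:
            raise DegenerateDataError("both chains must have the same bead count")
        if not 2 <= self.chain_a.shape[1] <= 4:
            raise DegenerateDataError("chains must have 2-4 beads")
        if self.po4.shape[0] != self.lipid_resids.shape[0]:
            raise DegenerateDataError("one PO4 bead per lipid required")

    @property
    def n_lipids(self) -> int:
        return int(self.po4.shape[0])

    @property
    def chain_beads(self) -> int:
        return int(self.chain_a.shape[1])

    @property
    def bond_labels(self) -> tuple[str, ...]:
        return BOND_LABELS[: self.chain_beads]


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames of one replica with times in microseconds."""

    frames: tuple[CGFrame, ...]
    frame_times_us: np.ndarray
    replica_id: str = "0"

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        t = np.asarray(self.frame_times_us, dtype=float)
        object.__setattr__(self, "frame_times_us", t)
        if len(self.frames) < 1:
            raise DegenerateDataError("trajectory needs >= 1 frame")
        if t.shape != (len(self.frames),) or np.any(np.diff(t) < 0):
            raise DegenerateDataError("frame times must be nondecreasing, one per frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class LipidSelection:
    """Per-frame set of lipid indices selected by an annular or bulk rule."""

    mode: str                        # "near_residue" | "bulk"
    indices: np.ndarray              # lipid indices into the frame
    anchor_residue: int | None = None
    cutoff: float = 12.0


@dataclass(frozen=True)
class SelectionProfile:
    """Aggregated thickness and per-bond order for one selection."""

    thickness_mean: float
    thickness_sd: float
    order_mean: dict[str, float]
    order_sd: dict[str, float]
    n_replicas: int


@dataclass(frozen=True)
class MembraneProfile:
    """Thickness and order parameters for all selections, across replicas."""

    selections: dict[str, SelectionProfile]
    n_replicas: int
    burn_in_fraction: float

    def to_records(self) -> list[dict]:
        """Tidy rows: one per (selection, metric/bond)."""
        rows = []
        for name, prof in self.selections.items():
            rows.append({"selection": name, "metric": "thickness",
                         "mean": prof.thickness_mean, "sd": prof.thickness_sd})
            for bond in prof.order_mean:
                rows.append({"selection": name, "metric": f"order:{bond}",
                             "mean": prof.order_mean[bond],
                             "sd": prof.order_sd[bond]})
        return rows


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs distances, minimum image in x/y, non-periodic z."""
    d = a[:, None, :] - b[None, :, :]
    for ax in (0, 1):
        length = box[ax]
        d[..., ax] -= length * np.round(d[..., ax] / length)
    return np.sqrt(np.sum(d * d, axis=-1))


def assign_leaflets(frame: CGFrame) -> CGFrame:
    """Partition lipids into leaflets by PO4 z relative to the midplane.

    The midplane is the mean PO4 z over all lipids; lipids above it are
    labeled upper (+1), the rest lower (-1).
    """
    if frame.n_lipids < 2:
        raise DegenerateDataError("need >= 2 lipids to assign leaflets")
    z = frame.po4[:, 2]
    mid = float(np.mean(z))
    leaflet = np.where(z > mid, 1, -1).astype(int)
    if np.all(leaflet == leaflet[0]):
        raise DegenerateDataError("all lipids on one side of midplane: not a bilayer")
    return dataclasses.replace(frame, leaflet=leaflet)


def select_lipids(frame: CGFrame,
                  mode: str,
                  anchor_residue: int | None = None,
                  cutoff: float | None = None,
                  *,
                  use_whole_lipid: bool = False) -> LipidSelection:
    """Select annular or bulk lipids for one frame.

    ``near_residue`` keeps lipids whose phosphate bead lies within
    ``cutoff`` (inclusive, default 12 A) of any bead of
    ``anchor_residue``; with ``use_whole_lipid`` the minimum over all
    lipid beads is used instead of the phosphate only.  ``bulk`` keeps
    lipids whose phosphate is strictly farther than ``cutoff`` (default
    30 A) from every protein bead; without a protein all lipids are bulk.
    """
    if mode == "near_residue":
        if cutoff is None:
            cutoff = 12.0
        if anchor_residue is None:
            raise DegenerateDataError("near_residue selection needs an anchor residue")
        mask = frame.protein_resids == anchor_residue
        if not np.any(mask):
            raise DegenerateDataError(f"residue {anchor_residue} not in protein")
        anchor = frame.protein_xyz[mask]
        ref = _lipid_reference_points(frame, use_whole_lipid)
        d = _min_image_dist(ref, anchor, frame.box).min(axis=1)
        if use_whole_lipid:
            d = d.reshape(frame.n_lipids, -1).min(axis=1)
        indices = np.nonzero(d <= cutoff)[0]
    elif mode == "bulk":
        if cutoff is None:
            cutoff = 30.0
        if frame.protein_xyz.shape[0] == 0:
            indices = np.arange(frame.n_lipids)
        else:
            d = _min_image_dist(frame.po4, frame.protein_xyz, frame.box).min(axis=1)
            indices = np.nonzero(d > cutoff)[0]
    else:
        raise DegenerateDataError(f"unknown selection mode {mode!r}")
    if cutoff <= 0:
        raise DegenerateDataError("cutoff must be positive")
    return LipidSelection(mode=mode, indices=indices,
                          anchor_residue=anchor_residue, cutoff=cutoff)


def _lipid_reference_points(frame: CGFrame, use_whole_lipid: bool) -> np.ndarray:
    if not use_whole_lipid:
        return frame.po4
    stacked = np.concatenate(
        [frame.po4[:, None, :], frame.gl1[:, None, :], frame.gl2[:, None, :],
         frame.chain_a, frame.chain_b]
        + ([frame.nc3[:, None, :]] if frame.nc3 is not None else []),
        axis=1,
    )
    return stacked.reshape(-1, 3)


def thickness(frame: CGFrame, selection: LipidSelection,
              min_per_leaflet: int = 3) -> float | None:
    """Phosphate-based bilayer thickness over a lipid selection.

    Returns mean upper-leaflet PO4 z minus mean lower-leaflet PO4 z of
    the selected lipids, or None (logged) when either leaflet has fewer
    than ``min_per_leaflet`` members.
    """
    if frame.leaflet is None:
        frame = assign_leaflets(frame)
    sel = selection.indices
    leaf = frame.leaflet[sel]
    upper = frame.po4[sel[leaf > 0], 2]
    lower = frame.po4[sel[leaf < 0], 2]
    if upper.size < min_per_leaflet or lower.size < min_per_leaflet:
        log.debug("selection %s/%s underpopulated (%d upper / %d lower)",
                  selection.mode, selection.anchor_residue, upper.size, lower.size)
        return None
    return float(np.mean(upper) - np.mean(lower))


def order_parameters(frame: CGFrame,
                     selection: LipidSelection) -> dict[str, float]:
    """Per-bond S = 0.5*(3 cos^2 theta - 1) averaged over a selection.

    The bilayer normal is the z axis.  For every selected lipid the G-1
    bond (GL1->C1A and GL2->C1B) and the consecutive chain bonds are
    evaluated on both chains and pooled; zero-length bond vectors are
    skipped (logged).
    """
    sel = selection.indices
    out: dict[str, float] = {}
    bonds_a = [frame.chain_a[sel, 0] - frame.gl1[sel]]
    bonds_b = [frame.chain_b[sel, 0] - frame.gl2[sel]]
    for i in range(frame.chain_beads - 1):
        bonds_a.append(frame.chain_a[sel, i + 1] - frame.chain_a[sel, i])
        bonds_b.append(frame.chain_b[sel, i + 1] - frame.chain_b[sel, i])
    for label, va, vb in zip(frame.bond_labels, bonds_a, bonds_b):
        v = np.concatenate([va, vb], axis=0)
        norms = np.linalg.norm(v, axis=1)
        ok = norms > 0
        if not np.all(ok):
            log.debug("skipping %d zero-length %s bonds", int((~ok).sum()), label)
        if not np.any(ok):
            out[label] = float("nan")
            continue
        cos2 = (v[ok, 2] / norms[ok]) ** 2
        out[label] = float(np.mean(0.5 * (3.0 * cos2 - 1.0)))
    return out


# ---------------------------------------------------------------------------
# trajectory aggregation
# ---------------------------------------------------------------------------

def burn_in_slice(n_frames: int, burn_in_fraction: float) -> slice:
    """Frames retained for analysis: drop the leading burn-in fraction."""
    if not 0 <= burn_in_fraction < 1:
        raise DegenerateDataError("burn_in_fraction must be in [0, 1)")
    return slice(int(round(n_frames * burn_in_fraction)), n_frames)


def profile_trajectories(trajectories: Sequence[Trajectory],
                         anchors: Sequence[int],
                         burn_in_fraction: float = 1.0 / 6.0,
                         *,
                         cutoff: float = 12.0,
                         bulk_cutoff: float = 30.0,
                         min_per_leaflet: int = 3,
                         use_whole_lipid: bool = False) -> MembraneProfile:
    """Thickness and order profiles per selection, mean +/- SD over replicas.

    For each replica, observables are time-averaged over the post-burn-in
    frames for every anchor's annular selection plus the bulk selection;
    replica averages are then combined into mean and sample SD (a single
    replica reports SD = 0).  Selections are recomputed every frame.

    Raises
    ------
    DegenerateDataError
        If replicas have differing chain-bond sets (incompatible topology).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise DegenerateDataError("need >= 1 trajectory")
    labels = {traj.frames[0].bond_labels for traj in trajectories}
    if len(labels) != 1:
        raise DegenerateDataError("replicas have differing bond sets")
    bond_labels = labels.pop()

    selection_names = [f"near_{a}" for a in anchors] + ["bulk"]
    per_replica: dict[str, dict[str, list[float]]] = {
        name: {"thickness": [], **{b: [] for b in bond_labels}}
        for name in selection_names
    }

    for traj in trajectories:
        frames = traj.frames[burn_in_slice(traj.n_frames, burn_in_fraction)]
        acc: dict[str, dict[str, list[float]]] = {
            name: {"thickness": [], **{b: [] for b in bond_labels}}
            for name in selection_names
        }
        for frame in frames:
            frame = assign_leaflets(frame)
            sels = {f"near_{a}": select_lipids(frame, "near_residue", a, cutoff,
                                               use_whole_lipid=use_whole_lipid)
                    for a in anchors}
            sels["bulk"] = select_lipids(frame, "bulk", cutoff=bulk_cutoff)
            for name, sel in sels.items():
                th = thickness(frame, sel, min_per_leaflet)
                if th is not None:
                    acc[name]["thickness"].append(th)
                if sel.indices.size:
                    for bond, val in order_parameters(frame, sel).items():
                        if math.isfinite(val):
                            acc[name][bond].append(val)
        for name in selection_names:
            for key, vals in acc[name].items():
                if vals:
                    per_replica[name][key].append(float(np.mean(vals)))

    selections = {}
    n_rep = len(trajectories)
    for name in selection_names:
        th = per_replica[name]["thickness"]
        order_mean, order_sd = {}, {}
        for bond in bond_labels:
            vals = per_replica[name][bond]
            order_mean[bond] = float(np.mean(vals)) if vals else float("nan")
            order_sd[bond] = _sample_sd(vals)
        selections[name] = SelectionProfile(
            thickness_mean=float(np.mean(th)) if th else float("nan"),
            thickness_sd=_sample_sd(th),
            order_mean=order_mean,
            order_sd=order_sd,
            n_replicas=n_rep,
        )
    return MembraneProfile(selections=selections, n_replicas=n_rep,
                           burn_in_fraction=burn_in_fraction)


def _sample_sd(values: list[float]) -> float:
    if len(values) > 1:
        return float(np.std(values, ddof=1))
    return 0.0
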