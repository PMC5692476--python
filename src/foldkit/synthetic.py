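"""Seeded generators for every input the pipeline consumes.

Two families of synthetic data stand in for the wet-lab and MD inputs:

* **Folding transients** — single/double-exponential decays and
  lag-then-rise (logistic) traces with multiplicative Gaussian noise,
  emulating tryptophan-fluorescence folding assays.
* **Coarse-grained bilayer trajectories** — planar two-leaflet MARTINI-
  style bilayers (PO4 + two glycerol beads + two acyl chains of 2-4
  beads) around an embedded cylindrical barrel of protein beads, with an
  imposed radial thinning / chain-disorder profile centered on a
  designated seam residue.

The bilayer generator is built so its ground truth is *analytic*: the
local leaflet separation follows a plateau-plus-Gaussian-shoulder radial
profile, and acyl chains are grown bead-by-bead with a fixed polar
(cone) angle and uniform random azimuth, so every bond's order parameter
is exactly S = 0.5*(3 cos^2 theta_c - 1).  Per-lipid rigid-body jitter
is the only noise, which makes recovery tests sharp.  Frames are i.i.d.
perturbations, not time-correlated dynamics.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError
from .kinetics import FoldingTransient
from .membrane import CGFrame, Trajectory

__all__ = [
    "TransientSpec",
    "BilayerSpec",
    "BilayerGroundTruth",
    "generate_transients",
    "generate_bilayer_trajectory",
    "generate_bilayer_trajectories",
]

TRANSIENT_MODELS = ("single_exp", "double_exp", "lag_sigmoid")


@dataclass(frozen=True)
class TransientSpec:
    """Recipe for a set of replicate folding transients.

    Exponential models follow the fitting convention
    y = sum_i A_i exp(-k_i t) + c, so a rising trace has a negative
    amplitude.  ``lag_sigmoid`` produces a logistic lag-then-rise with
    ``rates[0]`` as steepness and ``midpoint_s`` as the inflection time.
    ``noise_fraction`` is multiplicative Gaussian noise
    (y -> y * (1 + noise_fraction * eps)).
    """

    model: str = "single_exp"
    rates: tuple[float, ...] = (0.0149,)
    amplitudes: tuple[float, ...] = (-5.0,)
    offset: float = 7.0
    noise_fraction: float = 0.0
    duration_s: float = 600.0
    sample_interval_s: float = 1.0
    n_replicates: int = 3
    seed: int = 0
    midpoint_s: float | None = None
    replicate_amplitude_scales: tuple[float, ...] | None = None
    condition_label: str = ""
    batch_id: str | None = None

    def __post_init__(self):
        if self.model not in TRANSIENT_MODELS:
            raise DegenerateDataError(f"unknown transient model {self.model!r}")
        if any(k <= 0 for k in self.rates):
            raise DegenerateDataError("rates must be positive")
        n_exp = {"single_exp": 1, "double_exp": 2, "lag_sigmoid": 1}[self.model]
        if len(self.rates) != n_exp or len(self.amplitudes) != n_exp:
            raise DegenerateDataError(
                f"{self.model} needs {n_exp} rate(s) and amplitude(s)")
        if self.noise_fraction < 0:
            raise DegenerateDataError("noise_fraction must be >= 0")
        if self.duration_s / self.sample_interval_s < 9:
            raise DegenerateDataError("need >= 10 samples")
        if self.n_replicates < 1:
            raise DegenerateDataError("need >= 1 replicate")
        if (self.replicate_amplitude_scales is not None
                and len(self.replicate_amplitude_scales) != self.n_replicates):
            raise DegenerateDataError("one amplitude scale per replicate required")


def generate_transients(spec: TransientSpec) -> list[FoldingTransient]:
    """Deterministic (seeded) replicate transients from a spec."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_s + 0.5 * spec.sample_interval_s,
                  spec.sample_interval_s)
    out = []
    for i in range(spec.n_replicates):
        scale = (spec.replicate_amplitude_scales[i]
                 if spec.replicate_amplitude_scales is not None else 1.0)
        if spec.model == "lag_sigmoid":
            mid = spec.midpoint_s if spec.midpoint_s is not None else spec.duration_s / 2
            y = spec.offset + scale * spec.amplitudes[0] / (
                1.0 + np.exp(-spec.rates[0] * (t - mid)))
        else:
            y = np.full_like(t, spec.offset)
            for a, k in zip(spec.amplitudes, spec.rates):
                y = y + scale * a * np.exp(-k * t)
        if spec.noise_fraction > 0:
            y = y * (1.0 + spec.noise_fraction * rng.standard_normal(t.shape))
        out.append(FoldingTransient(
            time=t, signal=y,
            condition_label=spec.condition_label or spec.model,
            replicate_id=f"rep{i + 1}",
            batch_id=spec.batch_id,
        ))
    return out


# ---------------------------------------------------------------------------
# coarse-grained bilayer generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BilayerSpec:
    """Recipe for a synthetic protein-in-bilayer CG system.

    The bilayer is two jittered square lattices of lipids; the protein is
    a cylinder of bead columns (one residue per angular column, beads
    stacked through the membrane so annular selection behaves radially).
    The seam anchor column sits at azimuth 0, the opposite anchor
    diametrically across.  Local leaflet separation is

        T(r) = bulk_thickness - thinning_depth * g(r)

    with r the in-plane distance to the seam column and g(r) = 1 inside
    ``thinning_plateau_radius``, decaying as a Gaussian of width
    ``thinning_width`` beyond it; the chain cone angle interpolates from
    ``cone_angle_bulk_deg`` to ``cone_angle_seam_deg`` with the same g(r).
    Lengths in Angstrom, times in microseconds.
    """

    chain_beads: int = 4
    n_lipids_side: int = 16           # lattice sites per box edge, per leaflet
    lattice_spacing: float = 7.0
    bulk_thickness: float = 38.0
    thinning_depth: float = 0.0
    thinning_plateau_radius: float = 13.0
    thinning_width: float = 4.0
    cone_angle_bulk_deg: float = 30.0
    cone_angle_seam_deg: float | None = None
    positional_jitter: float = 0.8
    bond_length: float = 4.7
    n_frames: int = 30
    n_replicas: int = 5
    total_time_us: float = 3.0
    seed: int = 0
    protein_radius: float = 20.0
    protein_columns: int = 24
    seam_residue: int = 808
    opposite_residue: int = 613

    def __post_init__(self):
        if self.chain_beads not in (2, 3, 4):
            raise DegenerateDataError("chain_beads must be 2, 3 or 4")
        if self.thinning_depth >= self.bulk_thickness:
            raise DegenerateDataError("thinning depth must be < bulk thickness")
        for angle in (self.cone_angle_bulk_deg, self.cone_angle_seam_deg or 0.0):
            if not 0.0 <= angle <= 90.0:
                raise DegenerateDataError("cone angles must be in [0, 90] degrees")
        if self.protein_radius >= self.box_xy / 2:
            raise DegenerateDataError("protein radius must be < half the box")
        if self.n_frames < 1 or self.n_replicas < 1:
            raise DegenerateDataError("need >= 1 frame and >= 1 replica")

    @property
    def box_xy(self) -> float:
        return self.n_lipids_side * self.lattice_spacing

    @property
    def seam_angle_deg(self) -> float:
        return 0.0

    @property
    def cone_angle_seam(self) -> float:
        return (self.cone_angle_seam_deg
                if self.cone_angle_seam_deg is not None
                else self.cone_angle_bulk_deg)


@dataclass(frozen=True)
class BilayerGroundTruth:
    """Analytic fields imposed by the generator, for recovery tests."""

    spec: BilayerSpec
    seam_xy: tuple[float, float]

    def _g(self, r):
        r = np.asarray(r, dtype=float)
        r0, sigma = self.spec.thinning_plateau_radius, self.spec.thinning_width
        excess = np.clip(r - r0, 0.0, None)
        return np.exp(-excess ** 2 / (2.0 * sigma ** 2))

    def thickness_at(self, r) -> np.ndarray:
        """Imposed leaflet separation (A) at in-plane distance r from the seam."""
        return self.spec.bulk_thickness - self.spec.thinning_depth * self._g(r)

    def cone_angle_at_deg(self, r) -> np.ndarray:
        base = self.spec.cone_angle_bulk_deg
        return base + (self.spec.cone_angle_seam - base) * self._g(r)

    def order_at(self, r) -> np.ndarray:
        """Exact per-bond order parameter at distance r (same for all bonds)."""
        theta = np.radians(self.cone_angle_at_deg(r))
        return 0.5 * (3.0 * np.cos(theta) ** 2 - 1.0)

    @property
    def seam_thickness(self) -> float:
        return float(self.thickness_at(0.0))

    @property
    def bulk_thickness(self) -> float:
        return self.spec.bulk_thickness

    @property
    def seam_order(self) -> float:
        return float(self.order_at(0.0))

    @property
    def bulk_order(self) -> float:
        return float(self.order_at(np.inf))


def _protein_geometry(spec: BilayerSpec):
    """Bead positions/resids for the cylindrical barrel stand-in.

    One residue per angular column; the seam column (azimuth 0) and the
    opposite column carry the author-numbered anchor resids, all other
    columns are numbered sequentially.
    """
    cx = cy = spec.box_xy / 2.0
    half_h = spec.bulk_thickness / 2.0 + 2.0
    n_rings = max(5, int(math.ceil(2 * half_h / 7.0)) + 1)
    z_levels = np.linspace(-half_h, half_h, n_rings)
    angles = 2.0 * np.pi * np.arange(spec.protein_columns) / spec.protein_columns

    resids = np.arange(1, spec.protein_columns + 1)
    if spec.seam_residue in resids or spec.opposite_residue in resids:
        resids = resids + spec.protein_columns
    resids = resids.copy()
    resids[0] = spec.seam_residue
    resids[spec.protein_columns // 2] = spec.opposite_residue

    xyz, ids = [], []
    for angle, resid in zip(angles, resids):
        x = cx + spec.protein_radius * np.cos(angle)
        y = cy + spec.protein_radius * np.sin(angle)
        for z in z_levels:
            xyz.append((x, y, z))
            ids.append(resid)
    seam_xy = (cx + spec.protein_radius, cy)
    return np.asarray(xyz), np.asarray(ids, dtype=int), seam_xy


def _lattice_sites(spec: BilayerSpec) -> np.ndarray:
    edge = np.arange(spec.n_lipids_side) * spec.lattice_spacing + spec.lattice_spacing / 2
    xx, yy = np.meshgrid(edge, edge, indexing="ij")
    sites = np.column_stack([xx.ravel(), yy.ravel()])
    center = spec.box_xy / 2.0
    r_center = np.hypot(sites[:, 0] - center, sites[:, 1] - center)
    return sites[r_center > spec.protein_radius + 2.0]


def _min_image_r(xy: np.ndarray, ref: tuple[float, float], box: float) -> np.ndarray:
    d = xy - np.asarray(ref)
    d -= box * np.round(d / box)
    return np.hypot(d[:, 0], d[:, 1])


def _build_frame(spec: BilayerSpec, truth: BilayerGroundTruth,
                 protein_xyz: np.ndarray, protein_resids: np.ndarray,
                 sites: np.ndarray, rng: np.random.Generator) -> CGFrame:
    n_per_leaflet = sites.shape[0]
    n_lip = 2 * n_per_leaflet
    box = np.array([spec.box_xy, spec.box_xy,
                    spec.bulk_thickness + 6 * spec.chain_beads * spec.bond_length])
    cz = box[2] / 2.0

    r = _min_image_r(sites, truth.seam_xy, spec.box_xy)
    half_t = 0.5 * truth.thickness_at(r)
    theta = np.radians(truth.cone_angle_at_deg(r))

    po4 = np.empty((n_lip, 3))
    gl1 = np.empty((n_lip, 3))
    gl2 = np.empty((n_lip, 3))
    nc3 = np.empty((n_lip, 3))
    chain_a = np.empty((n_lip, spec.chain_beads, 3))
    chain_b = np.empty((n_lip, spec.chain_beads, 3))

    for leaf_idx, sign in ((0, 1.0), (1, -1.0)):
        sl = slice(leaf_idx * n_per_leaflet, (leaf_idx + 1) * n_per_leaflet)
        jitter = spec.positional_jitter * rng.standard_normal((n_per_leaflet, 3))
        base = np.column_stack([sites[:, 0], sites[:, 1],
                                cz + sign * half_t]) + jitter
        po4[sl] = base
        nc3[sl] = base + [0.0, 0.0, sign * 3.0]
        gl1[sl] = base + [0.0, 0.0, -sign * 3.0]
        gl2[sl] = gl1[sl] + [2.0, 0.0, 0.0]
        # chains grown bead-by-bead at fixed polar angle, random azimuth,
        # pointing toward the midplane -> every bond has exact cone angle
        for start, chain in ((gl1[sl], chain_a), (gl2[sl], chain_b)):
            prev = start
            for b in range(spec.chain_beads):
                phi = rng.uniform(0.0, 2.0 * np.pi, n_per_leaflet)
                step = spec.bond_length * np.column_stack([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    -sign * np.cos(theta),
                ])
                prev = prev + step
                chain[sl, b] = prev

    lipid_resids = np.arange(1, n_lip + 1)
    prot = protein_xyz.copy()
    prot[:, 2] += cz
    return CGFrame(box=box, lipid_resids=lipid_resids, po4=po4, gl1=gl1, gl2=gl2,
                   chain_a=chain_a, chain_b=chain_b, nc3=nc3,
                   protein_xyz=prot, protein_resids=protein_resids)


def generate_bilayer_trajectory(spec: BilayerSpec,
                                replica_index: int = 0
                                ) -> tuple[Trajectory, BilayerGroundTruth]:
    """One replica trajectory of i.i.d. jittered frames, plus ground truth."""
    protein_xyz, protein_resids, seam_xy = _protein_geometry(spec)
    truth = BilayerGroundTruth(spec=spec, seam_xy=seam_xy)
    sites = _lattice_sites(spec)
    rng = np.random.default_rng([spec.seed, replica_index])
    frames = [_build_frame(spec, truth, protein_xyz, protein_resids, sites, rng)
              for _ in range(spec.n_frames)]
    times = np.arange(1, spec.n_frames + 1) * spec.total_time_us / spec.n_frames
    traj = Trajectory(frames=tuple(frames), frame_times_us=times,
                      replica_id=f"rep{replica_index + 1}")
    return traj, truth


def generate_bilayer_trajectories(spec: BilayerSpec
                                  ) -> tuple[list[Trajectory], BilayerGroundTruth]:
    """All replicas of a spec (seeded independently from the base seed)."""
    trajs = []
    truth = None
    for i in range(spec.n_replicas):
        traj, truth = generate_bilayer_trajectory(spec, replica_index=i)
        trajs.append(traj)
    return trajs, truth
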