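"""Domain-center spatial sampling, the binding-induced switch score, and
membrane-contact analysis.

The receptor behaves like a coupled pendulum hinged at the membrane: in the
apo state the extracellular antigen-binding head sweeps a wide arch while
the intracellular tail stays confined; antigen binding tethers the head and
the sampling width migrates to the intracellular side. The *switch score*
quantifies that exchange from the covariance traces of the per-frame
domain-center clouds:

    S = ln(tr Σ_AB^apo / tr Σ_AB^holo) + ln(tr Σ_SI^holo / tr Σ_SI^apo)

S > 0 means the signature is present (extracellular sampling shrinks and/or
intracellular sampling grows, net). Clouds live in the TM-aligned frame:
z is the membrane normal, x-y the membrane plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import NumericalError, SelectionError
from .geometry import MetricSeries, align_trajectory
from .model import AtomSelection, Trajectory

__all__ = [
    "PointCloud", "SamplingSummary", "ContactSeries", "SwitchReport",
    "center_cloud", "sampling_summary", "bidds_switch_score",
    "contact_count_series", "burial_depth_series",
]


@dataclass(frozen=True)
class PointCloud:
    """One 3-D point per frame (a domain center), in the TM-aligned frame."""

    points: np.ndarray  # (n_frames, 3), Å
    label: str = ""

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SamplingSummary:
    """Spread statistics of a domain-center point cloud."""

    centroid: np.ndarray  # (3,)
    covariance_trace: float  # Å²
    principal_extents: np.ndarray  # (3,) sorted descending, Å
    planar_spread: float  # sqrt(var x + var y), Å
    normal_spread: float  # sd of z, Å
    hull_volume: float  # Å³; 0 if fewer than 4 non-coplanar points


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame atom-pair contact counts between a residue group and the membrane."""

    group: str
    per_frame_counts: np.ndarray  # non-negative ints
    cutoff: float  # Å

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_frame_counts))


@dataclass(frozen=True)
class SwitchReport:
    """Sampling summaries of the four state/domain clouds plus the switch score."""

    ab_apo: SamplingSummary
    ab_holo: SamplingSummary
    si_apo: SamplingSummary
    si_holo: SamplingSummary
    switch_score: float


def center_cloud(traj: Trajectory, domain_sel: AtomSelection,
                 fit_sel: AtomSelection, equilibration_cut: int = 0) -> PointCloud:
    """Frame-by-frame domain Cα centroid after superposing each frame on ``fit_sel``."""
    aligned = align_trajectory(traj, fit_sel)
    ca = [i for i in domain_sel.indices if traj.topology[i].name == "CA"]
    if not ca:
        raise SelectionError(f"no Cα atoms in selection '{domain_sel.label}'")
    pts = aligned[:, ca].mean(axis=1)
    return PointCloud(points=pts[equilibration_cut:], label=domain_sel.label)


def sampling_summary(cloud: PointCloud) -> SamplingSummary:
    """Eigen-summary of the 3×3 covariance of a point cloud.

    Population covariance (1/n) is used so the trace of an n-point cloud of
    i.i.d. isotropic Gaussians with per-axis variance σ² converges to 3σ².
    """
    pts = np.asarray(cloud.points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise NumericalError("sampling summary requires at least 2 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / pts.shape[0]
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    try:
        hull_volume = float(ConvexHull(pts).volume)
    except QhullError:
        hull_volume = 0.0
    return SamplingSummary(
        centroid=centroid,
        covariance_trace=float(np.trace(cov)),
        principal_extents=np.sqrt(eigvals),
        planar_spread=float(np.sqrt(cov[0, 0] + cov[1, 1])),
        normal_spread=float(np.sqrt(cov[2, 2])),
        hull_volume=hull_volume,
    )


def bidds_switch_score(ab_apo: SamplingSummary, ab_holo: SamplingSummary,
                       si_apo: SamplingSummary, si_holo: SamplingSummary) -> float:
    """Log-ratio switch statistic over the AB and SI covariance traces.

    Positive when antigen binding narrows extracellular AB sampling and/or
    widens intracellular SI sampling, net; exactly antisymmetric under
    swapping the apo and holo labels.
    """
    traces = [ab_apo.covariance_trace, ab_holo.covariance_trace,
              si_apo.covariance_trace, si_holo.covariance_trace]
    if any(t <= 0 for t in traces):
        raise NumericalError("switch score undefined for a zero covariance trace")
    return (math.log(ab_apo.covariance_trace / ab_holo.covariance_trace)
            + math.log(si_holo.covariance_trace / si_apo.covariance_trace))


def contact_count_series(traj: Trajectory, group_sel: AtomSelection,
                         membrane_sel: AtomSelection, cutoff: float = 2.5,
                         group_name: str | None = None) -> ContactSeries:
    """Per-frame count of heavy-atom pairs within ``cutoff`` between a group
    and the membrane.

    Contacts are atom *pairs*, not residues; hydrogens must already be
    excluded from both selections (``select_atoms`` does so by default).
    """
    if len(group_sel) == 0 or len(membrane_sel) == 0:
        raise SelectionError("contact counting requires non-empty selections")
    if cutoff <= 0:
        raise NumericalError("contact cutoff must be positive")
    gi = group_sel.array
    mi = membrane_sel.array
    counts = np.empty(traj.n_frames, dtype=int)
    for k in range(traj.n_frames):
        tree = cKDTree(traj.coords[k, mi])
        counts[k] = sum(len(hits) for hits in
                        tree.query_ball_point(traj.coords[k, gi], r=cutoff))
    return ContactSeries(group=group_name or group_sel.label,
                         per_frame_counts=counts, cutoff=cutoff)


def burial_depth_series(traj: Trajectory, atom_sel: AtomSelection,
                        slab_halfwidth: float,
                        fit_sel: AtomSelection | None = None) -> MetricSeries:
    """Per-frame maximal membrane-insertion depth of a selection.

    The membrane slab occupies |z| ≤ halfwidth in the TM-aligned frame (pass
    ``fit_sel`` to align on the fly if the trajectory is not already in that
    frame). Depth = halfwidth − |z|: positive inside the slab; a series with
    positive mean flags burial.
    """
    if len(atom_sel) == 0:
        raise SelectionError("burial depth requires a non-empty selection")
    coords = (align_trajectory(traj, fit_sel) if fit_sel is not None
              else traj.coords)
    z = coords[:, atom_sel.array, 2]
    depth = slab_halfwidth - np.abs(z)
    vals = depth.max(axis=1)
    return MetricSeries(name=f"burial[{atom_sel.label}]", per_frame_values=vals,
                        units="Å", fit_selection=fit_sel.label if fit_sel else "",
                        measure_selection=atom_sel.label)
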