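"""Superposition and per-frame geometry metrics.

The central protocol: superpose each frame onto a reference over a *fit*
selection (the transmembrane domain by default, so the membrane frame is the
laboratory frame), then measure RMSD, fluctuations, radii of gyration or
inter-domain distances over a *measure* selection. Fitting a domain to
itself ("fit-to-self") isolates intra-domain deformation; fitting to TM
keeps inter-domain rigid-body motion in the measurement, and the difference
of the two apo-vs-holo contrasts attributes conformational change to
inter-domain rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NumericalError, SelectionError
from .model import AtomSelection, Frame, Trajectory

__all__ = [
    "RigidTransform", "MetricSeries", "ResidueProfile", "DecompositionResult",
    "StateComparison", "kabsch_superpose", "rmsd", "rmsd_series", "rmsf_profile",
    "radius_of_gyration", "domain_center", "center_distance_series",
    "end_to_end_series", "decompose_interdomain", "decompose_domains",
    "compare_states", "align_trajectory",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: x ↦ R·x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,) Å

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise NumericalError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise NumericalError("rotation matrix is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MetricSeries:
    """A per-frame scalar measurement with provenance labels."""

    name: str
    per_frame_values: np.ndarray
    units: str = "Å"
    fit_selection: str = ""
    measure_selection: str = ""

    @property
    def values(self) -> np.ndarray:
        return self.per_frame_values

    def __len__(self) -> int:
        return len(self.per_frame_values)


@dataclass(frozen=True)
class ResidueProfile:
    """A per-residue measurement (e.g. RMSF), indexed by residue id."""

    residue_ids: np.ndarray
    values: np.ndarray
    units: str = "Å"


@dataclass(frozen=True)
class DecompositionResult:
    """Apo-vs-holo RMSD difference split into intra- and inter-domain parts."""

    domain: str
    overall_diff: float  # fit-to-TM contrast, Å
    intra_diff: float  # fit-to-self contrast, Å

    @property
    def inter_diff(self) -> float:
        return self.overall_diff - self.intra_diff


@dataclass(frozen=True)
class StateComparison:
    """Mean ± sd of a metric in each state, over the post-equilibration window."""

    metric: str
    apo_mean: float
    apo_sd: float
    holo_mean: float
    holo_sd: float

    @property
    def signed_diff(self) -> float:
        return self.holo_mean - self.apo_mean

    @property
    def abs_diff(self) -> float:
        return abs(self.signed_diff)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray,
                     reference: np.ndarray) -> tuple[RigidTransform, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rotation + translation and the transformed
    mobile coordinates. Reflections are never returned; rank-deficient
    (collinear or <3 point) inputs raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SelectionError(
            f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[0] < 3 or mobile.shape[1] != 3:
        raise NumericalError("superposition requires at least 3 points in 3-D")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    a = mobile - mob_c
    b = reference - ref_c
    if np.linalg.matrix_rank(a, tol=1e-9) < 2 or np.linalg.matrix_rank(b, tol=1e-9) < 2:
        raise NumericalError("degenerate geometry: points are collinear or coincident")
    # align_vectors solves the orthogonal Procrustes problem with the proper-
    # rotation (no reflection) branch enforced
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    transform = RigidTransform(rotation=R, translation=t)
    return transform, transform.apply(mobile)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between two coordinate sets (no fitting)."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.shape != coords_b.shape:
        raise SelectionError(
            f"coordinate sets differ in shape: {coords_a.shape} vs {coords_b.shape}")
    return float(np.sqrt(np.mean(np.sum((coords_a - coords_b) ** 2, axis=-1))))


def superposed_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition."""
    _, aligned = kabsch_superpose(mobile, reference)
    return rmsd(aligned, reference)


def align_trajectory(traj: Trajectory, fit_sel: AtomSelection,
                     reference: Frame | None = None) -> np.ndarray:
    """Superpose every frame onto the reference over ``fit_sel``.

    Returns a new ``(n_frames, n_atoms, 3)`` array; the reference defaults to
    frame 0 of the same trajectory.
    """
    ref = reference if reference is not None else traj.frame(0)
    ref_fit = ref.coords[fit_sel.array]
    out = np.empty_like(traj.coords)
    for k in range(traj.n_frames):
        tf, _ = kabsch_superpose(traj.coords[k][fit_sel.array], ref_fit)
        out[k] = tf.apply(traj.coords[k])
    return out


# ---------------------------------------------------------------------------
# Per-frame series
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference: Frame | None,
                fit_sel: AtomSelection, measure_sel: AtomSelection,
                name: str | None = None) -> MetricSeries:
    """Per-frame RMSD over ``measure_sel`` after superposing on ``fit_sel``.

    Passing the same selection for both yields the fit-to-self series that
    isolates intra-domain deformation.
    """
    ref = reference if reference is not None else traj.frame(0)
    aligned = align_trajectory(traj, fit_sel, ref)
    ref_meas = ref.coords[measure_sel.array]
    diffs = aligned[:, measure_sel.array] - ref_meas
    vals = np.sqrt(np.mean(np.sum(diffs ** 2, axis=-1), axis=-1))
    return MetricSeries(
        name=name or f"rmsd[{measure_sel.label}]",
        per_frame_values=vals, units="Å",
        fit_selection=fit_sel.label, measure_selection=measure_sel.label,
    )


def rmsf_profile(traj: Trajectory, fit_sel: AtomSelection,
                 measure_sel: AtomSelection) -> ResidueProfile:
    """Per-residue RMS fluctuation about the time-mean position.

    Frames are first superposed on ``fit_sel``; ``measure_sel`` should be a
    Cα selection so one value per residue results.
    """
    if traj.n_frames < 2:
        raise NumericalError("RMSF undefined for a single-frame trajectory")
    aligned = align_trajectory(traj, fit_sel)[:, measure_sel.array]
    mean_pos = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=-1), axis=0))
    resids = np.array([traj.topology[i].residue_id for i in measure_sel.indices])
    return ResidueProfile(residue_ids=resids, values=fluct)


def radius_of_gyration(frame: Frame, sel: AtomSelection,
                       mass_weighted: bool = False) -> float:
    """Radius of gyration of a selection (unweighted by default)."""
    coords = frame.coords[sel.array]
    if coords.shape[0] == 0:
        raise SelectionError("empty selection for radius of gyration")
    if mass_weighted:
        masses = np.array([_MASS.get(frame.topology[i].element.upper(), 12.0)
                           for i in sel.indices])
        center = np.average(coords, axis=0, weights=masses)
        return float(np.sqrt(np.average(np.sum((coords - center) ** 2, axis=1),
                                        weights=masses)))
    center = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))


_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


def rgyr_series(traj: Trajectory, sel: AtomSelection,
                name: str | None = None) -> MetricSeries:
    """Per-frame radius of gyration (fitting is irrelevant: Rgyr is rigid-motion invariant)."""
    centered = traj.coords[:, sel.array] - traj.coords[:, sel.array].mean(axis=1, keepdims=True)
    vals = np.sqrt(np.mean(np.sum(centered ** 2, axis=-1), axis=-1))
    return MetricSeries(name=name or f"rgyr[{sel.label}]", per_frame_values=vals,
                        units="Å", measure_selection=sel.label)


def domain_center(frame: Frame, sel: AtomSelection) -> np.ndarray:
    """Unweighted centroid of a domain's Cα atoms."""
    ca = [i for i in sel.indices if frame.topology[i].name == "CA"]
    if not ca:
        raise SelectionError(f"no Cα atoms in selection '{sel.label}'")
    return frame.coords[ca].mean(axis=0)


def center_distance_series(traj: Trajectory, sel_a: AtomSelection,
                           sel_b: AtomSelection, fit_sel: AtomSelection,
                           name: str | None = None) -> MetricSeries:
    """Per-frame distance between two domain centroids after fitting on ``fit_sel``."""
    aligned = align_trajectory(traj, fit_sel)
    ca_a = [i for i in sel_a.indices if traj.topology[i].name == "CA"]
    ca_b = [i for i in sel_b.indices if traj.topology[i].name == "CA"]
    if not ca_a or not ca_b:
        raise SelectionError("domain-center distance requires Cα atoms in both selections")
    centers_a = aligned[:, ca_a].mean(axis=1)
    centers_b = aligned[:, ca_b].mean(axis=1)
    vals = np.linalg.norm(centers_a - centers_b, axis=1)
    return MetricSeries(
        name=name or f"dist[{sel_a.label}-{sel_b.label}]",
        per_frame_values=vals, units="Å",
        fit_selection=fit_sel.label,
        measure_selection=f"{sel_a.label}|{sel_b.label}",
    )


def end_to_end_series(traj: Trajectory, fit_sel: AtomSelection | None = None,
                      chain_id: str | None = None) -> MetricSeries:
    """Per-frame distance between the first and last residue Cα of a chain.

    End-to-end distance is invariant under the per-frame rigid fit, so
    ``fit_sel`` only affects provenance labelling.
    """
    ca = [(traj.topology[i].residue_id, i) for i in range(traj.n_atoms)
          if traj.topology[i].name == "CA" and not traj.topology[i].is_hetero
          and (chain_id is None or traj.topology[i].chain_id == chain_id)]
    if len(ca) < 2:
        raise SelectionError("end-to-end distance requires at least two Cα atoms")
    first = min(ca)[1]
    last = max(ca)[1]
    vals = np.linalg.norm(traj.coords[:, first] - traj.coords[:, last], axis=1)
    return MetricSeries(name="end_to_end", per_frame_values=vals, units="Å",
                        fit_selection=fit_sel.label if fit_sel else "",
                        measure_selection="termini")


# ---------------------------------------------------------------------------
# Apo/holo comparison arithmetic
# ---------------------------------------------------------------------------

def decompose_interdomain(overall_diff: float, intra_diff: float) -> float:
    """Inter-domain contribution = overall contrast − intra-domain contrast.

    Both inputs are apo-vs-holo differences of time-averaged Cα-RMSD: the
    overall contrast from fit-to-TM series, the intra contrast from
    fit-to-self series. The result may be negative when intra-domain
    deformation exceeds the overall change.
    """
    if not (np.isfinite(overall_diff) and np.isfinite(intra_diff)):
        raise NumericalError("decomposition inputs must be finite")
    return float(overall_diff) - float(intra_diff)


def decompose_domains(overall_diffs: dict[str, float],
                      intra_diffs: dict[str, float]) -> list[DecompositionResult]:
    """Batch decomposition: one result per domain present in both inputs."""
    out = []
    for dom in overall_diffs:
        if dom in intra_diffs:
            out.append(DecompositionResult(domain=dom,
                                           overall_diff=float(overall_diffs[dom]),
                                           intra_diff=float(intra_diffs[dom])))
    return out


def compare_states(apo: MetricSeries, holo: MetricSeries,
                   equilibration_cut: int = 0,
                   holo_equilibration_cut: int | None = None) -> StateComparison:
    """Mean ± sd of a metric per state over frames ≥ the equilibration cut."""
    cut_a = equilibration_cut
    cut_h = equilibration_cut if holo_equilibration_cut is None else holo_equilibration_cut
    if cut_a >= len(apo) or cut_h >= len(holo):
        raise NumericalError(
            f"equilibration cut leaves no frames (cuts {cut_a}/{cut_h}, "
            f"lengths {len(apo)}/{len(holo)})")
    a = apo.per_frame_values[cut_a:]
    h = holo.per_frame_values[cut_h:]
    return StateComparison(
        metric=apo.name,
        apo_mean=float(np.mean(a)), apo_sd=float(np.std(a)),
        holo_mean=float(np.mean(h)), holo_sd=float(np.std(h)),
    )
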