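"""Per-frame geometric primitives.

Centers of mass of named selections, dye-COM-to-nanoparticle-surface
distances, best-fit core planes and their parallelism with the local surface,
dipole moments of (possibly net-charged) selections and the angle θ between
two dipole vectors.

Conventions: lengths Å, angles degrees, charges e, dipoles e·Å
(1 e·Å = 4.8032 D). The nanoparticle is treated as a sphere: the surface
distance is ``|COM_dye − COM_np| − radius`` and may be negative for a COM
inside the nominal sphere.

For a selection with nonzero net charge q the dipole depends on the chosen
reference point: shifting the reference by t changes the vector by −q·t.  The
default reference is the selection's own center of mass, which makes dipoles
of different particles comparable and excludes any diffusing counterion layer
from the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import EA_TO_DEBYE
from .trajio import Topology, Trajectory, infer_roles

__all__ = [
    "DipoleVector",
    "NanoparticleModel",
    "center_of_mass",
    "center_of_mass_series",
    "surface_distance",
    "core_plane_normal",
    "plane_normal_series",
    "parallelism_angle",
    "dipole_moment",
    "dipole_series",
    "dipole_angle_theta",
    "trajectory_metrics",
    "pair_metrics",
]


@dataclass
class DipoleVector:
    """A dipole moment Σ qᵢ(rᵢ − reference) of a selection."""

    components: np.ndarray  # e·Å
    reference_point: np.ndarray  # Å
    net_charge: float  # e

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.reference_point = np.asarray(self.reference_point, dtype=float)

    @property
    def magnitude_debye(self) -> float:
        return float(EA_TO_DEBYE * np.linalg.norm(self.components))


@dataclass
class NanoparticleModel:
    """A spherical nanoparticle: group label, per-frame center and radius."""

    label: str
    centers: np.ndarray  # (3,) or (F, 3)
    radius: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.radius <= 0:
            raise ValueError("nanoparticle radius must be > 0")

    @classmethod
    def from_trajectory(
        cls,
        trajectory: Trajectory,
        group: str,
        diameter: float | None = None,
        mode: str = "nominal",
    ) -> "NanoparticleModel":
        """Build the model from a trajectory.

        ``mode='nominal'`` uses ``diameter/2`` as the radius; ``'empirical'``
        uses the 95th percentile of member radial distances in the first frame,
        which tracks the fact that the heavy-atom diameter of a small crystal
        particle can differ slightly from its nominal value.
        """
        idx = trajectory.topology.group_indices(group)
        centers = center_of_mass_series(trajectory.topology, trajectory.coords, group)
        if mode == "nominal":
            if diameter is None:
                raise ValueError("nominal mode needs a diameter")
            radius = diameter / 2.0
        elif mode == "empirical":
            r0 = trajectory.coords[0, idx] - centers[0]
            radius = float(np.percentile(np.linalg.norm(r0, axis=1), 95))
        else:
            raise ValueError(f"unknown radius mode {mode!r}")
        return cls(label=group, centers=centers, radius=radius)

    def center_at(self, frame: int) -> np.ndarray:
        return self.centers if self.centers.ndim == 1 else self.centers[frame]


def center_of_mass(topology: Topology, frame: np.ndarray, group: str) -> np.ndarray:
    """Mass-weighted mean position of *group* in one frame of coordinates."""
    idx = topology.group_indices(group)
    if idx.size == 0:
        raise ValueError(f"group {group!r} is empty")
    m = topology.masses[idx]
    return (m[:, None] * np.asarray(frame, dtype=float)[idx]).sum(axis=0) / m.sum()


def center_of_mass_series(
    topology: Topology, coords: np.ndarray, group: str
) -> np.ndarray:
    """COM of *group* for every frame, shape (F, 3)."""
    idx = topology.group_indices(group)
    if idx.size == 0:
        raise ValueError(f"group {group!r} is empty")
    m = topology.masses[idx]
    return np.einsum("m,fmi->fi", m, coords[:, idx, :]) / m.sum()


def surface_distance(
    dye_com: np.ndarray, np_model: NanoparticleModel, frame: int | None = None
) -> float | np.ndarray:
    """COM-to-surface distance ``|com − center| − radius`` (Å, may be < 0).

    ``dye_com`` may be one point or a per-frame series; for a series with
    per-frame centers the frames are matched elementwise.
    """
    com = np.asarray(dye_com, dtype=float)
    if com.ndim == 1:
        center = np_model.center_at(frame if frame is not None else 0)
        return float(np.linalg.norm(com - center) - np_model.radius)
    centers = np_model.centers
    if centers.ndim == 1:
        centers = centers[None, :]
    return np.linalg.norm(com - centers, axis=1) - np_model.radius


def _smallest_axis(coords: np.ndarray) -> np.ndarray:
    """Eigenvector of the smallest principal second moment, batched over frames.

    ``coords`` has shape (..., m, 3); degenerate (collinear or < 3 point)
    inputs raise.
    """
    x = np.asarray(coords, dtype=float)
    if x.shape[-2] < 3:
        raise ValueError("plane fit needs at least 3 particles")
    centered = x - x.mean(axis=-2, keepdims=True)
    cov = np.einsum("...mi,...mj->...ij", centered, centered)
    w, v = np.linalg.eigh(cov)
    # rank check: the two largest moments must be well above numerical zero,
    # otherwise the points are collinear and no plane is defined
    scale = np.maximum(w[..., 2], 1e-30)
    if np.any(w[..., 1] / scale < 1e-8):
        raise ValueError("degenerate (collinear) particle set; no plane normal")
    return v[..., :, 0]


def core_plane_normal(
    topology: Topology,
    frame: np.ndarray,
    core_group: str,
    reference_radial: np.ndarray | None = None,
) -> np.ndarray:
    """Unit normal of the best-fit plane of a planar core selection.

    The normal is the eigenvector of the smallest principal second moment of
    the centered core coordinates (no mass weighting).  When a radial
    direction toward the nanoparticle surface is supplied, the sign is fixed
    so the normal has a non-negative dot product with it.
    """
    idx = topology.group_indices(core_group)
    n = _smallest_axis(np.asarray(frame, dtype=float)[idx])
    if reference_radial is not None and float(np.dot(n, reference_radial)) < 0:
        n = -n
    return n


def plane_normal_series(
    topology: Topology,
    coords: np.ndarray,
    core_group: str,
    radial: np.ndarray | None = None,
) -> np.ndarray:
    """Best-fit plane normals for every frame, shape (F, 3)."""
    idx = topology.group_indices(core_group)
    n = _smallest_axis(coords[:, idx, :])
    if radial is not None:
        sign = np.sign(np.einsum("fi,fi->f", n, radial))
        sign[sign == 0] = 1.0
        n = n * sign[:, None]
    return n


def parallelism_angle(normal: np.ndarray, radial: np.ndarray) -> float | np.ndarray:
    """Angle (deg, in [0, 90]) between a plane normal and the radial direction.

    0° means the plane is exactly parallel to the local spherical surface.
    The sign of either vector is irrelevant: the angle is folded,
    min(α, 180 − α).
    """
    a = np.asarray(normal, dtype=float)
    b = np.asarray(radial, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero vector has no direction")
    c = np.abs(np.einsum("...i,...i->...", a, b) / (na * nb))
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


def dipole_moment(
    topology: Topology,
    frame: np.ndarray,
    group: str,
    reference: str | np.ndarray = "com",
) -> DipoleVector:
    """Dipole Σ qᵢ(rᵢ − reference) of *group* in one frame.

    ``reference`` is either the string ``'com'`` (the group's own mass-weighted
    center, the default) or an explicit point.  For net-neutral groups the
    result is reference-independent; for charged groups shifting the reference
    by ``t`` shifts the dipole by ``−q_net·t`` exactly.
    """
    idx = topology.group_indices(group)
    if idx.size == 0:
        raise ValueError(f"group {group!r} is empty")
    q = topology.charges[idx]
    r = np.asarray(frame, dtype=float)[idx]
    ref = (
        center_of_mass(topology, frame, group)
        if isinstance(reference, str) and reference == "com"
        else np.asarray(reference, dtype=float)
    )
    comp = (q[:, None] * (r - ref)).sum(axis=0)
    return DipoleVector(components=comp, reference_point=ref, net_charge=float(q.sum()))


def dipole_series(
    topology: Topology, coords: np.ndarray, group: str
) -> np.ndarray:
    """Per-frame dipole components (F, 3), COM-referenced."""
    idx = topology.group_indices(group)
    q = topology.charges[idx]
    com = center_of_mass_series(topology, coords, group)
    rel = coords[:, idx, :] - com[:, None, :]
    return np.einsum("m,fmi->fi", q, rel)


def dipole_angle_theta(
    d1: DipoleVector | np.ndarray, d2: DipoleVector | np.ndarray
) -> float | np.ndarray:
    """Angle θ (deg, [0, 180]) between two dipole vectors.

    During stable adsorption of a cationic dye on an anionic particle the two
    dipoles approach an antiparallel arrangement, θ → 180°, although thermal
    motion and the surrounding ion atmosphere keep the observed mean well
    below the ideal value.
    """
    a = d1.components if isinstance(d1, DipoleVector) else np.asarray(d1, float)
    b = d2.components if isinstance(d2, DipoleVector) else np.asarray(d2, float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero dipole has no direction")
    c = np.einsum("...i,...i->...", a, b) / (na * nb)
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


# ---------------------------------------------------------------------------
# per-frame metric tables
# ---------------------------------------------------------------------------


def trajectory_metrics(
    trajectory: Trajectory,
    dyes: list[str] | None = None,
    np_models: list[NanoparticleModel] | None = None,
    np_diameter: float | None = None,
    radius_mode: str = "nominal",
) -> pd.DataFrame:
    """Per-frame dye–nanoparticle metrics for every dye/NP combination.

    Columns: ``time_ns, dye, np, surface_dist_A, parallel_angle_deg,
    theta_deg``.  Dyes and nanoparticles default to the ``_core`` naming
    convention of the topology (see :func:`dyesorb.trajio.infer_roles`).
    """
    top = trajectory.topology
    auto_dyes, auto_nps = infer_roles(top)
    dyes = dyes if dyes is not None else auto_dyes
    if np_models is None:
        np_models = [
            NanoparticleModel.from_trajectory(
                trajectory, g, diameter=np_diameter, mode=radius_mode
            )
            for g in auto_nps
        ]
    f = trajectory.n_frames
    frames_out = []
    np_dipoles = {
        m.label: dipole_series(top, trajectory.coords, m.label) for m in np_models
    }
    for dye in dyes:
        com = center_of_mass_series(top, trajectory.coords, dye)
        dye_dip = dipole_series(top, trajectory.coords, dye)
        for m in np_models:
            centers = m.centers if m.centers.ndim == 2 else np.tile(m.centers, (f, 1))
            radial = com - centers
            dist = np.linalg.norm(radial, axis=1) - m.radius
            radial_unit = radial / np.linalg.norm(radial, axis=1)[:, None]
            normals = plane_normal_series(
                top, trajectory.coords, f"{dye}_core", radial=radial_unit
            )
            par = parallelism_angle(normals, radial_unit)
            theta = dipole_angle_theta(dye_dip, np_dipoles[m.label])
            frames_out.append(
                pd.DataFrame(
                    {
                        "time_ns": trajectory.times,
                        "dye": dye,
                        "np": m.label,
                        "surface_dist_A": dist,
                        "parallel_angle_deg": par,
                        "theta_deg": theta,
                    }
                )
            )
    return pd.concat(frames_out, ignore_index=True)


def pair_metrics(
    trajectory: Trajectory,
    dyes: list[str] | None = None,
    np_models: list[NanoparticleModel] | None = None,
    np_diameter: float | None = None,
    radius_mode: str = "nominal",
) -> pd.DataFrame:
    """Per-frame dye-pair stacking metrics for dimer detection.

    Columns: ``time_ns, dye_i, dye_j, core_dist_A, stack_angle_deg,
    pair_surface_dist_A`` where ``stack_angle_deg`` is the folded angle
    between the two core-plane normals (0° for both parallel and antiparallel
    face-to-face stacking) and ``pair_surface_dist_A`` is the surface distance
    of the two-dye COM from the nearest nanoparticle (inf without particles).
    """
    top = trajectory.topology
    auto_dyes, auto_nps = infer_roles(top)
    dyes = dyes if dyes is not None else auto_dyes
    if np_models is None:
        np_models = [
            NanoparticleModel.from_trajectory(
                trajectory, g, diameter=np_diameter, mode=radius_mode
            )
            for g in auto_nps
        ]
    core_com = {
        d: center_of_mass_series(top, trajectory.coords, f"{d}_core") for d in dyes
    }
    normals = {
        d: plane_normal_series(top, trajectory.coords, f"{d}_core") for d in dyes
    }
    masses = {d: top.masses[top.group_indices(d)].sum() for d in dyes}
    dye_com = {d: center_of_mass_series(top, trajectory.coords, d) for d in dyes}
    out = []
    for a_i in range(len(dyes)):
        for b_i in range(a_i + 1, len(dyes)):
            di, dj = dyes[a_i], dyes[b_i]
            dist = np.linalg.norm(core_com[di] - core_com[dj], axis=1)
            ang = parallelism_angle(normals[di], normals[dj])
            pc = (
                masses[di] * dye_com[di] + masses[dj] * dye_com[dj]
            ) / (masses[di] + masses[dj])
            if np_models:
                surf = np.min(
                    np.stack([surface_distance(pc, m) for m in np_models]), axis=0
                )
            else:
                surf = np.full(trajectory.n_frames, np.inf)
            out.append(
                pd.DataFrame(
                    {
                        "time_ns": trajectory.times,
                        "dye_i": di,
                        "dye_j": dj,
                        "core_dist_A": dist,
                        "stack_angle_deg": ang,
                        "pair_surface_dist_A": surf,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)
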