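"""Synthetic trajectory, force-trace and system-composition generators.

Everything the analysis stages consume can be produced here without an MD
engine:

* a rigid-body Brownian toy simulator: each dye is a rigid 64-site body with
  a 30-site coplanar core, moved by overdamped translational/rotational
  Langevin updates in the field of one or more charged spheres.  A screened
  radial attraction pulls dyes toward each sphere; a short-range adsorption
  well engages only while the core-plane normal is inside an orientation
  gate around the radial direction (producing stable-adsorption episodes);
  a pairwise face-to-face stacking well produces dimers.  Gate functions are
  smooth cosine ramps;
* a *scripted* mode that replays user-specified state and dimer intervals
  exactly and noise-free, for ground-truth recovery tests;
* a quasi-static constant-velocity pulling generator whose sawtooth trace
  releases a known total well depth;
* composition fixtures for the eight reference dye/nanoparticle systems.

Ground truth (state intervals, dimer events, total well depth) is logged for
every generated object.  All randomness is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import PN_A_TO_EV
from .smd import ForceTrace
from .surface import SystemSpec, ionization_fraction_for_ph
from .trajio import Topology, Trajectory

__all__ = [
    "NPSpec",
    "SimConfig",
    "StateInterval",
    "DimerInterval",
    "TrimerScript",
    "Script",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_smd_trace",
    "make_table1_fixture",
    "frame_aligned_intervals",
    "TABLE1_SYSTEMS",
    "TABLE2_ADSORBED_PERCENT",
    "TABLE2_PRINTED_AVERAGE",
]


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class NPSpec:
    """A charged sphere: center (Å), radius (Å), adsorption well depth (kT)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 20.0
    well_depth: float = 8.0
    n_sites: int = 64
    total_charge: float = -51.0


@dataclass
class StateInterval:
    """A scripted or ground-truth state interval [start, end) in ns."""

    start: float
    end: float
    label: str  # FREE | A | RA | T
    np_index: int = 0


@dataclass
class DimerInterval:
    """A scripted or ground-truth dimer episode of dyes (i, j)."""

    i: int
    j: int
    start: float
    end: float
    location: str = "solute"  # solute | matrix
    breakup: str = "dissociation"  # dissociation | desorption | censored


@dataclass
class TrimerScript:
    """Scripted transient contact of a third dye with dimer (i, j)."""

    third: int
    i: int
    j: int
    start: float
    end: float


@dataclass
class Script:
    """Exact replay instructions: per-dye state intervals plus dimer episodes."""

    states: dict[int, list[StateInterval]] = field(default_factory=dict)
    dimers: list[DimerInterval] = field(default_factory=list)
    trimers: list[TrimerScript] = field(default_factory=list)


@dataclass
class GroundTruth:
    """True per-dye state intervals, dimer events and pulling well depth."""

    states: dict[int, list[StateInterval]] = field(default_factory=dict)
    dimers: list[DimerInterval] = field(default_factory=list)
    smd_total_depth_ev: float | None = None


@dataclass
class SimConfig:
    """Conditions of a toy dye/nanoparticle run.

    Defaults emulate the reference systems: six dyes of 64 sites (30-site
    planar core) around one 40 Å-diameter sphere, 100 ns at 0.01 ns/frame
    (10⁴ frames).  Diffusion constants are Stokes–Einstein estimates for a
    ~5 Å dye in water at 300 K (D_t ≈ 40 Å²/ns, D_r ≈ 1 rad²/ns).
    """

    n_dye: int = 6
    dye_site_count: int = 64
    core_site_count: int = 30
    nps: list[NPSpec] = field(default_factory=lambda: [NPSpec()])
    d_t: float = 40.0  # Å²/ns
    d_r: float = 1.0  # rad²/ns
    timestep: float = 0.01  # ns per frame
    duration: float = 100.0  # ns
    attraction_kt: float = 6.0  # screened radial attraction strength, kT
    adsorption_gate_deg: float = 30.0
    stacking_depth: float = 6.0  # kT
    stacking_gate_deg: float = 30.0
    debye_length: float = 10.0  # Å
    noise_sd: float = 0.0  # Å positional (measurement) noise on emitted sites
    confinement_radius: float | None = 60.0
    substeps: int = 5  # integration substeps per emitted frame (emergent mode)
    seed: int = 0
    script: Script | None = None

    def __post_init__(self) -> None:
        if self.n_dye < 1 or self.dye_site_count < self.core_site_count:
            raise ValueError("need >=1 dye and core smaller than the dye")
        if self.timestep <= 0 or self.duration <= self.timestep:
            raise ValueError("need a positive timestep shorter than the duration")
        for name in ("d_t", "d_r", "adsorption_gate_deg", "stacking_gate_deg",
                     "debye_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# rigid-body templates
# ---------------------------------------------------------------------------


def build_dye_template(
    n_sites: int = 64, n_core: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Body-frame dye sites: (coords, masses, charges, core_indices).

    The core is a planar grid in z = 0 (normal = body ẑ); the tail extends
    along +x.  Coordinates are centered on the mass-weighted COM; total
    charge is +1 e.
    """
    rows = max(3, int(round(math.sqrt(n_core * 2 / 3))))
    cols = int(math.ceil(n_core / rows))
    xs = np.linspace(-3.0, 3.0, cols)
    ys = np.linspace(-2.0, 2.0, rows)
    grid = np.array([(x, y, 0.0) for y in ys for x in xs])[:n_core]
    n_tail = n_sites - n_core
    tx = np.linspace(4.0, 10.0, n_tail)
    tail = np.stack(
        [tx, 0.4 * np.cos(np.arange(n_tail) * np.pi), np.zeros(n_tail)], axis=1
    )
    coords = np.vstack([grid, tail])
    masses = np.full(n_sites, 12.0)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    coords = coords - com
    charges = np.empty(n_sites)
    charges[:n_core] = 0.6 / n_core
    charges[n_core:] = 0.4 / n_tail
    return coords, masses, charges, np.arange(n_core)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def build_np_sites(spec: NPSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sphere-surface sites with a slight charge gradient giving a dipole."""
    unit = _fibonacci_sphere(spec.n_sites)
    coords = np.asarray(spec.center, dtype=float) + spec.radius * unit
    masses = np.full(spec.n_sites, 60.0)
    z = unit[:, 2]
    charges = spec.total_charge / spec.n_sites + 0.5 * (z - z.mean())
    return coords, masses, charges


def _build_topology(config: SimConfig) -> tuple[Topology, np.ndarray, np.ndarray]:
    """Topology with groups SNP1..k, R6G_1..n, R6G_i_core; returns NP site block."""
    dye_coords, dye_masses, dye_charges, core_idx = build_dye_template(
        config.dye_site_count, config.core_site_count
    )
    blocks_m, blocks_q, groups = [], [], {}
    np_coords_all = []
    offset = 0
    for k, spec in enumerate(config.nps):
        c, m, q = build_np_sites(spec)
        np_coords_all.append(c)
        blocks_m.append(m)
        blocks_q.append(q)
        groups[f"SNP{k + 1}"] = np.arange(offset, offset + spec.n_sites)
        offset += spec.n_sites
    for d in range(config.n_dye):
        blocks_m.append(dye_masses)
        blocks_q.append(dye_charges)
        groups[f"R6G_{d + 1}"] = np.arange(offset, offset + config.dye_site_count)
        groups[f"R6G_{d + 1}_core"] = offset + core_idx
        offset += config.dye_site_count
    top = Topology(
        masses=np.concatenate(blocks_m),
        charges=np.concatenate(blocks_q),
        groups=groups,
    )
    np_block = np.vstack(np_coords_all) if np_coords_all else np.empty((0, 3))
    return top, np_block, dye_coords


def _rotation_to(normal: np.ndarray, spin: float = 0.0) -> Rotation:
    """Minimal rotation taking body ẑ onto *normal*, then spun about it."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, n)
    s = np.linalg.norm(v)
    c = float(np.dot(z, n))
    if s < 1e-12:
        base = Rotation.identity() if c > 0 else Rotation.from_rotvec([np.pi, 0, 0])
    else:
        base = Rotation.from_rotvec(v / s * math.atan2(s, c))
    if spin:
        return Rotation.from_rotvec(np.asarray(n) * spin) * base
    return base


def _perp(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to u."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    return v / np.linalg.norm(v)


def _tilted(u: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit vector at the given angle from u (about a fixed perpendicular)."""
    axis = _perp(u)
    return Rotation.from_rotvec(axis * math.radians(angle_deg)).apply(u)


# ---------------------------------------------------------------------------
# scripted mode
# ---------------------------------------------------------------------------


def _fill_free(
    intervals: list[StateInterval], duration: float
) -> list[StateInterval]:
    """Sort, validate non-overlap and fill gaps with FREE to partition [0, T)."""
    ivs = sorted(intervals, key=lambda s: s.start)
    out: list[StateInterval] = []
    cursor = 0.0
    for s in ivs:
        if s.start < cursor - 1e-9:
            raise ValueError("scripted state intervals overlap")
        if s.start > cursor + 1e-9:
            out.append(StateInterval(cursor, s.start, "FREE"))
        out.append(replace(s))
        cursor = s.end
    if cursor < duration - 1e-9:
        out.append(StateInterval(cursor, duration, "FREE"))
    return out


def _scripted_paths(
    config: SimConfig, times: np.ndarray, b_core: np.ndarray
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Per-frame dye COM positions (F, n, 3) and rotations (F, n, quat)."""
    script = config.script
    n, f = config.n_dye, len(times)
    homes = _fibonacci_sphere(max(n, 4))[:n]
    centers = np.array([s.center for s in config.nps], dtype=float)
    radii = np.array([s.radius for s in config.nps], dtype=float)

    pos = np.empty((f, n, 3))
    quat = np.empty((f, n, 4))

    state_truth: dict[int, list[StateInterval]] = {}
    per_dye_states = {
        d: _fill_free(list((script.states or {}).get(d, [])), config.duration)
        for d in range(n)
    }

    for d in range(n):
        u = homes[d]
        for iv in per_dye_states[d]:
            c = centers[iv.np_index]
            r0 = radii[iv.np_index]
            mask = (times >= iv.start - 1e-12) & (times < iv.end - 1e-12)
            if not mask.any():
                continue
            t = times[mask]
            if iv.label == "FREE":
                rad = r0 + 25.0 + 5.0 * np.sin(2 * np.pi * t / 20.0 + d)
                normal = _tilted(u, 60.0)
                rot = _rotation_to(normal)
                pos[mask, d] = c + u[None, :] * rad[:, None]
                quat[mask, d] = rot.as_quat()
            elif iv.label == "A":
                pos[mask, d] = c + u * (r0 + 2.0)
                quat[mask, d] = _rotation_to(u).as_quat()
            elif iv.label == "T":
                pos[mask, d] = c + u * (r0 + 3.0)
                quat[mask, d] = _rotation_to(_tilted(u, 70.0)).as_quat()
            elif iv.label == "RA":
                rad = r0 + 3.0 + 1.2 * np.sin(2 * np.pi * t / 2.0)
                pos[mask, d] = c + u[None, :] * rad[:, None]
                phase = np.floor((t - iv.start) / 0.5).astype(int) % 2
                q_on = _rotation_to(_tilted(u, 10.0)).as_quat()
                q_off = _rotation_to(_tilted(u, 60.0)).as_quat()
                quat[mask, d] = np.where(phase[:, None] == 0, q_on, q_off)
            else:
                raise ValueError(f"unknown scripted label {iv.label!r}")
        state_truth[d] = [iv for iv in per_dye_states[d]]

    # dimer scripting overrides member positions during the episode
    dimer_truth: list[DimerInterval] = []
    for ev in script.dimers:
        i, j = ev.i, ev.j
        u_pair = homes[i] + homes[j]
        u_pair = (
            u_pair / np.linalg.norm(u_pair)
            if np.linalg.norm(u_pair) > 1e-6
            else _perp(homes[i])
        )
        c = centers[0]
        r0 = radii[0]
        w = _perp(u_pair)
        rot = _rotation_to(w, spin=0.0)
        off = rot.apply(b_core)  # core-COM offset shared by both members
        mask = (times >= ev.start - 1e-12) & (times < ev.end - 1e-12)
        t = times[mask]
        if ev.location == "matrix":
            pc = c + u_pair * (r0 + 2.5)
        else:
            pc = c + u_pair * (r0 + 30.0)
        pc = np.tile(pc, (mask.sum(), 1))
        if ev.breakup == "desorption":
            lead = times[mask] >= ev.end - 2.0
            pc[lead] = c + u_pair * (r0 + 12.0)
        q_mid = pc + off[None, :]
        pos[mask, i] = q_mid - 2.0 * w - off
        pos[mask, j] = q_mid + 2.0 * w - off
        quat[mask, i] = rot.as_quat()
        quat[mask, j] = rot.as_quat()
        dimer_truth.append(replace(ev))
        # ground-truth states of the members during the episode
        for d in (i, j):
            new: list[StateInterval] = []
            for iv in state_truth[d]:
                new.extend(_carve(iv, ev, config))
            state_truth[d] = new

    for tr in script.trimers:
        u_pair = homes[tr.i] + homes[tr.j]
        u_pair = (
            u_pair / np.linalg.norm(u_pair)
            if np.linalg.norm(u_pair) > 1e-6
            else _perp(homes[tr.i])
        )
        w = _perp(u_pair)
        rot = _rotation_to(w)
        off = rot.apply(b_core)
        mask = (times >= tr.start - 1e-12) & (times < tr.end - 1e-12)
        # park the third core 4.5 Å beyond member j's core
        base = pos[mask, tr.j] + off[None, :]
        pos[mask, tr.third] = base + 4.5 * w - off
        quat[mask, tr.third] = rot.as_quat()

    gt = GroundTruth(states=state_truth, dimers=dimer_truth)
    return pos, quat, gt


def _carve(
    iv: StateInterval, ev: DimerInterval, config: SimConfig
) -> list[StateInterval]:
    """Replace the overlap of a state interval with a dimer episode.

    Members of a solute dimer are FREE (far from every surface); members of a
    matrix dimer sit near the surface with their cores perpendicular to it,
    which the episode classifier sees as trapping (T) — except during the
    final 2 ns of a desorption episode, when the intact pair has left.
    """
    s, e = max(iv.start, ev.start), min(iv.end, ev.end)
    if s >= e:
        return [iv]
    if iv.label != "FREE":
        raise ValueError(
            "scripted dimer overlaps a non-FREE state interval of a member dye"
        )
    out = []
    if iv.start < s:
        out.append(StateInterval(iv.start, s, "FREE", iv.np_index))
    if ev.location == "matrix":
        if ev.breakup == "desorption" and e - 2.0 > s:
            out.append(StateInterval(s, e - 2.0, "T"))
            out.append(StateInterval(e - 2.0, e, "FREE"))
        else:
            out.append(StateInterval(s, e, "T"))
    else:
        out.append(StateInterval(s, e, "FREE"))
    if iv.end > e:
        out.append(StateInterval(e, iv.end, "FREE", iv.np_index))
    return out


# ---------------------------------------------------------------------------
# emergent mode
# ---------------------------------------------------------------------------


def _cos_gate(angle_deg: np.ndarray, width_deg: float) -> np.ndarray:
    """Smooth cosine ramp: 1 at 0°, 0 beyond the gate width."""
    x = np.clip(np.asarray(angle_deg, dtype=float) / width_deg, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * x))


def _rotate_towards(
    rot: Rotation, normals: np.ndarray, targets: np.ndarray, max_angle: np.ndarray
) -> Rotation:
    """Rotate each body so its normal moves toward ±target by ≤ max_angle."""
    sign = np.sign(np.einsum("ni,ni->n", normals, targets))
    sign[sign == 0] = 1.0
    tgt = targets * sign[:, None]
    v = np.cross(normals, tgt)
    s = np.linalg.norm(v, axis=1)
    ang = np.arctan2(s, np.einsum("ni,ni->n", normals, tgt))
    step = np.minimum(ang, max_angle)
    axis = np.where(s[:, None] > 1e-12, v / np.maximum(s, 1e-12)[:, None], 0.0)
    return Rotation.from_rotvec(axis * step[:, None]) * rot


#: regularized force field: total deterministic force per dye is capped (kT/Å)
_FORCE_CAP = 4.0


def _emergent_paths(
    config: SimConfig, times: np.ndarray, b_core: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    n, f = config.n_dye, len(times)
    sub = max(1, int(config.substeps))
    dts = config.timestep / sub  # integration substep between emitted frames
    centers = np.array([s.center for s in config.nps], dtype=float)
    radii = np.array([s.radius for s in config.nps], dtype=float)
    depths = np.array([s.well_depth for s in config.nps], dtype=float)

    homes = _fibonacci_sphere(max(n, 4))[:n]
    start_r = (radii.max() if len(config.nps) else 0.0) + 15.0
    pos = (centers[0] if len(config.nps) else np.zeros(3)) + homes * start_r
    q0 = rng.normal(size=(n, 4))
    rot = Rotation.from_quat(q0 / np.linalg.norm(q0, axis=1, keepdims=True))

    zhat = np.array([0.0, 0.0, 1.0])
    pos_out = np.empty((f, n, 3))
    quat_out = np.empty((f, n, 4))
    latent_dist = np.empty((f, n, max(len(config.nps), 1)))
    latent_par = np.empty((f, n, max(len(config.nps), 1)))
    latent_core = np.empty((f, n, 3))
    latent_norm = np.empty((f, n, 3))

    sig_t = math.sqrt(2.0 * config.d_t * dts)
    sig_r = math.sqrt(2.0 * config.d_r * dts)

    def advance(pos: np.ndarray, rot: Rotation) -> tuple[np.ndarray, Rotation]:
        normals = rot.apply(zhat)
        cores = pos + rot.apply(b_core)
        force = np.zeros((n, 3))
        for k in range(len(config.nps)):
            delta = pos - centers[k]
            dist = np.linalg.norm(delta, axis=1)
            rad = delta / dist[:, None]
            d = dist - radii[k]
            par = np.degrees(
                np.arccos(np.clip(np.abs(np.einsum("ni,ni->n", normals, rad)), 0, 1))
            )
            amp = (config.attraction_kt / config.debye_length) * np.exp(
                -np.clip(d, 0.0, None) / config.debye_length
            )
            force -= amp[:, None] * rad
            wall = d < 1.0
            force[wall] += (50.0 * (1.0 - d[wall]))[:, None] * rad[wall]
            g = _cos_gate(par, config.adsorption_gate_deg)
            engaged = d < 8.0
            well = np.where(engaged, depths[k] * g * (d - 2.5) / 1.5, 0.0)
            force -= well[:, None] * rad
            # orientation capture near the surface (wide 90° ramp for the
            # torque so misoriented dyes can still be steered into the gate)
            g_wide = _cos_gate(par, 90.0)
            max_ang = np.where(engaged, 10.0 * depths[k] * g_wide * dts, 0.0)
            if np.any(max_ang > 0):
                rot = _rotate_towards(rot, normals, rad, np.minimum(max_ang, 0.6))
                normals = rot.apply(zhat)

        if config.stacking_depth > 0 and n > 1:
            for a in range(n):
                for b in range(a + 1, n):
                    sep = cores[a] - cores[b]
                    s = float(np.linalg.norm(sep))
                    if s > 10.0 or s < 1e-9:
                        continue
                    u = sep / s
                    ang = math.degrees(
                        math.acos(min(1.0, abs(float(np.dot(normals[a], normals[b])))))
                    )
                    g = _cos_gate(np.array(ang), 90.0)
                    fmag = config.stacking_depth * float(g) * (s - 4.0) / 1.5
                    if s < 3.0:  # ungated core overlap repulsion
                        fmag += 4.0 * (s - 3.0)
                    force[a] -= fmag * u
                    force[b] += fmag * u
                    cap = np.minimum(
                        np.full(2, 20.0 * config.stacking_depth * float(g) * dts), 0.6
                    )
                    pair_rot = _rotate_towards(
                        Rotation.from_quat(rot.as_quat()[[a, b]]),
                        normals[[a, b]],
                        np.stack([u, u]),
                        cap,
                    )
                    qs = rot.as_quat()
                    qs[[a, b]] = pair_rot.as_quat()
                    rot = Rotation.from_quat(qs)
                    normals = rot.apply(zhat)

        if config.confinement_radius is not None:
            rr = np.linalg.norm(pos, axis=1)
            outside = rr > config.confinement_radius
            if outside.any():
                force[outside] -= (
                    5.0 * (rr[outside] - config.confinement_radius)
                )[:, None] * (pos[outside] / rr[outside, None])

        mag = np.linalg.norm(force, axis=1)
        force = force * np.minimum(1.0, _FORCE_CAP / np.maximum(mag, 1e-12))[:, None]
        drift = config.d_t * force * dts
        if np.any(np.linalg.norm(drift, axis=1) > 0.5):
            raise ValueError(
                "unstable timestep: deterministic displacement per step exceeds 0.5 A"
            )
        pos = pos + drift + sig_t * rng.standard_normal((n, 3))
        rot = Rotation.from_rotvec(sig_r * rng.standard_normal((n, 3))) * rot
        return pos, rot

    for fi in range(f):
        normals = rot.apply(zhat)
        cores = pos + rot.apply(b_core)
        pos_out[fi] = pos
        quat_out[fi] = rot.as_quat()
        latent_core[fi] = cores
        latent_norm[fi] = normals
        for k in range(len(config.nps)):
            delta = pos - centers[k]
            dist = np.linalg.norm(delta, axis=1)
            rad = delta / dist[:, None]
            latent_dist[fi, :, k] = dist - radii[k]
            latent_par[fi, :, k] = np.degrees(
                np.arccos(np.clip(np.abs(np.einsum("ni,ni->n", normals, rad)), 0, 1))
            )
        if fi < f - 1:
            for _ in range(sub):
                pos, rot = advance(pos, rot)

    gt = _emergent_ground_truth(config, times, latent_dist, latent_par,
                                latent_core, latent_norm)
    return pos_out, quat_out, gt


def _emergent_ground_truth(
    config: SimConfig,
    times: np.ndarray,
    dist: np.ndarray,
    par: np.ndarray,
    cores: np.ndarray,
    normals: np.ndarray,
) -> GroundTruth:
    """Label the exact latent series with the default episode rules."""
    from .dimers import DimerConfig, detect_dimers
    from .states import ClassifierConfig, segment_states

    cfg = ClassifierConfig()
    states: dict[int, list[StateInterval]] = {}
    dt = config.timestep
    for d in range(config.n_dye):
        ivs: list[StateInterval] = []
        for k in range(len(config.nps)):
            for seg in segment_states(
                times, dist[:, d, k], par[:, d, k], None, cfg,
                dye=f"R6G_{d + 1}", np_label=f"SNP{k + 1}",
            ):
                ivs.append(StateInterval(seg.start, seg.end + dt, seg.label, k))
        states[d] = _fill_free(sorted(ivs, key=lambda s: s.start), config.duration)

    pairs = [
        (f"R6G_{a + 1}", f"R6G_{b + 1}")
        for a in range(config.n_dye)
        for b in range(a + 1, config.n_dye)
    ]
    idx = [(a, b) for a in range(config.n_dye) for b in range(a + 1, config.n_dye)]
    core_d = np.stack(
        [np.linalg.norm(cores[:, a] - cores[:, b], axis=1) for a, b in idx], axis=1
    )
    ang = np.stack(
        [
            np.degrees(
                np.arccos(
                    np.clip(
                        np.abs(np.einsum("fi,fi->f", normals[:, a], normals[:, b])),
                        0,
                        1,
                    )
                )
            )
            for a, b in idx
        ],
        axis=1,
    )
    dcfg = DimerConfig()
    events = detect_dimers(times, pairs, core_d, ang, dcfg)
    name_to_num = {f"R6G_{d + 1}": d for d in range(config.n_dye)}
    dimers = [
        DimerInterval(
            i=name_to_num[e.pair[0]],
            j=name_to_num[e.pair[1]],
            start=e.start,
            end=e.end + dt,
        )
        for e in events
    ]
    return GroundTruth(states=states, dimers=dimers)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def simulate_trajectory(
    config: SimConfig,
) -> tuple[Trajectory, Topology, GroundTruth]:
    """Generate a toy trajectory plus its topology and ground truth.

    ``config.script`` selects scripted replay (exact, noise-free dynamics);
    otherwise the rigid-body Brownian simulator runs.  Emitted site
    coordinates optionally carry Gaussian measurement noise ``noise_sd``.
    Identical configs (same seed) produce bit-identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    top, np_sites, dye_template = _build_topology(config)
    core_idx = np.arange(config.core_site_count)
    b_core = dye_template[core_idx].mean(axis=0)

    n_frames = int(round(config.duration / config.timestep))
    times = np.arange(n_frames) * config.timestep

    if config.script is not None:
        pos, quat, gt = _scripted_paths(config, times, b_core)
    else:
        pos, quat, gt = _emergent_paths(config, times, b_core, rng)

    f, n = n_frames, config.n_dye
    mats = Rotation.from_quat(quat.reshape(-1, 4)).as_matrix().reshape(f, n, 3, 3)
    dye_sites = (
        np.einsum("fnij,mj->fnmi", mats, dye_template) + pos[:, :, None, :]
    )
    coords = np.empty((f, top.n_particles, 3))
    n_np_sites = np_sites.shape[0]
    coords[:, :n_np_sites, :] = np_sites[None, :, :]
    coords[:, n_np_sites:, :] = dye_sites.reshape(f, n * config.dye_site_count, 3)
    if config.noise_sd > 0:
        coords = coords + rng.normal(0.0, config.noise_sd, size=coords.shape)
    top.reference_coords = coords[0].copy()
    traj = Trajectory(times=times, coords=coords, topology=top)
    return traj, top, gt


def frame_aligned_intervals(
    intervals: list[StateInterval] | list[DimerInterval], times: np.ndarray
) -> list[tuple]:
    """Snap [start, end) ground-truth intervals to the frame grid.

    Returns (first-frame time, last-frame time, …tag) tuples comparable with
    classifier output, which reports first/last frame times of an episode.
    """
    times = np.asarray(times, dtype=float)
    out = []
    for iv in intervals:
        lo = int(np.searchsorted(times, iv.start - 1e-9))
        hi = int(np.searchsorted(times, iv.end - 1e-9)) - 1
        if hi < lo:
            continue
        if isinstance(iv, StateInterval):
            out.append((times[lo], times[hi], iv.label, iv.np_index))
        else:
            out.append((times[lo], times[hi], iv.i, iv.j))
    return out


def simulate_smd_trace(
    well_depths_ev: list[float],
    positions_A: list[float] | None = None,
    k: float = 278.0,
    velocity: float = 0.01,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_ps: float = 1.0,
    tail_A: float = 10.0,
) -> tuple[ForceTrace, GroundTruth]:
    """Quasi-static constant-velocity pulling over a sequence of wells.

    The pulled compound sits pinned at each well position while the spring
    force ramps at slope k·v; at the rupture force F_i = √(2k·E_i) it escapes
    and relaxes to the cantilever position (the force drops to zero and the
    displacement jumps by F_i/k), so each sawtooth releases exactly the well
    depth E_i of spring energy and the ground-truth total is Σ E_i.  Gaussian
    noise of ``noise_sd`` pN is added to the force samples.
    """
    depths_pna = np.asarray(well_depths_ev, dtype=float) / PN_A_TO_EV
    if np.any(depths_pna < 0):
        raise ValueError("well depths must be >= 0")
    f_rup = np.sqrt(2.0 * k * depths_pna)
    n_wells = len(depths_pna)
    if positions_A is None:
        positions = [0.0]
        for i in range(1, n_wells):
            positions.append(positions[-1] + f_rup[i - 1] / k + 5.0)
    else:
        positions = [float(p) for p in positions_A]
        if len(positions) != n_wells:
            raise ValueError("one position per well required")
        for i in range(1, n_wells):
            if positions[i] - positions[i - 1] <= f_rup[i - 1] / k:
                raise ValueError(
                    "overlapping wells: spacing must exceed the rupture stretch"
                )
    rng = np.random.default_rng(seed)
    start = positions[0] if n_wells else 0.0
    end_x = (positions[-1] + f_rup[-1] / k if n_wells else start) + tail_A
    n_samples = int(math.ceil((end_x - start) / (velocity * dt_ps))) + 1
    times = np.arange(n_samples) * dt_ps
    force = np.zeros(n_samples)
    disp = np.zeros(n_samples)
    widx = 0
    pinned = n_wells > 0
    z = start
    for si in range(n_samples):
        x = start + velocity * times[si]
        if pinned:
            fspring = k * (x - z)
            if fspring >= f_rup[widx]:
                # rupture: relax to the cantilever position
                z = x
                fspring = 0.0
                widx += 1
                pinned = False
        if not pinned:
            z = x
            fspring = 0.0
            if widx < n_wells and x >= positions[widx]:
                z = positions[widx]
                pinned = True
                fspring = k * (x - z)
        force[si] = fspring
        disp[si] = z
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=n_samples)
    trace = ForceTrace(
        times=times,
        force=force,
        displacement=disp,
        spring_constant=k,
        pulling_velocity=velocity,
    )
    return trace, GroundTruth(smd_total_depth_ev=float(np.sum(well_depths_ev)))


# ---------------------------------------------------------------------------
# composition fixtures
# ---------------------------------------------------------------------------

#: printed composition of the eight reference systems:
#: crystal, diameter Å, pH, n_snp, atoms/snp, n_cl, n_na per snp, water atoms
TABLE1_SYSTEMS: dict[str, tuple[str, float, int, int, int, int, int, int]] = {
    "40qSNP7": ("quartz", 40.0, 7, 1, 3141, 6, 51, 80118),
    "40qSNP12": ("quartz", 40.0, 12, 1, 3077, 6, 116, 80612),
    "40cSNP7": ("cristobalite", 40.0, 7, 1, 2725, 6, 58, 81832),
    "40cSNP12": ("cristobalite", 40.0, 12, 1, 2638, 6, 155, 80292),
    "20qSNP7": ("quartz", 20.0, 7, 3, 436, 6, 11, 82731),
    "20qSNP12": ("quartz", 20.0, 12, 3, 421, 6, 27, 84153),
    "20cSNP7": ("cristobalite", 20.0, 7, 3, 376, 6, 17, 83325),
    "20cSNP12": ("cristobalite", 20.0, 12, 3, 354, 6, 39, 81861),
}

#: per-repetition adsorbed-time percentages of the four independent runs
TABLE2_ADSORBED_PERCENT: dict[str, list[int]] = {
    "40qSNP7": [31, 20, 21, 18],
    "40qSNP12": [3, 21, 12, 0],
    "40cSNP7": [30, 24, 28, 48],
    "40cSNP12": [6, 0, 9, 0],
    "20qSNP7": [53, 29, 51, 24],
    "20qSNP12": [3, 21, 12, 0],
    "20cSNP7": [38, 32, 37, 23],
    "20cSNP12": [10, 7, 5, 0],
}

#: the published column averages (the last two are not arithmetic means of
#: the published repetitions; see the methods note)
TABLE2_PRINTED_AVERAGE: dict[str, int] = {
    "40qSNP7": 23,
    "40qSNP12": 9,
    "40cSNP7": 33,
    "40cSNP12": 4,
    "20qSNP7": 39,
    "20qSNP12": 9,
    "20cSNP7": 30,
    "20cSNP12": 8,
}


def make_table1_fixture(name: str) -> SystemSpec:
    """Composition fixture for one of the eight reference systems.

    The silanol count is synthetic: it is back-computed as
    ``round(n_Na / ionization_fraction)`` because only the counterion counts
    are published; the back-computed value round-trips to the published Na
    count for every system.
    """
    try:
        crystal, diam, ph, n_snp, atoms_snp, n_cl, n_na, water = TABLE1_SYSTEMS[name]
    except KeyError:
        raise ValueError(
            f"unknown system {name!r}; known: {sorted(TABLE1_SYSTEMS)}"
        ) from None
    frac = ionization_fraction_for_ph(ph)
    return SystemSpec(
        name=name,
        crystal=crystal,
        nominal_diameter=diam,
        ph=ph,
        n_snp=n_snp,
        atoms_per_snp=atoms_snp,
        n_dye=6,
        atoms_per_dye=64,
        dye_charge=1,
        n_silanol=round(n_na / frac),
        ionization_fraction=frac,
        n_cl=n_cl,
        n_na_per_snp=n_na,
        n_water_atoms=water,
    )
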