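"""Topology and trajectory I/O and tabular result writing.

The canonical on-disk formats are plain, diffable text:

* topology: a PDB file (coordinates beyond the first model are ignored)
  accompanied by a sidecar TSV ``particle_id\tmass\tcharge\tgroups`` carrying
  masses (amu), charges (e) and the named selections (semicolon-separated),
  since PDB records hold neither masses nor partial charges;
* trajectory: a TSV with one row per particle per frame,
  ``frame\ttime_ns\tparticle_id\tx\ty\tz`` (Å, ns);
* results: TSV with a header, UTF-8, ``.`` decimal separator, fixed float
  precision, deterministic column order.

Readers reject malformed input; they never silently repair it.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Trajectory",
    "TopologyError",
    "TrajectoryError",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "write_table",
    "read_table",
    "register_schema",
    "write_adsorption_matrix",
    "infer_roles",
]

#: float precision used when writing coordinates / generic result floats
COORD_FMT = "%.4f"
TIME_FMT = "%.6f"


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input."""


@dataclass
class Topology:
    """Particle identities: masses, charges and named selections.

    Particle ids are implicit 0-based row indices into ``masses``/``charges``.
    A group named ``<dye>_core`` must be a subset of the group ``<dye>``.
    """

    masses: np.ndarray
    charges: np.ndarray
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    reference_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.groups = {
            name: np.asarray(np.sort(np.unique(idx)), dtype=int)
            for name, idx in self.groups.items()
        }
        if self.reference_coords is not None:
            self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.validate()

    @property
    def n_particles(self) -> int:
        return int(self.masses.shape[0])

    def group_indices(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise TopologyError(f"unknown group {name!r}") from None

    def validate(self) -> None:
        n = self.n_particles
        if self.charges.shape != (n,):
            raise TopologyError("masses and charges must have equal length")
        if n == 0:
            raise TopologyError("topology has no particles")
        if not np.all(np.isfinite(self.masses)) or np.any(self.masses <= 0):
            raise TopologyError("masses must be finite and > 0")
        if not np.all(np.isfinite(self.charges)):
            raise TopologyError("charges must be finite")
        for name, idx in self.groups.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TopologyError(
                    f"group {name!r} references particle ids outside 0..{n - 1}"
                )
        for name in self.groups:
            if name.endswith("_core"):
                parent = name[: -len("_core")]
                if parent not in self.groups:
                    raise TopologyError(
                        f"core group {name!r} has no parent group {parent!r}"
                    )
                if not np.isin(self.groups[name], self.groups[parent]).all():
                    raise TopologyError(
                        f"core group {name!r} is not a subset of {parent!r}"
                    )
        if self.reference_coords is not None and self.reference_coords.shape != (n, 3):
            raise TopologyError("reference coordinates must have shape (n, 3)")


@dataclass
class Trajectory:
    """Frame times (ns, strictly increasing) and coordinates (frames × particles × 3, Å)."""

    times: np.ndarray
    coords: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def length_ns(self) -> float:
        """Spanned time, last frame minus first."""
        return float(self.times[-1] - self.times[0])

    def validate(self) -> None:
        if self.times.ndim != 1 or self.times.size < 1:
            raise TrajectoryError("trajectory needs at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")
        expected = (self.times.size, self.topology.n_particles, 3)
        if self.coords.shape != expected:
            raise TrajectoryError(
                f"coordinate array has shape {self.coords.shape}, expected {expected}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("coordinates must be finite")


# ---------------------------------------------------------------------------
# topology I/O
# ---------------------------------------------------------------------------


def _default_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".sidecar.tsv")


def read_topology(path: str | Path, sidecar: str | Path | None = None) -> Topology:
    """Read a PDB plus its mass/charge/group sidecar table.

    The PDB supplies reference coordinates (first model only); masses, charges
    and group membership come exclusively from the sidecar — there is no
    element-based guessing.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar table {sidecar} not found; masses/charges cannot be guessed"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = u.atoms.positions.astype(float)
    n = len(u.atoms)

    tab = pd.read_csv(sidecar, sep="\t", dtype={"groups": str}, keep_default_na=False)
    required = {"particle_id", "mass", "charge", "groups"}
    if not required.issubset(tab.columns):
        raise TopologyError(
            f"sidecar {sidecar} must have columns {sorted(required)}"
        )
    ids = tab["particle_id"].to_numpy(dtype=int)
    if len(ids) != len(set(ids)):
        raise TopologyError("duplicate particle ids in sidecar")
    if sorted(ids) != list(range(n)):
        raise TopologyError(
            f"sidecar particle ids must be contiguous 0..{n - 1} matching the PDB"
        )
    order = np.argsort(ids)
    masses = tab["mass"].to_numpy(dtype=float)[order]
    charges = tab["charge"].to_numpy(dtype=float)[order]
    groups: dict[str, list[int]] = {}
    for pid, raw in zip(ids, tab["groups"]):
        for name in str(raw).split(";"):
            name = name.strip()
            if name:
                groups.setdefault(name, []).append(int(pid))
    return Topology(
        masses=masses,
        charges=charges,
        groups={k: np.asarray(v, dtype=int) for k, v in groups.items()},
        reference_coords=coords,
    )


def write_topology(
    topology: Topology,
    path: str | Path,
    sidecar: str | Path | None = None,
    coords: np.ndarray | None = None,
) -> None:
    """Write a PDB (reference coordinates) plus the sidecar table."""
    import MDAnalysis as mda

    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _default_sidecar(path)
    if coords is None:
        coords = topology.reference_coords
    if coords is None:
        raise TopologyError("no coordinates available to write the PDB")
    n = topology.n_particles
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", [f"P{i % 100:02d}" for i in range(n)])
        u.atoms.positions = np.asarray(coords, dtype=float)
        u.atoms.write(str(path))

    member_of: list[list[str]] = [[] for _ in range(n)]
    for name in sorted(topology.groups):
        for i in topology.groups[name]:
            member_of[int(i)].append(name)
    rows = {
        "particle_id": np.arange(n),
        "mass": topology.masses,
        "charge": topology.charges,
        "groups": [";".join(m) for m in member_of],
    }
    pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False, float_format="%.6f")


def infer_roles(topology: Topology) -> tuple[list[str], list[str]]:
    """Split group names into (dyes, nanoparticles) by the ``_core`` convention.

    A dye is any group with a matching ``<name>_core`` selection; every
    remaining non-core group is treated as a nanoparticle.
    """
    cores = {g for g in topology.groups if g.endswith("_core")}
    dyes = sorted(g for g in topology.groups if f"{g}_core" in topology.groups)
    nps = sorted(
        g for g in topology.groups if g not in cores and g not in dyes
    )
    return dyes, nps


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["frame", "time_ns", "particle_id", "x", "y", "z"]


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a trajectory table and validate it against *topology*."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TRAJ_COLUMNS:
        raise TrajectoryError(
            f"trajectory table must have columns {_TRAJ_COLUMNS}, got {list(df.columns)}"
        )
    n = topology.n_particles
    frames = df["frame"].to_numpy(dtype=int)
    order = np.lexsort((df["particle_id"].to_numpy(), frames))
    df = df.iloc[order]
    uniq = np.unique(frames)
    if len(df) != len(uniq) * n:
        raise TrajectoryError(
            f"expected {n} particles in each of {len(uniq)} frames, got {len(df)} rows"
        )
    pid = df["particle_id"].to_numpy(dtype=int).reshape(len(uniq), n)
    if not np.array_equal(pid, np.tile(np.arange(n), (len(uniq), 1))):
        raise TrajectoryError("each frame must contain particle ids 0..n-1 exactly once")
    times_all = df["time_ns"].to_numpy(dtype=float).reshape(len(uniq), n)
    if not np.all(times_all == times_all[:, :1]):
        raise TrajectoryError("all rows of one frame must share one time stamp")
    times = times_all[:, 0]
    if np.any(np.diff(times) <= 0):
        raise TrajectoryError("frame times must be strictly increasing")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(len(uniq), n, 3)
    return Trajectory(times=times, coords=coords, topology=topology)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write the trajectory table at fixed precision (time %.6f ns, coords %.4f Å)."""
    f, n = trajectory.n_frames, trajectory.topology.n_particles
    xyz = trajectory.coords.reshape(f * n, 3)
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(f), n),
            "time_ns": [TIME_FMT % t for t in np.repeat(trajectory.times, n)],
            "particle_id": np.tile(np.arange(n), f),
            "x": [COORD_FMT % v for v in xyz[:, 0]],
            "y": [COORD_FMT % v for v in xyz[:, 1]],
            "z": [COORD_FMT % v for v in xyz[:, 2]],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

#: registry: kind name -> (columns, per-column printf format or None)
_SCHEMAS: dict[str, tuple[list[str], dict[str, str]]] = {}
#: record type -> kind name
_KIND_OF_TYPE: dict[type, str] = {}


def register_schema(
    kind: str,
    columns: Sequence[str],
    formats: Mapping[str, str] | None = None,
    record_type: type | None = None,
) -> None:
    """Register a tabular schema for :func:`write_table`."""
    _SCHEMAS[kind] = (list(columns), dict(formats or {}))
    if record_type is not None:
        _KIND_OF_TYPE[record_type] = kind


def _record_to_mapping(rec) -> Mapping:
    if isinstance(rec, Mapping):
        return rec
    if dataclasses.is_dataclass(rec):
        return dataclasses.asdict(rec)
    raise TypeError(f"cannot turn {type(rec).__name__} into a table row")


def write_table(records: Iterable, path: str | Path, kind: str | None = None) -> None:
    """Write result records as a TSV with a registered, deterministic schema.

    ``kind`` may be omitted when the record type was registered; an empty
    record list requires an explicit ``kind``.
    """
    records = list(records)
    if kind is None:
        if not records:
            raise ValueError("empty record list needs an explicit schema kind")
        kind = _KIND_OF_TYPE.get(type(records[0]))
        if kind is None:
            raise ValueError(
                f"no schema registered for record type {type(records[0]).__name__}"
            )
    if kind not in _SCHEMAS:
        raise ValueError(f"unregistered schema kind {kind!r}")
    columns, formats = _SCHEMAS[kind]
    rows = []
    for rec in records:
        m = _record_to_mapping(rec)
        row = []
        for col in columns:
            v = m[col]
            fmt = formats.get(col, COORD_FMT)
            row.append(fmt % v if isinstance(v, float) else str(v))
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a result TSV."""
    return pd.read_csv(path, sep="\t")


def write_adsorption_matrix(
    per_run: Mapping[str, Sequence[float]], path: str | Path
) -> pd.DataFrame:
    """Write a runs × systems adsorbed-percentage matrix with an ``average`` row.

    Percentages are printed as integers (half-up), matching the reporting style
    of per-repetition adsorption summaries; the average row is the half-up
    rounded arithmetic mean of the rounded repetition values.
    """
    from .states import average_over_repetitions, round_half_up

    systems = list(per_run)
    n_rep = {len(v) for v in per_run.values()}
    if len(n_rep) != 1:
        raise ValueError("all systems must have the same number of repetitions")
    reps = n_rep.pop()
    data: dict[str, list[int | str]] = {
        "repetition": [str(i + 1) for i in range(reps)] + ["average"]
    }
    for s in systems:
        vals = [round_half_up(v) for v in per_run[s]]
        data[s] = vals + [average_over_repetitions(vals)]
    df = pd.DataFrame(data)
    df.to_csv(path, sep="\t", index=False)
    return df
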