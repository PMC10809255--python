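"""Constant-velocity pulling (steered-MD / AFM-style) force-trace analysis.

A harmonic spring of constant ``k`` (pN/Å) pulled at constant velocity
produces a sawtooth force trace: the force ramps while the pulled compound is
stuck in a potential well and drops when a barrier is crossed.  Each detected
drop (a *transition*) releases spring potential energy

    dE = ((F₀ + dF)² − F₀²) / (2k) = F₀·dF/k + dF²/(2k)

where ``F₀`` is the force at the end of the transition and ``dF`` the force
change during it.  The binding (desorption or dissociation) energy estimate
ΔE is the sum of all dE.  The algebraic form with F₀ taken at the *peak*
instead is exposed behind the ``f0_convention`` switch
(``'end'``, the default, or ``'peak'``); both describe the same spring-energy
difference across the drop and with the stored (F_end, dF) fields

    'end'  : dE = ((F_end + dF)² − F_end²) / (2k)
    'peak' : dE = (F_peak² − (F_peak − dF)²) / (2k)   with F_peak = F_end + dF

are numerically identical — the switch matters only when energies are
recomputed from externally supplied F₀ values.

Detection is deliberately simple and robust: a centred moving-average smooth,
a noise scale from the median absolute deviation of the detrended trace, and
local maximum → following local minimum pairs whose drop exceeds a threshold
multiple of the noise and is accompanied by the mandatory displacement
increase of at least dF/k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .constants import KCAL_MOL_A_TO_PN_A, PN_A_TO_EV, EV_TO_KCAL_MOL
from .trajio import register_schema

__all__ = [
    "ForceTrace",
    "Transition",
    "convert_spring_constant",
    "detect_transitions",
    "transition_energy",
    "binding_energy",
    "read_force_trace",
    "write_force_trace",
]


@dataclass
class ForceTrace:
    """A pulling trace: times (ps), force (pN), displacement (Å)."""

    times: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    spring_constant: float  # pN/Å
    pulling_velocity: float  # Å/ps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.size == 0:
            raise ValueError("empty force trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be > 0")
        if not (self.times.shape == self.force.shape == self.displacement.shape):
            raise ValueError("time/force/displacement must be aligned")


@dataclass
class Transition:
    """One rupture: force peak, subsequent minimum, drop and released energy."""

    t_peak: float  # ps
    t_end: float  # ps
    F_end: float  # pN, force at the end of the transition (F₀)
    dF: float  # pN, drop magnitude
    dE: float = float("nan")  # eV

    def __post_init__(self) -> None:
        if self.t_peak >= self.t_end:
            raise ValueError("transition must end after its peak")
        if self.dF <= 0:
            raise ValueError("drop magnitude must be > 0")


register_schema(
    "transitions",
    ["t_peak", "t_end", "F_end", "dF", "dE"],
    formats={"t_peak": "%.2f", "t_end": "%.2f", "dE": "%.6f"},
    record_type=Transition,
)


def convert_spring_constant(value_kcal_mol_A: float) -> float:
    """kcal mol⁻¹ Å⁻¹ → pN/Å (4 kcal/(mol·Å) ≈ 278 pN/Å)."""
    if value_kcal_mol_A < 0:
        raise ValueError("spring constant must be >= 0")
    return value_kcal_mol_A * KCAL_MOL_A_TO_PN_A


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    s = pd.Series(x)
    return s.rolling(w, center=True, min_periods=1).mean().to_numpy()


def detect_transitions(
    trace: ForceTrace,
    smoothing_window: float = 50.0,
    drop_threshold: float = 3.0,
    displacement_slack: float = 0.8,
) -> list[Transition]:
    """Detect force-drop transitions (without energies).

    ``smoothing_window`` is the centred moving-average window in ps; the noise
    scale is 1.4826 × MAD of the detrended trace; a local-maximum → next
    local-minimum pair qualifies when its drop exceeds
    ``drop_threshold × noise`` and the displacement grows by at least
    ``displacement_slack × dF/k`` across the drop (the slack absorbs
    smoothing-induced blur of the step edges).  Minimum spacing between
    detected extrema equals the smoothing window.
    """
    dt = float(np.median(np.diff(trace.times)))
    w = max(1, int(round(smoothing_window / dt)))
    if len(trace.times) < w:
        raise ValueError("trace shorter than the smoothing window")
    smooth = _moving_average(trace.force, w)
    resid = trace.force - smooth
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    floor = max(drop_threshold * sigma, 1e-9)

    peaks, _ = find_peaks(smooth, distance=w, prominence=floor)
    if peaks.size == 0:
        return []
    # short window for sharper amplitude readout at the located extrema
    # (raw samples when the trace carries no measurable noise)
    ws = 1 if sigma < 1e-12 else max(1, w // 10)
    sharp = _moving_average(trace.force, ws)
    k = trace.spring_constant

    out: list[Transition] = []
    bounds = list(peaks[1:]) + [len(smooth) - 1]
    prev_end = 0
    for p, nxt in zip(peaks, bounds):
        if nxt <= p + 1:
            continue
        m = p + 1 + int(np.argmin(smooth[p + 1 : nxt + 1]))
        lo = max(prev_end, p - w)
        p_ref = lo + int(np.argmax(sharp[lo : min(m, p + w) + 1]))
        m_lo = max(p_ref + 1, m - w)
        m_ref = m_lo + int(np.argmin(sharp[m_lo : min(nxt, m + w) + 1]))
        f_peak = float(sharp[p_ref])
        f_end = float(sharp[m_ref])
        d_f = f_peak - f_end
        if d_f < floor:
            continue
        disp_gain = float(trace.displacement[m_ref] - trace.displacement[p_ref])
        if disp_gain < displacement_slack * d_f / k:
            continue
        out.append(
            Transition(
                t_peak=float(trace.times[p_ref]),
                t_end=float(trace.times[m_ref]),
                F_end=f_end,
                dF=d_f,
            )
        )
        prev_end = m_ref
    return out


def transition_energy(
    transition: Transition | None = None,
    k: float = None,
    F0: float | None = None,
    dF: float | None = None,
    f0_convention: str = "end",
) -> float:
    """Spring energy (eV) released by one transition.

    Either pass a :class:`Transition` (its stored fields are used with the
    'end' convention) or explicit ``F0``/``dF`` with the convention stating
    whether F₀ is the force at the end (default) or at the peak of the
    transition.
    """
    if k is None or k <= 0:
        raise ValueError("spring constant must be > 0")
    if transition is not None:
        F0, dF = transition.F_end, transition.dF
        f0_convention = "end"
    if F0 is None or dF is None:
        raise ValueError("need a transition or explicit F0 and dF")
    if dF < 0:
        raise ValueError("drop magnitude must be >= 0")
    if f0_convention == "end":
        e_pn_a = ((F0 + dF) ** 2 - F0**2) / (2.0 * k)
    elif f0_convention == "peak":
        e_pn_a = (F0**2 - (F0 - dF) ** 2) / (2.0 * k)
    else:
        raise ValueError(f"unknown f0 convention {f0_convention!r}")
    return e_pn_a * PN_A_TO_EV


def binding_energy(
    transitions: list[Transition], k: float, attach_energies: bool = True
) -> float:
    """ΔE (eV): sum of per-transition spring energies; order-independent."""
    total = 0.0
    for tr in transitions:
        de = transition_energy(tr, k=k)
        if attach_energies:
            tr.dE = de
        total += de
    return total


def format_energy(delta_e_ev: float) -> str:
    """Render ΔE in eV, kcal/mol and pN·Å for reports."""
    return (
        f"dE = {delta_e_ev:.4f} eV = {delta_e_ev * EV_TO_KCAL_MOL:.2f} kcal/mol"
        f" = {delta_e_ev / PN_A_TO_EV:.1f} pN*A"
    )


def read_force_trace(
    path: str | Path, spring_constant: float, pulling_velocity: float = 0.01
) -> ForceTrace:
    """Read a ``time_ps\tforce_pN\tdisplacement_A`` TSV."""
    df = pd.read_csv(path, sep="\t")
    required = ["time_ps", "force_pN", "displacement_A"]
    if list(df.columns) != required:
        raise ValueError(f"trace table must have columns {required}")
    return ForceTrace(
        times=df["time_ps"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        displacement=df["displacement_A"].to_numpy(float),
        spring_constant=spring_constant,
        pulling_velocity=pulling_velocity,
    )


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_ps": ["%.3f" % t for t in trace.times],
            "force_pN": ["%.4f" % f for f in trace.force],
            "displacement_A": ["%.4f" % d for d in trace.displacement],
        }
    )
    df.to_csv(path, sep="\t", index=False)
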