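"""Transient response characteristics: duration, integrated response, strength.

For an output species with transient concentration profile q(t) on
[0, t_max], let t0 be the time at which q converges to zero (t_max if it
never does) and define the moment integrals T_k = int_0^t0 t^k q(t) dt.
The default ("heinrich") characteristics are the established moment-based
signaling measures:

    I   = T0                      integrated response
    tau = T1 / T0                 signaling time (mean of q as a density)
    D   = sqrt(T2/T0 - tau^2)     duration (central width of the transient)
    S   = I / (2 D)               signal strength (area per width)

An alternative ("mean_rate") convention with D = t0 and S = I/D is kept
behind the same switch.  Analyses operate on the natural logarithm of the
selected characteristic, which tames outliers under large rate
perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateResponseError

RESPONSE_KINDS = ("log_duration", "log_integrated", "log_strength")
RESPONSE_DEFS = ("heinrich", "mean_rate")


@dataclass(frozen=True)
class ResponseSpec:
    """Which characteristic of which species to use as the system response."""

    species: str
    kind: str = "log_duration"
    t_max: float = 21600.0          # 6 h observation window, seconds
    eps: float = 1e-3               # zero-convergence threshold, fraction of max
    definitions: str = "heinrich"
    n_points: int = 1201

    def __post_init__(self):
        if self.kind not in RESPONSE_KINDS:
            raise ValueError(f"kind must be one of {RESPONSE_KINDS}")
        if self.definitions not in RESPONSE_DEFS:
            raise ValueError(f"definitions must be one of {RESPONSE_DEFS}")
        if not (self.t_max > 0):
            raise ValueError("t_max must be positive")
        if not (0 < self.eps < 1):
            raise ValueError("eps must lie in (0, 1)")


def convergence_time(traj, species, eps=1e-3):
    """Earliest grid time after the global maximum at which q stays below
    eps * max(q) through the end of the grid; the final time if never.

    Raises :class:`DegenerateResponseError` for an identically-zero profile.
    """
    q = np.asarray(traj.species(species), dtype=float)
    qmax = q.max()
    if qmax <= 0:
        raise DegenerateResponseError(f"species {species!r} is identically zero")
    imax = int(q.argmax())
    thr = eps * qmax
    below = q < thr
    # stays-below condition: suffix AND
    stays = np.logical_and.accumulate(below[::-1])[::-1]
    candidates = np.nonzero(stays & (np.arange(q.size) > imax))[0]
    if candidates.size == 0:
        return float(traj.times[-1])
    return float(traj.times[candidates[0]])


def response_moments(traj, species, t0):
    """Moment integrals (T0, T1, T2), T_k = int_0^t0 t^k q dt, by composite
    trapezoid on the stored grid (grid points with t <= t0)."""
    t = np.asarray(traj.times, dtype=float)
    q = np.asarray(traj.species(species), dtype=float)
    if not np.all(np.isfinite(q)):
        raise DegenerateResponseError(f"non-finite concentrations for {species!r}")
    mask = t <= t0 + 1e-12 * max(t0, 1.0)
    t, q = t[mask], q[mask]
    T0 = float(np.trapezoid(q, t))
    T1 = float(np.trapezoid(t * q, t))
    T2 = float(np.trapezoid(t * t * q, t))
    return T0, T1, T2


def duration_integrated_strength(traj, species=None, spec=None):
    """Compute (D, I, S) for a trajectory under a :class:`ResponseSpec`."""
    if spec is None:
        spec = ResponseSpec(species=species)
    name = species if species is not None else spec.species
    t0 = convergence_time(traj, name, spec.eps)
    T0, T1, T2 = response_moments(traj, name, t0)
    if T0 <= 0:
        raise DegenerateResponseError("zero integrated response")
    I = T0
    if spec.definitions == "heinrich":
        tau = T1 / T0
        var = T2 / T0 - tau * tau
        if var <= 0:
            raise DegenerateResponseError("zero-width transient")
        D = float(np.sqrt(var))
        S = I / (2.0 * D)
    else:  # mean_rate
        D = t0
        if D <= 0:
            raise DegenerateResponseError("zero duration")
        S = I / D
    return D, I, S


def log_response(traj, spec):
    """Natural log of the selected characteristic (ln D, ln I, or ln S)."""
    D, I, S = duration_integrated_strength(traj, spec=spec)
    value = {"log_duration": D, "log_integrated": I, "log_strength": S}[spec.kind]
    if value <= 0:
        raise DegenerateResponseError(f"nonpositive {spec.kind[4:]}: {value}")
    return float(np.log(value))
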