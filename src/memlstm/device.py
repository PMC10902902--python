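"""Single metal-oxide-metal memristive device model.

The device carries a total current density that mixes an ohmic branch
(conduction through the formed filament, ``j_lin = u / rho``) with a
Poole-Frenkel branch (field-assisted transport over trap barriers in the
unfilamented oxide, ``j_nonlin = u * exp(B*u - E_b)``), weighted by the
internal state ``w`` in [0, 1]:

    j = w * j_lin + (1 - w) * j_nonlin

``w`` evolves by voltage-driven oxygen-ion migration over an effective
barrier ``E_m`` that is lowered by the applied field.  Above the positive
threshold ``u_set`` the device potentiates, below the negative threshold
``u_reset`` it depresses, and between the thresholds the state is frozen:

    dw/dt = +A * exp(-(E_m - alpha*|u|)) * (1 - (2w - 1)^(2p)),  u >= u_set
    dw/dt = 0,                                        u_reset < u < u_set
    dw/dt = -A * exp(-(E_m - alpha*|u|)) * (1 - (2w - 1)^(2p)),  u <= u_reset

The window term ``1 - (2w - 1)^(2p)`` pins the state at the interval
boundaries; the integrator therefore clamps ``w`` to
``[EPS_W, 1 - EPS_W]`` so the device stays switchable.

Barrier energies ``E_b`` and ``E_m`` are dimensionless (expressed in units
of the thermal energy as they appear inside the exponent); current is in
arbitrary consistent units since the device area is never fixed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, InvalidInputError

#: Clamp margin keeping the state off the window-function fixed points.
EPS_W = 1e-3


@dataclass(frozen=True)
class MemristorParams:
    """Physical constants of one device.

    Numeric defaults are a documented reference set chosen to produce
    bistable switching and a pinched hysteresis loop; the originating
    laboratory films were characterized but their fitted constants were
    never published, so every value is overridable.
    """

    A: float = 1e6          # rate prefactor, 1/s
    B: float = 2.0          # field coefficient of nonlinear conduction, 1/V
    alpha: float = 5.0      # field lowering of the migration barrier, 1/V
    rho: float = 1.0        # resistivity of the ohmic path
    E_b: float = 10.0       # conduction barrier (units of kT)
    E_m: float = 20.0       # migration barrier (units of kT)
    p: int = 5              # window exponent, positive integer
    u_set: float = 1.0      # positive switching threshold, V
    u_reset: float = -1.0   # negative switching threshold, V

    def __post_init__(self) -> None:
        for name in ("A", "B", "alpha", "rho", "E_b", "E_m"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (isinstance(self.p, (int, np.integer)) and self.p >= 1):
            raise ConfigError("p must be a positive integer")
        if not (self.u_reset < 0 < self.u_set):
            raise ConfigError("thresholds must satisfy u_reset < 0 < u_set")


@dataclass
class MemristorState:
    """Internal state fraction of one device, clamped off {0, 1}."""

    w: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.w) or not (EPS_W <= self.w <= 1 - EPS_W):
            raise InvalidInputError(
                f"state w={self.w} outside [{EPS_W}, {1 - EPS_W}]"
            )


@dataclass
class SweepTrace:
    """Recorded (t, u, j, w) samples of one characterization sweep."""

    times: np.ndarray
    voltages: np.ndarray
    currents: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.voltages) == len(self.currents) == len(self.states) == n):
            raise InvalidInputError("sweep trace sequences must share a length")

    def to_csv(self, path: str | Path) -> None:
        """Write the trace as ``time,voltage,current,state`` CSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time", "voltage", "current", "state"])
            for row in zip(self.times, self.voltages, self.currents, self.states):
                writer.writerow([repr(float(v)) for v in row])

    def loop_area(self) -> float:
        """Unsigned area enclosed by the (u, j) curve (shoelace formula)."""
        u, j = np.asarray(self.voltages), np.asarray(self.currents)
        return float(abs(np.sum(u * np.roll(j, -1) - np.roll(u, -1) * j)) / 2.0)


def current_density(u, w, params: MemristorParams):
    """Total current density ``w*(u/rho) + (1-w)*u*exp(B*u - E_b)``.

    Both branches are proportional to ``u``, so the I-V curve is pinched
    at the origin regardless of state.  Accepts scalars or arrays.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(w))):
        raise InvalidInputError("u and w must be finite")
    if np.any(w < 0) or np.any(w > 1):
        raise InvalidInputError("w must lie in [0, 1]")
    j = w * (u / params.rho) + (1.0 - w) * u * np.exp(params.B * u - params.E_b)
    return j if j.ndim else float(j)


def state_derivative(u, w, params: MemristorParams):
    """State velocity dw/dt of the threshold-gated migration model.

    Zero in the dead zone ``u_reset < u < u_set``; outside it the rate is
    ``±A * exp(-(E_m - alpha*|u|)) * (1 - (2w-1)^(2p))`` with the sign of
    the driving polarity.  The window factor vanishes at w in {0, 1}.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(w))):
        raise InvalidInputError("u and w must be finite")
    if np.any(w < 0) or np.any(w > 1):
        raise InvalidInputError("w must lie in [0, 1]")
    rate = params.A * np.exp(-(params.E_m - params.alpha * np.abs(u)))
    window = 1.0 - (2.0 * w - 1.0) ** (2 * params.p)
    sign = np.where(u >= params.u_set, 1.0, np.where(u <= params.u_reset, -1.0, 0.0))
    dw = sign * rate * window
    return dw if dw.ndim else float(dw)


def integrate_state(
    voltages: np.ndarray,
    dt: float,
    w0: float,
    params: MemristorParams,
) -> np.ndarray:
    """Explicit-Euler trajectory of ``w`` under a sampled voltage waveform.

    Returns one state per waveform sample; ``states[k]`` is the state at
    which ``voltages[k]`` is applied (so ``states[0] == w0``).  The state
    is clamped to ``[EPS_W, 1-EPS_W]`` after every step.
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    voltages = np.asarray(voltages, dtype=float)
    if not (EPS_W <= w0 <= 1 - EPS_W):
        raise InvalidInputError(f"w0 must lie in [{EPS_W}, {1 - EPS_W}]")
    states = np.empty_like(voltages)
    w = float(w0)
    lo, hi = EPS_W, 1.0 - EPS_W
    for k, u in enumerate(voltages):
        states[k] = w
        w = w + dt * state_derivative(u, w, params)
        w = lo if w < lo else hi if w > hi else w
    return states


def iv_sweep(
    amplitude: float,
    period: float,
    cycles: int,
    params: MemristorParams,
    w0: float = 0.5,
    dt: float | None = None,
) -> SweepTrace:
    """Drive a symmetric triangular voltage and record (u, j, w).

    One cycle is 0 -> +amplitude -> 0 -> -amplitude -> 0 over ``period``
    seconds.  ``dt`` defaults to ``period / 1e4``.
    """
    if amplitude <= 0:
        raise InvalidInputError("amplitude must be positive")
    if cycles < 1:
        raise InvalidInputError("cycles must be >= 1")
    if dt is None:
        dt = period / 1e4
    if dt <= 0 or period <= 0:
        raise ConfigError("period and dt must be positive")
    t = np.arange(0.0, cycles * period, dt)
    phase = (t % period) / period
    # piecewise-linear triangle: up, down through zero, back up
    u = amplitude * np.where(
        phase < 0.25,
        4.0 * phase,
        np.where(phase < 0.75, 2.0 - 4.0 * phase, 4.0 * phase - 4.0),
    )
    u[np.abs(u) < amplitude * 1e-12] = 0.0  # exact zero at crossings
    states = integrate_state(u, dt, w0, params)
    currents = current_density(u, states, params)
    return SweepTrace(times=t, voltages=u, currents=currents, states=states)
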