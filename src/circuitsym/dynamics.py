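"""Linear feedforward + recurrent rate model built from circuit blocks.

The model is the standard linear filter of computational neuroscience:

    tau dv/dt = -v + M v + W u

with feedforward matrix ``W`` (hub input ``u`` into the block) and
recurrent matrix ``M`` (the block's internal circulant).  When ``M`` is
circulant its Fourier eigenmodes evolve independently with exponential
rate ``(lambda_k - 1) / tau``: modes with ``lambda_k < 1`` decay, a mode
with ``lambda_k > 1`` grows (the linear model does not saturate), and the
gap between the extreme eigenvalues supports oscillatory exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circulant import CirculantProfile, circulant_eigen

__all__ = ["LinearFilterModel", "steady_state", "simulate", "mode_projection"]


@dataclass(frozen=True)
class LinearFilterModel:
    tau: float
    W: np.ndarray = field(repr=False)       # output_dim x input_dim
    M_rec: np.ndarray = field(repr=False)   # output_dim x output_dim
    u: np.ndarray = field(repr=False)       # input activity (constant drive)
    recurrent_profile: CirculantProfile | None = None

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        M = np.atleast_2d(np.asarray(self.M_rec, dtype=float))
        u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if M.shape[0] != M.shape[1]:
            raise ValueError("M_rec must be square")
        if W.shape[0] != M.shape[0] or W.shape[1] != u.shape[0]:
            raise ValueError(
                f"inconsistent dimensions: W {W.shape}, M {M.shape}, u {u.shape}"
            )
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "M_rec", M)
        object.__setattr__(self, "u", u)

    @property
    def dim(self) -> int:
        return self.M_rec.shape[0]

    def drive(self) -> np.ndarray:
        return self.W @ self.u

    def mode_rates(self) -> np.ndarray:
        """Per-eigenmode exponential rates (lambda - 1) / tau."""
        lam = np.linalg.eigvals(self.M_rec)
        lam = np.real_if_close(lam)
        return (np.sort(lam.real) - 1) / self.tau


def steady_state(m: LinearFilterModel) -> np.ndarray:
    """Fixed point v* = (I - M)^{-1} W u; requires 1 not an eigenvalue of M."""
    I = np.eye(m.dim)
    A = I - m.M_rec
    if np.abs(np.linalg.det(A)) < 1e-12:
        lam = np.real_if_close(np.linalg.eigvals(m.M_rec))
        unit = lam[np.isclose(lam, 1.0)]
        raise np.linalg.LinAlgError(
            f"I - M_rec is singular: M_rec has eigenvalue(s) {unit} at 1; "
            "no steady state for the linear model"
        )
    return np.linalg.solve(A, m.drive())


def simulate(m: LinearFilterModel, v0, dt: float, T: float) -> dict:
    """Fixed-step 4th-order Runge-Kutta integration of the linear ODE.

    Returns ``{"t": times, "v": trajectory}`` with one row per step,
    including t=0.  Guards ``dt < tau / 2`` (explicit-scheme stability).
    """
    if dt >= m.tau / 2:
        raise ValueError(f"dt={dt} must be < tau/2 = {m.tau / 2}")
    if T <= 0:
        raise ValueError("T must be positive")
    v = np.asarray(v0, dtype=float).copy()
    if v.shape != (m.dim,):
        raise ValueError(f"v0 must have shape ({m.dim},)")
    drive = m.drive()
    A = (m.M_rec - np.eye(m.dim)) / m.tau
    b = drive / m.tau

    def f(x: np.ndarray) -> np.ndarray:
        return A @ x + b

    steps = int(round(T / dt))
    ts = [0.0]
    traj = [v.copy()]
    for k in range(steps):
        k1 = f(v)
        k2 = f(v + dt / 2 * k1)
        k3 = f(v + dt / 2 * k2)
        k4 = f(v + dt * k3)
        v = v + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ts.append((k + 1) * dt)
        traj.append(v.copy())
    return {"t": np.asarray(ts), "v": np.asarray(traj)}


def mode_projection(m: LinearFilterModel, trajectory: dict) -> dict:
    """Project a trajectory onto the Fourier eigenbasis of a circulant M.

    Requires ``m.recurrent_profile`` (an exact circulant).  Returns
    ``{"t", "amplitudes", "eigenvalues", "rates"}``: one amplitude time
    series per mode and the exponential rate (lambda - 1)/tau of each.
    """
    if m.recurrent_profile is None or m.recurrent_profile.deviation != 0:
        raise ValueError("mode projection requires an exact circulant M_rec "
                         "(set recurrent_profile)")
    eig = circulant_eigen(m.recurrent_profile)
    V = eig.eigenvectors
    if np.iscomplexobj(V):
        raise ValueError("mode projection implemented for the real "
                         "(symmetric first row) basis")
    amps = trajectory["v"] @ V          # (steps, modes)
    lam = np.asarray(eig.eigenvalues, dtype=float)
    return {
        "t": trajectory["t"],
        "amplitudes": amps,
        "eigenvalues": lam,
        "rates": (lam - 1) / m.tau,
    }
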