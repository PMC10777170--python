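"""Cubic-spline trajectory estimates between the tracker planes.

Each proton's transverse trajectory (t and v separately) is modeled as a
cubic Hermite interpolant on the normalized depth s = (u - u_front) /
(u_rear - u_front), constrained to the measured tracker positions and
directions. The endpoint tangents are the measured slopes times the tracker
separation, optionally rescaled by factors (lambda0, lambda1); lambda = 1
gives the plain Hermite spline, while the optimized factors of the cubic
spline path literature can be supplied through the configuration.

Depth is parameterized geometrically (mm along the beam axis), not in
water-equivalent units; for water-dominated objects the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montecarlo import PhaseSpace

__all__ = ["PathEstimate", "fit_spline", "lateral_at_depth"]


@dataclass
class PathEstimate:
    """Vectorized cubic Hermite paths for a set of events.

    ``coeffs_t``/``coeffs_v`` hold the polynomial coefficients (a, b, c, d)
    of t(s) = ((a s + b) s + c) s + d per event, with s the normalized depth.
    """

    coeffs_t: np.ndarray  # shape (4, n)
    coeffs_v: np.ndarray  # shape (4, n)
    u_front: float
    u_rear: float
    lambda0: float = 1.0
    lambda1: float = 1.0

    def __len__(self) -> int:
        return self.coeffs_t.shape[1]


def _hermite_coeffs(p0, m0, p1, m1) -> np.ndarray:
    """Power-basis coefficients of the cubic Hermite interpolant on [0, 1].

    h(s) = h00 p0 + h10 m0 + h01 p1 + h11 m1 expanded in powers of s.
    """
    a = 2.0 * p0 + m0 - 2.0 * p1 + m1
    b = -3.0 * p0 - 2.0 * m0 + 3.0 * p1 - m1
    c = m0
    d = p0
    return np.stack([a, b, c, d])


def fit_spline(rec: PhaseSpace, lambda0: float = 1.0,
               lambda1: float = 1.0) -> PathEstimate:
    """Fit per-event cubic Hermite splines through the tracker measurements.

    The spline passes exactly through the measured entry/exit positions with
    endpoint slopes equal to the measured slopes scaled by lambda0/lambda1.
    """
    if rec.u_rear <= rec.u_front:
        raise ValueError("u_rear must exceed u_front")
    length = rec.u_rear - rec.u_front
    for c in ("t0", "v0", "st0", "sv0", "t1", "v1", "st1", "sv1"):
        if not np.all(np.isfinite(getattr(rec, c))):
            raise ValueError(f"non-finite values in {c}")
    ct = _hermite_coeffs(rec.t0, rec.st0 * length * lambda0,
                         rec.t1, rec.st1 * length * lambda1)
    cv = _hermite_coeffs(rec.v0, rec.sv0 * length * lambda0,
                         rec.v1, rec.sv1 * length * lambda1)
    return PathEstimate(ct.astype(np.float64), cv.astype(np.float64),
                        rec.u_front, rec.u_rear, lambda0, lambda1)


def lateral_at_depth(path: PathEstimate, u: float) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the estimated lateral displacement (t, v) of every event at
    depth ``u`` (mm, within the tracker span)."""
    if not (path.u_front <= u <= path.u_rear):
        raise ValueError(
            f"depth {u} outside tracker span [{path.u_front}, {path.u_rear}]")
    s = (u - path.u_front) / (path.u_rear - path.u_front)
    a, b, c, d = path.coeffs_t
    t = ((a * s + b) * s + c) * s + d
    a, b, c, d = path.coeffs_v
    v = ((a * s + b) * s + c) * s + d
    return t, v
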