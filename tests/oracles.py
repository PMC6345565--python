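"""Independent oracles used by the test suite.

The explicit-Euler integrator here deliberately shares no code with the
production solver: it is a plain fixed-step loop over the same mass-action
rate laws, used to cross-check the adaptive integration.
"""

from __future__ import annotations

import math

DEFAULT_STAT = (2.0, 2.0, 2.0, 2.0)


def euler_bivalent(
    k1: float,
    k_off: float,
    k2: float,
    aa: float,
    t_end: float,
    dt: float = 1e-3,
    stat=DEFAULT_STAT,
    y0=(1.0, 0.0, 0.0, 0.0),
    sample_every: float | None = None,
):
    """Fixed-step explicit Euler integration of the homobivalent scheme.

    Returns a list of (t, U, G, R, B) samples every ``sample_every``
    minutes (default: only the endpoint).
    """
    s1, s2, s3, s4 = stat
    U, G, R, B = y0
    n = int(round(t_end / dt))
    record = int(round((sample_every or t_end) / dt))
    out = []
    c1 = s1 * k1 * aa
    c2 = s3 * k1 * aa
    for i in range(1, n + 1):
        v1 = c1 * U
        vg = k_off * G
        v3 = k2 * G
        vr = s2 * k_off * R
        v2 = c2 * G
        vb = s4 * k_off * B
        U += dt * (-v1 + vg)
        G += dt * (v1 - vg - v3 + vr - v2 + vb)
        R += dt * (v3 - vr)
        B += dt * (v2 - vb)
        if i % record == 0:
            out.append((i * dt, U, G, R, B))
    return out


def langmuir_occupancy(aa: float, kd: float) -> float:
    """Closed-form single-site equilibrium isotherm."""
    return aa / (aa + kd)


def pseudo_first_order(aa, k1, k_off, t):
    """Closed-form single-site association time course."""
    k_obs = k1 * aa + k_off
    return langmuir_occupancy(aa, k_off / k1) * (1.0 - math.exp(-k_obs * t))
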