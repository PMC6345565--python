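"""Mass-action kinetics of a homobivalent ligand binding paired membrane sites.

The model describes a dimeric ligand ``aa`` (two identical binding domains)
interacting with a pair of identical, proximate target sites ``AA`` embedded
in a membrane.  A target pair can be in one of four occupancy states:

* ``U`` — free pair, ``AA``
* ``G`` — one ligand bound through one domain (``AAaa``/``aaAA`` pooled),
  the "green" complex
* ``R`` — one ligand bound through both domains, ``aAAa``, the "red"
  bivalent complex
* ``B`` — two ligands each bound through one domain, ``aaAAaa``, the "blue"
  ternary complex

All transitions are reversible mass-action steps.  The only non-standard
rate is the intramolecular ring closure ``G -> R``: once one domain is
bound, the free domain of the same molecule sees its target site at a high
local concentration ``[L]`` (one molecule in a half-sphere of the
inter-domain reach radius ``r``), reduced by a dimensionless penalty ``f``
for steric strain, restricted rotation and entropic cost.  Its composite
first-order rate constant is ``k2 = k1 * [L] / f``.

Macroscopic rate laws carry statistical factors counting the microscopic
realizations of each transition.  The shipped default gives every step two
realizations (two free sites on ``U``, two arms on an incoming free ligand,
two breakable bonds in ``R``, two dissociable ligands in ``B``) except ring
closure, which pairs one tethered arm with one specific free site:

    dU/dt = -s1*k1*[aa]*U + k_off*G
    dG/dt =  s1*k1*[aa]*U - k_off*G - k2*G + s2*k_off*R
             - s3*k1*[aa]*G + s4*k_off*B
    dR/dt =  k2*G - s2*k_off*R
    dB/dt =  s3*k1*[aa]*G - s4*k_off*B

with ``(s1, s2, s3, s4) = (2, 2, 2, 2)``.

Bulk ligand is assumed in large excess: ``[aa]`` is held constant during
incubation and is exactly zero during washout.  Units are minutes and molar
internally; the reach radius is accepted in ångström.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import (
    CrossoverNotFoundError,
    InvalidParameterError,
    InvalidStateError,
    SolverError,
)

AVOGADRO = 6.02214076e23  # mol^-1
_ANGSTROM_TO_DM = 1e-9  # 1 Å = 1e-10 m = 1e-9 dm

#: Default statistical factors (s1, s2, s3, s4); see module docstring.
DEFAULT_STAT_FACTORS = (2.0, 2.0, 2.0, 2.0)

CONSERVATION_TOL = 1e-8
NEGATIVITY_TOL = 1e-10


def local_concentration(r_angstrom: float) -> float:
    """Effective molar concentration of one tethered molecule.

    Computed as one molecule within a half-sphere of radius ``r``:
    ``[L] = 1 / (N_A * (2/3) * pi * r^3)`` with ``r`` in decimetres so the
    volume is in litres.

    Parameters
    ----------
    r_angstrom : float
        Inter-domain reach radius in ångström; must be > 0.

    Returns
    -------
    float
        Local concentration in molar.
    """
    if not r_angstrom > 0:
        raise InvalidParameterError(f"reach radius must be > 0 Å, got {r_angstrom}")
    r_dm = r_angstrom * _ANGSTROM_TO_DM
    half_sphere_litres = (2.0 / 3.0) * math.pi * r_dm**3
    return 1.0 / (AVOGADRO * half_sphere_litres)


def composite_k2(k1: float, r_angstrom: float, f: float) -> float:
    """Composite first-order rebinding (ring closure) rate constant.

    ``k2 = k1 * [L](r) / f`` in min^-1; ``k1`` in M^-1 min^-1, ``f``
    dimensionless >= numerically positive.
    """
    if not k1 > 0:
        raise InvalidParameterError(f"k1 must be > 0, got {k1}")
    if not f > 0:
        raise InvalidParameterError(f"penalty factor f must be > 0, got {f}")
    return k1 * local_concentration(r_angstrom) / f


def intrinsic_kd(k1: float, k_off: float) -> float:
    """Intrinsic single-domain dissociation constant ``k_off / k1`` in molar."""
    if not k1 > 0:
        raise InvalidParameterError(f"k1 must be > 0, got {k1}")
    if k_off < 0:
        raise InvalidParameterError(f"k_off must be >= 0, got {k_off}")
    return k_off / k1


@dataclass(frozen=True)
class RateParameters:
    """Intrinsic and composite rate constants of the bivalent scheme.

    Parameters
    ----------
    k1 : float
        Intrinsic bimolecular association rate constant, M^-1 min^-1.
    k_off : float
        Intrinsic dissociation rate constant k_-1, min^-1.
    r : float
        Inter-domain reach radius, ångström.
    f : float
        Dimensionless penalty factor (>= 1) on the ring-closure rate.
    k2_override : float, optional
        Explicit composite rate constant overriding the derived
        ``k1*[L]/f``; a >1 % mismatch with the derived value warns.
    """

    k1: float
    k_off: float
    r: float = 180.0
    f: float = 185.0
    k2_override: float | None = None

    def __post_init__(self):
        if not self.k1 > 0:
            raise InvalidParameterError(f"k1 must be > 0, got {self.k1}")
        if self.k_off < 0:
            raise InvalidParameterError(f"k_off must be >= 0, got {self.k_off}")
        if not self.r > 0:
            raise InvalidParameterError(f"r must be > 0 Å, got {self.r}")
        if self.f < 1:
            raise InvalidParameterError(f"penalty factor f must be >= 1, got {self.f}")
        if self.k2_override is not None:
            if not self.k2_override >= 0:
                raise InvalidParameterError(
                    f"explicit k2 must be >= 0, got {self.k2_override}"
                )
            derived = composite_k2(self.k1, self.r, self.f)
            if derived > 0 and abs(self.k2_override - derived) / derived > 0.01:
                warnings.warn(
                    f"explicit k2={self.k2_override:g} min^-1 differs from derived "
                    f"k1*[L]/f={derived:g} min^-1 by more than 1%",
                    stacklevel=2,
                )

    @property
    def L(self) -> float:
        """Local concentration of the tethered free domain, molar."""
        return local_concentration(self.r)

    @property
    def k2(self) -> float:
        """Composite ring-closure rate constant, min^-1."""
        if self.k2_override is not None:
            return self.k2_override
        return composite_k2(self.k1, self.r, self.f)

    @property
    def kd_int(self) -> float:
        """Intrinsic dissociation constant k_off/k1, molar."""
        return intrinsic_kd(self.k1, self.k_off)


#: Rate parameters of the reference simulation scenario (PICK1-like dimer):
#: k1 and k_off from in-solution single-domain binding, r from the SAXS
#: inter-domain distance, f chosen so that k2 = 0.136 min^-1.
REFERENCE_PARAMS = RateParameters(k1=1.85e5, k_off=0.0085, r=180.0, f=185.0)


@dataclass(frozen=True)
class BulkLigandSchedule:
    """Constant-bulk incubation, optionally followed by a zero-ligand washout.

    Bulk ligand is in large excess: ``[aa]`` stays at ``incubation_conc``
    (molar) for ``t_incubation`` minutes, then drops to exactly zero for
    ``t_washout`` minutes if ``washout`` is set.
    """

    incubation_conc: float
    t_incubation: float
    washout: bool = False
    t_washout: float = 0.0

    def __post_init__(self):
        if self.incubation_conc < 0:
            raise InvalidParameterError(
                f"bulk concentration must be >= 0, got {self.incubation_conc}"
            )
        if self.t_incubation < 0 or self.t_washout < 0:
            raise InvalidParameterError("durations must be >= 0")
        if self.washout and self.t_washout <= 0:
            raise InvalidParameterError("washout requires t_washout > 0")

    @property
    def total_time(self) -> float:
        return self.t_incubation + (self.t_washout if self.washout else 0.0)

    def bulk_at(self, t: float) -> float:
        """Bulk ligand concentration at time t (minutes from start)."""
        if self.washout and t > self.t_incubation:
            return 0.0
        return self.incubation_conc


class SpeciesState(NamedTuple):
    """Fractional occupancy of the four target-pair states (sums to 1)."""

    U: float
    G: float
    R: float
    B: float

    def validate(self, tol: float = CONSERVATION_TOL) -> "SpeciesState":
        arr = np.asarray(self)
        if np.any(arr < -NEGATIVITY_TOL):
            raise InvalidStateError(f"negative species abundance in {self}")
        if abs(float(arr.sum()) - 1.0) > tol:
            raise InvalidStateError(
                f"target-pair conservation violated: sum={float(arr.sum())!r}"
            )
        return self


ALL_FREE = SpeciesState(1.0, 0.0, 0.0, 0.0)


def derivatives(
    state: Sequence[float],
    params: RateParameters,
    aa: float,
    stat_factors: Sequence[float] = DEFAULT_STAT_FACTORS,
) -> tuple[float, float, float, float]:
    """Mass-action time derivatives (dU, dG, dR, dB) in min^-1.

    ``aa`` is the instantaneous bulk ligand concentration (molar).  The four
    rates sum to zero exactly: each flux enters one state and leaves
    another.  Fluxes: V1 = s1*k1*aa*U (association to G), V2 = s3*k1*aa*G
    (association to B), V3 = k2*G (ring closure to R).
    """
    U, G, R, B = state
    if aa < 0:
        raise InvalidParameterError(f"bulk concentration must be >= 0, got {aa}")
    if min(U, G, R, B) < -NEGATIVITY_TOL:
        raise InvalidStateError(f"negative species abundance in state {state}")
    s1, s2, s3, s4 = stat_factors
    v1 = s1 * params.k1 * aa * U
    v_g_off = params.k_off * G
    v3 = params.k2 * G
    v_r_open = s2 * params.k_off * R
    v2 = s3 * params.k1 * aa * G
    v_b_off = s4 * params.k_off * B
    dU = -v1 + v_g_off
    dG = v1 - v_g_off - v3 + v_r_open - v2 + v_b_off
    dR = v3 - v_r_open
    dB = v2 - v_b_off
    return (dU, dG, dR, dB)


def _signal(G, R, B, mode: str):
    if mode == "ligands":
        return G + R + 2.0 * B
    if mode == "complexes":
        return G + R + B
    raise InvalidParameterError(f"unknown signal mode {mode!r}")


@dataclass
class TimeCourse:
    """Sampled trajectory of the four species plus a bound-ligand readout.

    ``signal`` defaults to the number of bound ligand molecules per target
    pair, ``G + R + 2B`` (mode ``"ligands"``); mode ``"complexes"`` counts
    occupied pairs ``G + R + B`` instead.
    """

    times: np.ndarray
    U: np.ndarray
    G: np.ndarray
    R: np.ndarray
    B: np.ndarray
    signal: np.ndarray
    signal_mode: str = "ligands"

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState(self.U[i], self.G[i], self.R[i], self.B[i])

    @property
    def final_state(self) -> SpeciesState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "U": self.U,
                "G": self.G,
                "R": self.R,
                "B": self.B,
                "signal": self.signal,
            }
        )


@dataclass
class SaturationSimResult:
    """Endpoint species and total signal across a bulk-concentration grid."""

    concentrations: np.ndarray  # molar
    U: np.ndarray
    G: np.ndarray
    R: np.ndarray
    B: np.ndarray
    total_signal: np.ndarray
    t_incubation: float
    signal_mode: str = "ligands"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "conc_nM": self.concentrations * 1e9,
                "U": self.U,
                "G": self.G,
                "R": self.R,
                "B": self.B,
                "total_signal": self.total_signal,
            }
        )


def _integrate_phase(rhs, y0, t_span, t_eval, rtol, atol):
    if t_span[1] <= t_span[0]:
        return np.asarray(t_eval), np.tile(np.asarray(y0)[:, None], (1, len(t_eval)))
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"ODE integration failed (rtol={rtol}, atol={atol}): {sol.message}"
        )
    return sol.t, sol.y


def simulate_time_course(
    params: RateParameters,
    schedule: BulkLigandSchedule,
    sample_times: Sequence[float] | None = None,
    *,
    initial_state: Sequence[float] = ALL_FREE,
    stat_factors: Sequence[float] = DEFAULT_STAT_FACTORS,
    signal_mode: str = "ligands",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the bivalent scheme over an incubation (+ optional washout).

    ``sample_times`` are minutes from the start of incubation and must fall
    within the schedule; default is 200 evenly spaced samples.  The bulk
    concentration is piecewise constant, so each phase is integrated
    separately with the adaptive stiff-capable LSODA method and the washout
    phase chains from the incubation endpoint.

    Conservation (U+G+R+B = 1) and non-negativity are verified on every
    output sample.
    """
    if sample_times is None:
        sample_times = np.linspace(0.0, schedule.total_time, 201)
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise InvalidParameterError("sample_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("sample_times must be strictly increasing")
    if times[0] < 0 or times[-1] > schedule.total_time + 1e-9:
        raise InvalidParameterError(
            f"sample_times must lie within [0, {schedule.total_time}] min"
        )
    y0 = np.asarray(initial_state, dtype=float)
    SpeciesState(*y0).validate()

    def make_rhs(aa):
        def rhs(t, y):
            return derivatives(y, params, aa, stat_factors)

        return rhs

    t_inc = schedule.t_incubation
    out_t = []
    out_y = []

    inc_mask = times <= t_inc
    inc_times = times[inc_mask]
    # Incubation phase: integrate to t_inc regardless, to seed the washout.
    eval_inc = inc_times if len(inc_times) else np.array([t_inc])
    if len(eval_inc) == 0 or eval_inc[-1] < t_inc:
        eval_full = np.append(eval_inc, t_inc)
    else:
        eval_full = eval_inc
    if eval_full[0] > 0.0:
        eval_full = np.insert(eval_full, 0, 0.0)
    tt, yy = _integrate_phase(
        make_rhs(schedule.incubation_conc), y0, (0.0, t_inc), eval_full, rtol, atol
    ) if t_inc > 0 else (eval_full, np.tile(y0[:, None], (1, len(eval_full))))
    y_end = yy[:, -1]
    keep = np.isin(tt, inc_times)
    out_t.append(tt[keep])
    out_y.append(yy[:, keep])

    if schedule.washout:
        wash_times = times[~inc_mask] - t_inc
        if len(wash_times):
            eval_w = wash_times
            if eval_w[0] > 0.0:
                eval_w = np.insert(eval_w, 0, 0.0)
                tt, yy = _integrate_phase(
                    make_rhs(0.0), y_end, (0.0, wash_times[-1]), eval_w, rtol, atol
                )
                tt, yy = tt[1:], yy[:, 1:]
            else:
                tt, yy = _integrate_phase(
                    make_rhs(0.0), y_end, (0.0, wash_times[-1]), eval_w, rtol, atol
                )
            out_t.append(tt + t_inc)
            out_y.append(yy)

    t_all = np.concatenate(out_t)
    y_all = np.concatenate(out_y, axis=1)
    U, G, R, B = y_all

    if np.any(y_all < -NEGATIVITY_TOL):
        raise SolverError(
            f"negative concentration excursion beyond {NEGATIVITY_TOL:g} "
            f"(min={y_all.min():g}); tighten rtol/atol"
        )
    drift = np.abs(y_all.sum(axis=0) - 1.0)
    if drift.max() > CONSERVATION_TOL:
        raise SolverError(
            f"target-pair conservation drift {drift.max():g} exceeds "
            f"{CONSERVATION_TOL:g}; tighten rtol/atol"
        )
    return TimeCourse(
        times=t_all,
        U=U,
        G=G,
        R=R,
        B=B,
        signal=_signal(G, R, B, signal_mode),
        signal_mode=signal_mode,
    )


def simulate_saturation_curve(
    params: RateParameters,
    conc_grid: Sequence[float],
    t_incubation: float = 120.0,
    *,
    stat_factors: Sequence[float] = DEFAULT_STAT_FACTORS,
    signal_mode: str = "ligands",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SaturationSimResult:
    """Endpoint occupancy after ``t_incubation`` min across a concentration grid.

    The grid must contain at least 6 strictly positive concentrations
    (molar) spanning at least two decades, mirroring an experimental
    saturation series.
    """
    grid = np.asarray(conc_grid, dtype=float)
    if len(grid) < 6:
        raise InvalidParameterError("conc_grid needs >= 6 points")
    if np.any(grid <= 0):
        raise InvalidParameterError("conc_grid must be strictly positive")
    if grid.max() / grid.min() < 100.0:
        raise InvalidParameterError("conc_grid must span >= 2 decades")
    if t_incubation < 0:
        raise InvalidParameterError("t_incubation must be >= 0")

    ends = np.empty((4, len(grid)))
    for i, aa in enumerate(grid):
        if t_incubation == 0:
            ends[:, i] = ALL_FREE
            continue
        tc = simulate_time_course(
            params,
            BulkLigandSchedule(aa, t_incubation),
            sample_times=[t_incubation],
            stat_factors=stat_factors,
            signal_mode=signal_mode,
            rtol=rtol,
            atol=atol,
        )
        ends[:, i] = tc.final_state
    U, G, R, B = ends
    return SaturationSimResult(
        concentrations=grid,
        U=U,
        G=G,
        R=R,
        B=B,
        total_signal=_signal(G, R, B, signal_mode),
        t_incubation=t_incubation,
        signal_mode=signal_mode,
    )


def _endpoint_state(params, aa, t_incubation, stat_factors, rtol, atol):
    if aa == 0 or t_incubation == 0:
        return ALL_FREE
    tc = simulate_time_course(
        params,
        BulkLigandSchedule(aa, t_incubation),
        sample_times=[t_incubation],
        stat_factors=stat_factors,
        rtol=rtol,
        atol=atol,
    )
    return tc.final_state


def find_species_crossover(
    params: RateParameters,
    t_incubation: float = 120.0,
    search_range: tuple[float, float] = (1e-9, 1e-6),
    *,
    stat_factors: Sequence[float] = DEFAULT_STAT_FACTORS,
    rel_tol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> float:
    """Bulk concentration (molar) where endpoint B equals endpoint R.

    Below the crossover the bivalent "red" complex dominates the ternary
    "blue" complex at the incubation endpoint; above it, the ternary wins.
    Located by bisection on log10-concentration to ``rel_tol`` relative
    accuracy.  Raises :class:`CrossoverNotFoundError` when B - R does not
    change sign over ``search_range``.
    """
    lo, hi = search_range
    if not (0 < lo < hi):
        raise InvalidParameterError(f"invalid search range {search_range}")

    def gap(log_aa):
        st = _endpoint_state(params, 10.0**log_aa, t_incubation, stat_factors, rtol, atol)
        return st.B - st.R

    g_lo, g_hi = gap(math.log10(lo)), gap(math.log10(hi))
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if g_lo * g_hi > 0:
        raise CrossoverNotFoundError(
            f"endpoint B-R does not change sign on [{lo:g}, {hi:g}] M "
            f"(B-R = {g_lo:g} at lower edge, {g_hi:g} at upper edge)"
        )
    log_root = brentq(
        gap, math.log10(lo), math.log10(hi), xtol=rel_tol / math.log(10.0)
    )
    return 10.0**log_root


def simulate_monovalent(
    params: RateParameters,
    schedule: BulkLigandSchedule,
    sample_times: Sequence[float] | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Single-site control: one functional binding domain, no R or B states.

    Models the heterodimer analogue in which one of the two ligand domains
    is non-functional.  Each target site binds independently with on-rate
    ``k1*[aa]`` and off-rate ``k_off``; occupancy is reported as the bound
    fraction, which equals the signal.  The long-time limit is the single
    -site isotherm ``aa / (aa + kd_int)``.
    """
    if sample_times is None:
        sample_times = np.linspace(0.0, schedule.total_time, 201)
    times = np.asarray(sample_times, dtype=float)
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise InvalidParameterError("sample_times must be strictly increasing and >= 0")
    if times[-1] > schedule.total_time + 1e-9:
        raise InvalidParameterError("sample_times exceed schedule duration")

    def rhs_factory(aa):
        def rhs(t, y):
            return [params.k1 * aa * (1.0 - y[0]) - params.k_off * y[0]]

        return rhs

    t_inc = schedule.t_incubation
    inc_mask = times <= t_inc
    eval_inc = times[inc_mask]
    eval_full = eval_inc if len(eval_inc) and eval_inc[-1] >= t_inc else np.append(eval_inc, t_inc)
    if len(eval_full) == 0 or eval_full[0] > 0:
        eval_full = np.insert(eval_full, 0, 0.0)
    tt, yy = _integrate_phase(
        rhs_factory(schedule.incubation_conc), [0.0], (0.0, t_inc), eval_full, rtol, atol
    ) if t_inc > 0 else (eval_full, np.zeros((1, len(eval_full))))
    occ_end = yy[0, -1]
    keep = np.isin(tt, eval_inc)
    out_t = [tt[keep]]
    out_occ = [yy[0, keep]]
    if schedule.washout:
        wash_times = times[~inc_mask] - t_inc
        if len(wash_times):
            eval_w = wash_times if wash_times[0] == 0 else np.insert(wash_times, 0, 0.0)
            tt, yy = _integrate_phase(
                rhs_factory(0.0), [occ_end], (0.0, wash_times[-1]), eval_w, rtol, atol
            )
            keep = np.isin(tt, wash_times)
            out_t.append(tt[keep] + t_inc)
            out_occ.append(yy[0, keep])
    t_all = np.concatenate(out_t)
    occ = np.concatenate(out_occ)
    zero = np.zeros_like(occ)
    return TimeCourse(
        times=t_all,
        U=1.0 - occ,
        G=occ,
        R=zero,
        B=zero,
        signal=occ.copy(),
        signal_mode="ligands",
    )
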