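"""Empirical nonlinear fits for binding data.

Covers the four fit families used around membrane-sheet binding assays:

* sigmoidal saturation binding (four-parameter log-logistic, ascending),
  reporting the half-maximal concentration as an apparent Kd*
* competition binding (descending log-logistic), reporting Ki*/IC50
* mono-exponential association to a plateau
* one- and two-phase exponential dissociation with corrected-AIC model
  comparison

Concentration tables are in nM (the assay interface unit), times in
minutes.  Fits are unweighted least squares on individual replicate points;
standard errors are asymptotic (from the Jacobian at the optimum).
Initialization is deterministic: the EC50 starts at the measured
concentration whose signal is nearest the half-range, exponential rates
start from log-linear regression on the early/late thirds of the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from lmfit import Model

from .errors import DataError, FitConvergenceError

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# model functions


def dose_response_model(conc, top, bottom, log_ec50, hill):
    """Four-parameter log-logistic dose-response curve (ascending for hill>0).

    ``bottom + (top - bottom) / (1 + 10**((log_ec50 - log10(conc)) * hill))``;
    at ``conc == 0`` the limit ``bottom`` is returned.  ``conc`` and
    ``10**log_ec50`` share whatever unit the caller uses (nM throughout this
    package).
    """
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log10(conc)
    val = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))
    if val.ndim == 0:
        return float(val)
    return val


def competition_model(conc, top, bottom, log_ic50, hill):
    """Descending log-logistic: signal falls from top to bottom with conc."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log10(conc)
    val = bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - log_ic50) * hill))
    if val.ndim == 0:
        return float(val)
    return val


def association_model(t, plateau, rate):
    """Mono-exponential rise to plateau: ``plateau * (1 - exp(-rate*t))``."""
    t = np.asarray(t, dtype=float)
    return plateau * (1.0 - np.exp(-rate * t))


def one_phase_decay(t, amplitude, rate, plateau=0.0):
    t = np.asarray(t, dtype=float)
    return plateau + amplitude * np.exp(-rate * t)


def two_phase_decay(t, amplitude, fraction_fast, rate_fast, rate_slow, plateau=0.0):
    t = np.asarray(t, dtype=float)
    return plateau + amplitude * (
        fraction_fast * np.exp(-rate_fast * t)
        + (1.0 - fraction_fast) * np.exp(-rate_slow * t)
    )


# ---------------------------------------------------------------------------
# result containers


@dataclass
class DoseResponseFit:
    """Parameters of a sigmoidal dose-response fit (concentrations in nM)."""

    top: float
    bottom: float
    log_ec50: float
    hill: float
    stderr: dict = field(default_factory=dict)
    orientation: Literal["ascending", "descending"] = "ascending"
    rss: float = float("nan")
    n_points: int = 0

    @property
    def ec50(self) -> float:
        """Half-maximal concentration, nM (Kd*, Ki* or IC50 by assay)."""
        return 10.0**self.log_ec50

    @property
    def bmax_percent(self) -> float:
        """Fitted span (top - bottom); in percent when signals are normalized."""
        return self.top - self.bottom

    def predict(self, conc):
        f = dose_response_model if self.orientation == "ascending" else competition_model
        return f(conc, self.top, self.bottom, self.log_ec50, self.hill)

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "log_ec50": self.log_ec50,
            "ec50_nM": self.ec50,
            "hill": self.hill,
            "orientation": self.orientation,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_points": self.n_points,
        }


@dataclass
class AssociationFit:
    """Mono-exponential association parameters."""

    plateau: float
    rate: float  # min^-1
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    @property
    def t_half(self) -> float:
        """Time to half-maximal binding, min."""
        return LN2 / self.rate

    def to_dict(self) -> dict:
        return {
            "plateau": self.plateau,
            "rate_per_min": self.rate,
            "t_half_min": self.t_half,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_points": self.n_points,
        }


@dataclass
class DecayFit:
    """One- or two-phase exponential dissociation parameters."""

    mode: Literal["one-phase", "two-phase"]
    amplitude: float
    rates: tuple  # (rate,) or (rate_fast, rate_slow), min^-1
    fraction_fast: float  # 1.0 in one-phase mode
    plateau: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    aicc: float = float("nan")
    n_points: int = 0
    degenerate: bool = False

    @property
    def half_lives(self) -> tuple:
        """Half-life per phase, min (fast first in two-phase mode)."""
        return tuple(LN2 / k for k in self.rates)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "amplitude": self.amplitude,
            "rates_per_min": list(self.rates),
            "half_lives_min": list(self.half_lives),
            "fraction_fast": self.fraction_fast,
            "plateau": self.plateau,
            "stderr": self.stderr,
            "rss": self.rss,
            "aicc": self.aicc,
            "degenerate": self.degenerate,
        }


@dataclass
class DecayComparison:
    """Verdict of one- vs two-phase dissociation model comparison."""

    one_phase: DecayFit
    two_phase: DecayFit
    delta_aicc: float  # AICc(one) - AICc(two); positive favors two-phase
    preferred: Literal["one-phase", "two-phase"]

    def to_dict(self) -> dict:
        return {
            "preferred": self.preferred,
            "delta_aicc": self.delta_aicc,
            "one_phase": self.one_phase.to_dict(),
            "two_phase": self.two_phase.to_dict(),
        }


# ---------------------------------------------------------------------------
# helpers


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    ``n * ln(rss/n) + 2k + 2k(k+1)/(n-k-1)`` with ``k`` the number of free
    parameters.  Requires ``n >= k + 2``.
    """
    if n < k + 2:
        raise DataError(f"AICc undefined for n={n}, k={k} (need n >= k+2)")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _columns(df: pd.DataFrame, x_candidates: tuple, y: str = "signal"):
    for cand in x_candidates:
        if cand in df.columns:
            if y not in df.columns:
                raise DataError(f"input table is missing column {y!r}")
            sub = df[[cand, y]].dropna()
            return sub[cand].to_numpy(float), sub[y].to_numpy(float)
    raise DataError(
        f"input table is missing a {x_candidates[0]!r} column (columns: {list(df.columns)})"
    )


def _check_fit(result, what: str):
    if not result.success:
        raise FitConvergenceError(
            f"{what} fit did not converge: {result.message}",
            diagnostics={"nfev": result.nfev, "message": result.message},
        )


def _stderr(result) -> dict:
    out = {}
    for name, par in result.params.items():
        if par.vary:
            out[name] = par.stderr if par.stderr is not None else float("nan")
    return out


# ---------------------------------------------------------------------------
# fitting operations


def _prepare_dose_response(df, descending: bool):
    conc, sig = _columns(df, ("conc_nM", "conc"))
    if np.any(conc < 0):
        raise DataError("concentrations must be >= 0")
    if not np.all(np.isfinite(sig)):
        raise DataError("signals must be finite")
    pos = conc > 0
    n_distinct = len(np.unique(conc))
    if n_distinct < 5:
        raise DataError(f"need >= 5 distinct concentrations, got {n_distinct}")
    if np.ptp(sig) == 0:
        raise DataError("signal has zero range; sigmoid is underdetermined")
    # EC50 start: measured concentration whose mean signal is nearest half-range
    half = (sig.max() + sig.min()) / 2.0
    cpos, spos = conc[pos], sig[pos]
    means = pd.Series(spos).groupby(cpos).mean()
    start_ec50 = float(means.index[np.argmin(np.abs(means.to_numpy() - half))])
    return conc, sig, start_ec50


def fit_dose_response(
    df: pd.DataFrame,
    variable_slope: bool = False,
    *,
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Fit an ascending saturation binding curve; EC50 reported as Kd* (nM).

    ``df`` needs columns ``conc_nM`` and ``signal`` (replicates as separate
    rows).  ``variable_slope`` frees the Hill slope (otherwise pinned at 1).
    ``fix_bottom`` pins the lower asymptote (commonly 0 for normalized
    data).
    """
    conc, sig, start_ec50 = _prepare_dose_response(df, descending=False)
    model = Model(dose_response_model)
    params = model.make_params(
        top=float(sig.max()),
        bottom=float(sig.min()) if fix_bottom is None else fix_bottom,
        log_ec50=math.log10(start_ec50),
        hill=1.0,
    )
    params["hill"].vary = variable_slope
    if variable_slope:
        params["hill"].set(min=0.05, max=10.0)
    if fix_bottom is not None:
        params["bottom"].vary = False
    result = model.fit(sig, params, conc=conc)
    _check_fit(result, "dose-response")
    p = result.params
    if p["top"].value < p["bottom"].value:
        raise FitConvergenceError(
            "dose-response fit inverted (top < bottom); data may be descending"
        )
    return DoseResponseFit(
        top=p["top"].value,
        bottom=p["bottom"].value,
        log_ec50=p["log_ec50"].value,
        hill=p["hill"].value,
        stderr=_stderr(result),
        orientation="ascending",
        rss=float(np.sum(result.residual**2)),
        n_points=len(sig),
    )


def fit_competition(
    df: pd.DataFrame,
    variable_slope: bool = False,
    *,
    fix_bottom: float | None = None,
    tracer_conc_nM: float | None = None,
) -> DoseResponseFit:
    """Fit a descending competition curve; midpoint reported as Ki*/IC50 (nM).

    ``tracer_conc_nM`` is carried as metadata only (the apparent-Kd
    convention folds tracer occupancy into the reported Ki*).
    """
    conc, sig, start_ic50 = _prepare_dose_response(df, descending=True)
    model = Model(competition_model)
    params = model.make_params(
        top=float(sig.max()),
        bottom=float(sig.min()) if fix_bottom is None else fix_bottom,
        log_ic50=math.log10(start_ic50),
        hill=1.0,
    )
    params["hill"].vary = variable_slope
    if fix_bottom is not None:
        params["bottom"].vary = False
    result = model.fit(sig, params, conc=conc)
    _check_fit(result, "competition")
    p = result.params
    span = p["top"].value - p["bottom"].value
    if span <= 0 or span < 0.05 * max(np.ptp(sig), np.finfo(float).tiny):
        raise FitConvergenceError("competition fit found no descending span")
    fit = DoseResponseFit(
        top=p["top"].value,
        bottom=p["bottom"].value,
        log_ec50=p["log_ic50"].value,
        hill=p["hill"].value,
        stderr=_stderr(result),
        orientation="descending",
        rss=float(np.sum(result.residual**2)),
        n_points=len(sig),
    )
    fit.tracer_conc_nM = tracer_conc_nM
    return fit


def fit_association(df: pd.DataFrame) -> AssociationFit:
    """Fit a mono-exponential rise to plateau; reports t1/2 = ln2/rate (min)."""
    t, sig = _columns(df, ("time_min", "time"))
    if np.any(t < 0):
        raise DataError("times must be >= 0")
    if len(t) < 3:
        raise DataError("need >= 3 time points")
    if np.ptp(sig) == 0 or sig.max() <= 0:
        raise DataError("signal has no rise; association is underdetermined")
    plateau0 = float(sig.max())
    # rate start: first time the signal passes half its final level
    above = t[(sig >= plateau0 / 2.0) & (t > 0)]
    rate0 = LN2 / float(above.min()) if len(above) else 1.0 / max(t.max(), 1.0)
    model = Model(association_model)
    params = model.make_params(plateau=plateau0, rate=rate0)
    params["rate"].set(min=1e-8)
    result = model.fit(sig, params, t=t)
    _check_fit(result, "association")
    return AssociationFit(
        plateau=result.params["plateau"].value,
        rate=result.params["rate"].value,
        stderr=_stderr(result),
        rss=float(np.sum(result.residual**2)),
        n_points=len(sig),
    )


def _decay_rate_starts(t, sig):
    """Deterministic starts from log-linear regression on early/late thirds."""

    def slope(tt, ss):
        mask = ss > 0
        if mask.sum() < 2:
            return None
        k = -np.polyfit(tt[mask], np.log(ss[mask]), 1)[0]
        return k if k > 0 else None

    order = np.argsort(t)
    t, sig = t[order], sig[order]
    n = len(t)
    k_early = slope(t[: max(2, n // 3)], sig[: max(2, n // 3)])
    k_late = slope(t[-max(2, n // 3) :], sig[-max(2, n // 3) :])
    k_all = slope(t, sig) or 1.0 / max(t.max(), 1.0)
    k_fast = k_early or 5.0 * k_all
    k_slow = k_late or 0.2 * k_all
    if k_fast <= k_slow:
        k_fast = 5.0 * k_slow
    return k_all, k_fast, k_slow


def fit_decay(
    df: pd.DataFrame,
    mode: Literal["one-phase", "two-phase"] = "one-phase",
    *,
    plateau: float | None = 0.0,
) -> DecayFit:
    """Fit an exponential dissociation trace (columns ``time_min``, ``signal``).

    ``plateau`` is fixed at 0 by default (normalized washout data); pass
    ``None`` to float it.  Two-phase mode orders the recovered rates so the
    fast phase comes first and flags near-degenerate solutions (equal rates
    or a vanishing phase amplitude) instead of failing.
    """
    t, sig = _columns(df, ("time_min", "time"))
    if t.min() > 0:
        raise DataError("decay trace must include time 0")
    if mode not in ("one-phase", "two-phase"):
        raise DataError(f"unknown decay mode {mode!r}")
    n_min = 4 if mode == "one-phase" else 6
    if len(t) < n_min:
        raise DataError(f"{mode} decay fit needs >= {n_min} points, got {len(t)}")
    if np.ptp(sig) == 0:
        raise DataError("signal is constant; no decay to fit")
    k_all, k_fast0, k_slow0 = _decay_rate_starts(t, sig)
    amp0 = float(sig[np.argmin(t)])

    if mode == "one-phase":
        model = Model(one_phase_decay)
        params = model.make_params(amplitude=amp0, rate=k_all, plateau=0.0)
        params["rate"].set(min=1e-10)
        n_free = 2
    else:
        model = Model(two_phase_decay)
        params = model.make_params(
            amplitude=amp0,
            fraction_fast=0.5,
            rate_fast=k_fast0,
            rate_slow=k_slow0,
            plateau=0.0,
        )
        params["fraction_fast"].set(min=0.0, max=1.0)
        params["rate_fast"].set(min=1e-10)
        params["rate_slow"].set(min=1e-10)
        n_free = 4
    if plateau is None:
        params["plateau"].vary = True
        n_free += 1
    else:
        params["plateau"].set(value=plateau, vary=False)
    result = model.fit(sig, params, t=t)
    _check_fit(result, f"{mode} decay")
    p = result.params
    rss = float(np.sum(result.residual**2))
    if mode == "one-phase":
        rates = (p["rate"].value,)
        frac = 1.0
        degenerate = False
        stderr = _stderr(result)
    else:
        kf, ks = p["rate_fast"].value, p["rate_slow"].value
        frac = p["fraction_fast"].value
        stderr = _stderr(result)
        if kf < ks:  # reorder so the fast phase is first
            kf, ks = ks, kf
            frac = 1.0 - frac
            stderr["rate_fast"], stderr["rate_slow"] = (
                stderr.get("rate_slow"),
                stderr.get("rate_fast"),
            )
        rates = (kf, ks)
        degenerate = (kf / ks < 1.05) or frac < 1e-3 or frac > 1.0 - 1e-3
    return DecayFit(
        mode=mode,
        amplitude=p["amplitude"].value,
        rates=rates,
        fraction_fast=frac,
        plateau=p["plateau"].value,
        stderr=stderr,
        rss=rss,
        aicc=aicc(rss, len(sig), n_free),
        n_points=len(sig),
        degenerate=degenerate,
    )


def compare_decay_models(
    df: pd.DataFrame, *, plateau: float | None = 0.0, threshold: float = 2.0
) -> DecayComparison:
    """One- vs two-phase dissociation verdict by corrected-AIC difference.

    The two-phase model is preferred when it improves AICc by more than
    ``threshold`` (default 2); ties and small gains go to the simpler model.
    If the two-phase fit fails, the one-phase fit is returned as preferred
    with the partial result attached.
    """
    one = fit_decay(df, "one-phase", plateau=plateau)
    try:
        two = fit_decay(df, "two-phase", plateau=plateau)
    except (FitConvergenceError, DataError):
        return DecayComparison(
            one_phase=one,
            two_phase=None,
            delta_aicc=float("-inf"),
            preferred="one-phase",
        )
    delta = one.aicc - two.aicc
    preferred = "two-phase" if delta > threshold else "one-phase"
    return DecayComparison(
        one_phase=one, two_phase=two, delta_aicc=delta, preferred=preferred
    )


def normalize_to_top(df: pd.DataFrame, by: str | None = "experiment", **fit_kwargs) -> pd.DataFrame:
    """Normalize each independent experiment to its own fitted top (percent).

    Mirrors the pooling convention for combining saturation curves: each
    group in column ``by`` (or the whole table when absent) is fitted
    separately and its signals divided by the fitted top, so pooled data are
    on a common 0-100 % scale.
    """
    def _norm(g):
        fit = fit_dose_response(g, **fit_kwargs)
        out = g.copy()
        out["signal"] = 100.0 * g["signal"] / fit.top
        return out

    if by is None or by not in df.columns:
        return _norm(df)
    parts = [_norm(g) for _, g in df.groupby(by, sort=True)]
    return pd.concat(parts, ignore_index=True)
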