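"""Fluorescence polarization (FP) binding assay models and fits.

FP reports the rotational mobility of a fluorescent tracer peptide:
``FP = (IV - g*IH) / (IV + g*IH)`` where IV and IH are the emission
intensities in the vertical and horizontal planes and g is the instrument
g-factor.  Binding to a much larger protein slows tumbling and raises FP,
so a titration of protein against a fixed trace amount of labeled peptide
traces out a single-site isotherm between the free-tracer value FP_f and
the bound value FP_b:

    FP(Rt) = FP_f + (FP_b - FP_f) * [Rt] / (kd + [Rt])

with [Rt] the total protein concentration (tracer depletion neglected,
valid for tracer << protein).  Competition by an unlabeled ligand at
concentration x with inhibition constant ki shifts the apparent affinity:

    FP(x)  = FP_f + (FP_b - FP_f) * [Rt] / (kd * (1 + x/ki) + [Rt])

FP units are opaque here (plate readers report mP); FP_f and FP_b absorb
the scale.  Concentrations are molar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model

from .errors import DataError, FitConvergenceError, InvalidParameterError, UndefinedValueError


def polarization(iv, ih, g: float = 1.0):
    """Fluorescence polarization ``(IV - g*IH) / (IV + g*IH)``, in [-1, 1].

    Accepts scalars or arrays; raises when the total intensity
    ``IV + g*IH`` is zero (undefined polarization).
    """
    iv = np.asarray(iv, dtype=float)
    ih = np.asarray(ih, dtype=float)
    if np.any(iv < 0) or np.any(ih < 0):
        raise InvalidParameterError("emission intensities must be >= 0")
    total = iv + g * ih
    if np.any(total == 0):
        raise UndefinedValueError("IV + g*IH = 0: polarization undefined")
    val = (iv - g * ih) / total
    return float(val) if val.ndim == 0 else val


def fp_saturation_model(rt, fp_free, fp_bound, kd):
    """Single-site FP isotherm in total protein concentration ``rt`` (molar)."""
    rt = np.asarray(rt, dtype=float)
    val = fp_free + (fp_bound - fp_free) * rt / (kd + rt)
    return float(val) if val.ndim == 0 else val


def fp_competition_model(x, fp_free, fp_bound, rt, kd, ki):
    """FP competition curve in competitor concentration ``x`` (molar).

    Reduces to :func:`fp_saturation_model` at ``x = 0`` and decays to
    ``fp_free`` as ``x -> inf``.
    """
    x = np.asarray(x, dtype=float)
    val = fp_free + (fp_bound - fp_free) * rt / (kd * (1.0 + x / ki) + rt)
    return float(val) if val.ndim == 0 else val


@dataclass
class FPSaturationFit:
    """Result of an FP saturation fit (kd in molar, FP in input units)."""

    kd: float
    fp_free: float
    fp_bound: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "kd_M": self.kd,
            "fp_free": self.fp_free,
            "fp_bound": self.fp_bound,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_points": self.n_points,
        }


@dataclass
class FPCompetitionFit:
    """Result of an FP competition fit (ki in molar)."""

    ki: float
    fp_free: float
    fp_bound: float
    rt: float
    kd: float
    stderr: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "ki_M": self.ki,
            "fp_free": self.fp_free,
            "fp_bound": self.fp_bound,
            "rt_M": self.rt,
            "kd_M": self.kd,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_points": self.n_points,
        }


def _fp_table(df: pd.DataFrame, xcol_candidates, g: float = 1.0):
    for xcol in xcol_candidates:
        if xcol in df.columns:
            break
    else:
        raise DataError(
            f"FP table needs a {xcol_candidates[0]!r} column (columns: {list(df.columns)})"
        )
    if "fp" in df.columns:
        fp = df["fp"].to_numpy(float)
    elif {"iv", "ih"}.issubset(df.columns):
        fp = polarization(df["iv"].to_numpy(float), df["ih"].to_numpy(float), g)
    else:
        raise DataError("FP table needs either an 'fp' column or 'iv' and 'ih' columns")
    x = df[xcol].to_numpy(float)
    if np.any(x < 0):
        raise DataError("concentrations must be >= 0")
    return x, fp


def fit_fp_saturation(df: pd.DataFrame, *, g: float = 1.0) -> FPSaturationFit:
    """Fit the FP saturation isotherm; ``df`` has ``conc_M`` and ``fp``
    (or ``iv``/``ih``) columns, protein concentration in molar."""
    rt, fp = _fp_table(df, ("conc_M", "rt_M", "conc"), g)
    if len(np.unique(rt)) < 5:
        raise DataError("need >= 5 distinct protein concentrations")
    if np.ptp(fp) == 0:
        raise DataError("flat FP data; isotherm is underdetermined")
    pos = rt > 0
    half = (fp.min() + fp.max()) / 2.0
    kd0 = float(rt[pos][np.argmin(np.abs(fp[pos] - half))])
    model = Model(fp_saturation_model)
    params = model.make_params(fp_free=float(fp.min()), fp_bound=float(fp.max()), kd=kd0)
    params["kd"].set(min=np.finfo(float).tiny)
    result = model.fit(fp, params, rt=rt)
    if not result.success:
        raise FitConvergenceError(f"FP saturation fit failed: {result.message}")
    p = result.params
    return FPSaturationFit(
        kd=p["kd"].value,
        fp_free=p["fp_free"].value,
        fp_bound=p["fp_bound"].value,
        stderr={k: (v.stderr if v.stderr is not None else float("nan"))
                for k, v in p.items() if v.vary},
        rss=float(np.sum(result.residual**2)),
        n_points=len(fp),
    )


def fit_fp_competition(
    df: pd.DataFrame, rt: float, kd: float, *, g: float = 1.0
) -> FPCompetitionFit:
    """Fit ki from an FP competition titration at fixed protein ``rt``.

    ``kd`` is the apparent tracer dissociation constant from a prior
    saturation fit and is held fixed, as is ``rt`` (both molar).
    """
    if kd is None or not kd > 0:
        raise InvalidParameterError("apparent kd from a saturation fit is required (> 0)")
    if not rt > 0:
        raise InvalidParameterError("rt must be > 0")
    x, fp = _fp_table(df, ("conc_M", "x_M", "conc"), g)
    if len(np.unique(x)) < 5:
        raise DataError("need >= 5 distinct competitor concentrations")
    if np.ptp(fp) == 0:
        raise DataError("flat FP data; competition is underdetermined")
    pos = x > 0
    half = (fp.min() + fp.max()) / 2.0
    x_half = float(x[pos][np.argmin(np.abs(fp[pos] - half))])
    # invert the midpoint relation x_mid = ki * (1 + rt/kd) for the start value
    ki0 = max(x_half / (1.0 + rt / kd), np.finfo(float).tiny)
    model = Model(fp_competition_model)
    params = model.make_params(
        fp_free=float(fp.min()), fp_bound=float(fp.max()), rt=rt, kd=kd, ki=ki0
    )
    params["rt"].vary = False
    params["kd"].vary = False
    params["ki"].set(min=np.finfo(float).tiny)
    result = model.fit(fp, params, x=x)
    if not result.success:
        raise FitConvergenceError(f"FP competition fit failed: {result.message}")
    p = result.params
    return FPCompetitionFit(
        ki=p["ki"].value,
        fp_free=p["fp_free"].value,
        fp_bound=p["fp_bound"].value,
        rt=rt,
        kd=kd,
        stderr={k: (v.stderr if v.stderr is not None else float("nan"))
                for k, v in p.items() if v.vary},
        rss=float(np.sum(result.residual**2)),
        n_points=len(fp),
    )
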