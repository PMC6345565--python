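"""Synthetic data generators with known ground truth.

Every input class the pipeline consumes can be generated here with stated
truth parameters, a stated Gaussian noise model and a seed, so all stages
are testable end to end without external data.  Defaults mirror the
membrane-sheet study conditions: saturation series of 8 log-spaced
concentrations over 1-1000 nM in triplicate with apparent Kd* = 47 nM and
Bmax = 100 %, dissociation sampled to 600 min with half-lives 21/373 min
(two-phase) or 431 min (one-phase), FP titrations with kd = 9 uM and
ki = 2.1 uM, and ROI tables with planted saturated/dim outliers.

Noise is Gaussian and proportional to the noise-free signal by default
(sd = noise * |signal|), matching the multiplicative scatter of microscopy
ratio data; ``noise_model="absolute"`` uses a constant sd instead.  The
default noise level is 5 %.  Identical spec + seed reproduce outputs
bit-identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fits, fp, kinetics
from .errors import InvalidParameterError

DEFAULT_NOISE = 0.05
DEFAULT_CONC_GRID_NM = np.logspace(0, 3, 8)  # 1 .. 1000 nM
#: Dissociation sampling grid: every 30 min to 600 min (washout tables).
WASHOUT_TIMES_MIN = np.arange(0.0, 601.0, 30.0)
#: Decay-fit sampling grid: denser early sampling to resolve a fast phase.
DECAY_TIMES_MIN = np.array(
    [0, 5, 10, 15, 20, 25, 30, 40, 50, 60, 80, 100, 120,
     150, 180, 240, 300, 360, 420, 480, 540, 600], dtype=float
)


def _rng(seed):
    if seed is None:
        raise InvalidParameterError("a seed is required for reproducible generation")
    return np.random.default_rng(seed)


def _add_noise(rng, y, noise, noise_model):
    if noise < 0:
        raise InvalidParameterError(f"noise sd must be >= 0, got {noise}")
    if noise == 0:
        return np.asarray(y, dtype=float)
    y = np.asarray(y, dtype=float)
    if noise_model == "proportional":
        sd = noise * np.abs(y)
    elif noise_model == "absolute":
        sd = np.full_like(y, noise)
    else:
        raise InvalidParameterError(f"unknown noise model {noise_model!r}")
    return y + sd * rng.standard_normal(y.shape)


def gen_saturation(
    *,
    ec50_nM: float = 47.0,
    top: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
    conc_nM=DEFAULT_CONC_GRID_NM,
    n_replicates: int = 3,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Saturation dose-response table (columns conc_nM, replicate, signal).

    Truth defaults are the wild-type apparent membrane-sheet affinity
    (Kd* = 47 nM, Bmax = 100 %).  Returns (table, truth dict).
    """
    if ec50_nM <= 0:
        raise InvalidParameterError("ec50 truth must be > 0")
    rng = _rng(seed)
    conc = np.asarray(conc_nM, dtype=float)
    conc_rep = np.repeat(conc, n_replicates)
    clean = fits.dose_response_model(conc_rep, top, bottom, np.log10(ec50_nM), hill)
    df = pd.DataFrame(
        {
            "conc_nM": conc_rep,
            "replicate": np.tile(np.arange(1, n_replicates + 1), len(conc)),
            "signal": _add_noise(rng, clean, noise, noise_model),
        }
    )
    truth = {
        "ec50_nM": ec50_nM, "top": top, "bottom": bottom, "hill": hill,
        "noise": noise, "noise_model": noise_model, "seed": seed,
    }
    return df, truth


def gen_competition(
    *,
    ic50_nM: float = 29.0,
    top: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
    conc_nM=DEFAULT_CONC_GRID_NM,
    n_replicates: int = 3,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Descending competition table; truth IC50 defaults to 29 nM."""
    if ic50_nM <= 0:
        raise InvalidParameterError("ic50 truth must be > 0")
    rng = _rng(seed)
    conc = np.asarray(conc_nM, dtype=float)
    conc_rep = np.repeat(conc, n_replicates)
    clean = fits.competition_model(conc_rep, top, bottom, np.log10(ic50_nM), hill)
    df = pd.DataFrame(
        {
            "conc_nM": conc_rep,
            "replicate": np.tile(np.arange(1, n_replicates + 1), len(conc)),
            "signal": _add_noise(rng, clean, noise, noise_model),
        }
    )
    truth = {
        "ic50_nM": ic50_nM, "top": top, "bottom": bottom, "hill": hill,
        "noise": noise, "noise_model": noise_model, "seed": seed,
    }
    return df, truth


def gen_association(
    *,
    t_half_min: float = 24.0,
    plateau: float = 100.0,
    times_min=None,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Mono-exponential association trace; truth t1/2 defaults to 24 min."""
    if t_half_min <= 0:
        raise InvalidParameterError("t_half truth must be > 0")
    rng = _rng(seed)
    if times_min is None:
        times_min = np.array([0, 5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240], float)
    t = np.asarray(times_min, dtype=float)
    clean = fits.association_model(t, plateau, fits.LN2 / t_half_min)
    df = pd.DataFrame({"time_min": t, "signal": _add_noise(rng, clean, noise, noise_model)})
    truth = {"t_half_min": t_half_min, "plateau": plateau, "noise": noise, "seed": seed}
    return df, truth


def gen_decay(
    *,
    mode: str = "two-phase",
    half_lives_min=(21.0, 373.0),
    fraction_fast: float = 0.4,
    amplitude: float = 100.0,
    times_min=DECAY_TIMES_MIN,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Exponential dissociation trace with one- or two-phase truth.

    Two-phase defaults are the fast/slow half-lives 21 and 373 min; pass
    ``mode="one-phase"`` with ``half_lives_min=(431,)`` for the slow
    single-phase analogue.
    """
    rng = _rng(seed)
    t = np.asarray(times_min, dtype=float)
    hl = np.atleast_1d(np.asarray(half_lives_min, dtype=float))
    if np.any(hl <= 0):
        raise InvalidParameterError("half-life truths must be > 0")
    if mode == "one-phase":
        clean = fits.one_phase_decay(t, amplitude, fits.LN2 / hl[0])
        truth_frac = 1.0
    elif mode == "two-phase":
        if len(hl) != 2:
            raise InvalidParameterError("two-phase truth needs two half-lives")
        if not 0 <= fraction_fast <= 1:
            raise InvalidParameterError("fraction_fast must be in [0, 1]")
        clean = fits.two_phase_decay(
            t, amplitude, fraction_fast, fits.LN2 / hl[0], fits.LN2 / hl[1]
        )
        truth_frac = fraction_fast
    else:
        raise InvalidParameterError(f"unknown decay mode {mode!r}")
    df = pd.DataFrame({"time_min": t, "signal": _add_noise(rng, clean, noise, noise_model)})
    truth = {
        "mode": mode, "half_lives_min": list(hl), "fraction_fast": truth_frac,
        "amplitude": amplitude, "noise": noise, "noise_model": noise_model, "seed": seed,
    }
    return df, truth


def gen_fp(
    *,
    mode: str = "saturation",
    kd_M: float = 9e-6,
    ki_M: float = 2.1e-6,
    fp_free: float = 50.0,
    fp_bound: float = 250.0,
    rt_M: float | None = None,
    conc_M=None,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """FP titration table (columns conc_M, fp) from the stated binding models.

    Saturation mode titrates protein over the tracer (truth kd = 9 uM);
    competition mode titrates unlabeled competitor at a fixed 70 %-
    saturating protein concentration (truth ki = 2.1 uM).
    """
    rng = _rng(seed)
    if mode == "saturation":
        if conc_M is None:
            conc_M = np.logspace(-7.5, -3.5, 12)  # ~0.03 uM .. 300 uM
        x = np.asarray(conc_M, dtype=float)
        clean = fp.fp_saturation_model(x, fp_free, fp_bound, kd_M)
        truth = {"mode": mode, "kd_M": kd_M, "fp_free": fp_free,
                 "fp_bound": fp_bound, "noise": noise, "seed": seed}
    elif mode == "competition":
        if rt_M is None:
            rt_M = (0.7 / 0.3) * kd_M  # 70 % saturating protein
        if conc_M is None:
            conc_M = np.concatenate([[0.0], np.logspace(-8, -3, 12)])
        x = np.asarray(conc_M, dtype=float)
        clean = fp.fp_competition_model(x, fp_free, fp_bound, rt_M, kd_M, ki_M)
        truth = {"mode": mode, "kd_M": kd_M, "ki_M": ki_M, "rt_M": rt_M,
                 "fp_free": fp_free, "fp_bound": fp_bound, "noise": noise, "seed": seed}
    else:
        raise InvalidParameterError(f"unknown FP mode {mode!r}")
    df = pd.DataFrame({"conc_M": x, "fp": _add_noise(rng, clean, noise, noise_model)})
    return df, truth


def gen_roi_table(
    *,
    n_pass: int = 10,
    n_saturated: int = 2,
    n_dim: int = 3,
    ratio_truth: float = 1.5,
    receptor_level: float = 1000.0,
    background_mean: float = 50.0,
    background_sd: float = 5.0,
    condition: str = "LKV",
    conc_nM: float = 100.0,
    ligand_labeling: float = 1.0,
    noise: float = 0.0,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format ROI table with planted QC outliers and known truth ratios.

    Passing sheets carry a corrected ratio equal to ``ratio_truth`` exactly
    at ``noise=0`` (the generator plants
    ``i_obs = (background + level) * labeling_degree`` so that labeling and
    background corrections invert exactly).  Saturated sheets have the
    saturation flag set; dim sheets sit below background + 2 sd.  Returns
    (table, per-sheet truth table).
    """
    if min(n_pass, n_saturated, n_dim) < 0:
        raise InvalidParameterError("sheet counts must be >= 0")
    rng = _rng(seed)
    rows, truth_rows = [], []
    sheet = 0

    def backgrounds():
        return (
            float(np.round(rng.normal(background_mean, background_sd), 6)),
            float(np.round(rng.normal(background_mean, background_sd), 6)),
        )

    def add_sheet(kind):
        nonlocal sheet
        sheet += 1
        sid = f"sheet{sheet:03d}"
        back_l, back_r = backgrounds()
        lig_level = ratio_truth * receptor_level
        if kind == "dim":
            # below the 2-sigma acceptance line in the ligand channel
            i_lig = max(back_l - 1.0 * background_sd, 0.0)
            i_rec = back_r + receptor_level
        else:
            i_lig = (back_l + lig_level) * ligand_labeling
            i_rec = back_r + receptor_level
        if noise > 0:
            i_lig *= 1.0 + noise * rng.standard_normal()
            i_rec *= 1.0 + noise * rng.standard_normal()
        sat = kind == "saturated"
        rows.append((sid, condition, conc_nM, "ligand", max(i_lig, 0.0), back_l, sat))
        rows.append((sid, condition, conc_nM, "receptor", max(i_rec, 0.0), back_r, sat))
        truth_rows.append(
            {"sheet_id": sid, "planted_status": "pass" if kind == "pass" else kind,
             "ratio_truth": ratio_truth if kind == "pass" else float("nan")}
        )

    for _ in range(n_pass):
        add_sheet("pass")
    for _ in range(n_saturated):
        add_sheet("saturated")
    for _ in range(n_dim):
        add_sheet("dim")
    df = pd.DataFrame(
        rows, columns=["sheet_id", "condition", "conc_nM", "ch", "i_obs", "i_back", "saturated"]
    )
    return df, pd.DataFrame(truth_rows)


def gen_mechanistic(
    params: kinetics.RateParameters = kinetics.REFERENCE_PARAMS,
    *,
    mode: str = "saturation",
    conc_nM=None,
    preincubation_nM: float = 200.0,
    t_incubation: float = 120.0,
    times_min=WASHOUT_TIMES_MIN,
    noise: float = DEFAULT_NOISE,
    noise_model: str = "proportional",
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response or washout tables sampled from the kinetic simulator.

    ``mode="saturation"`` returns endpoint total signal versus bulk
    concentration after ``t_incubation`` min; ``mode="washout"`` returns
    the dissociation trace after preincubation, sampled every 30 min to
    600 min by default.  Noise is applied on top of the simulated signal.
    """
    rng = _rng(seed)
    if mode == "saturation":
        grid_nM = np.asarray(DEFAULT_CONC_GRID_NM if conc_nM is None else conc_nM, float)
        sim = kinetics.simulate_saturation_curve(params, grid_nM * 1e-9, t_incubation)
        df = pd.DataFrame(
            {
                "conc_nM": grid_nM,
                "signal": _add_noise(rng, sim.total_signal, noise, noise_model),
            }
        )
        truth = {"mode": mode, "t_incubation": t_incubation,
                 "clean_signal": sim.total_signal.tolist(), "noise": noise, "seed": seed}
        return df, truth
    if mode == "washout":
        t = np.asarray(times_min, dtype=float)
        schedule = kinetics.BulkLigandSchedule(
            preincubation_nM * 1e-9, t_incubation, washout=True, t_washout=float(t[-1])
        )
        tc = kinetics.simulate_time_course(params, schedule, sample_times=t + t_incubation)
        df = pd.DataFrame(
            {"time_min": t, "signal": _add_noise(rng, tc.signal, noise, noise_model)}
        )
        truth = {"mode": mode, "preincubation_nM": preincubation_nM,
                 "t_incubation": t_incubation, "clean_signal": tc.signal.tolist(),
                 "noise": noise, "seed": seed}
        return df, truth
    raise InvalidParameterError(f"unknown mechanistic mode {mode!r}")
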