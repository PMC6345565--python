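"""Per-sheet two-channel intensity quantification for membrane-sheet assays.

Raw inputs are already-reduced ROI statistics: one region of interest per
membrane sheet, with a mean sheet intensity and a mean local background per
channel (a "ligand" channel for the binder and a "receptor" channel for the
membrane-embedded target).  This module turns those into the normalized
binding ratio I_ligand / I_receptor with three corrections:

* degree of labeling — observed ligand fluorescence divided by the labeled
  fraction, correcting under-counting from unlabeled protein
* PMT gain — intensities rescaled by ``(V2/V1)**(alpha * n_dynodes)`` when
  detector voltage changed between acquisitions
* background — gain-corrected background subtracted

plus quality-control filtering: sheets with saturated pixels or with a
signal below ``mean(background) + sigma_mult * sd(background)`` are
discarded before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError, UndefinedValueError

ROI_COLUMNS = ["sheet_id", "condition", "conc_nM", "ch", "i_obs", "i_back", "saturated"]


def degree_of_labeling(a_dye, a_280, eps_280, eps_dye, cf_280: float = 0.0) -> float:
    """Moles of dye per mole of protein from a two-wavelength absorbance scan.

    ``(a_dye / eps_dye) / ((a_280 - a_dye * cf_280) / eps_280)`` where
    ``cf_280`` is the dye's 280-nm correction factor (absorbance of the dye
    at 280 nm relative to its excitation maximum; 0 when the dye does not
    absorb at 280 nm).
    """
    if a_dye < 0 or a_280 < 0:
        raise InvalidParameterError("absorbances must be >= 0")
    if not (eps_280 > 0 and eps_dye > 0):
        raise InvalidParameterError("extinction coefficients must be > 0")
    if cf_280 < 0:
        raise InvalidParameterError("cf_280 must be >= 0")
    protein_abs = a_280 - a_dye * cf_280
    if a_dye == 0:
        return 0.0
    if protein_abs <= 0:
        raise DataError(
            "corrected protein absorbance <= 0; dye correction exceeds A280"
        )
    return (a_dye / eps_dye) / (protein_abs / eps_280)


@dataclass(frozen=True)
class ChannelCalibration:
    """Per-channel labeling and detector calibration.

    ``alpha`` (dynode conductance exponent) and ``n_dynodes`` are instrument
    constants supplied by configuration; the gain factor is
    ``(pmt_v2 / pmt_v1) ** (alpha * n_dynodes)`` and equals 1 when the
    voltage did not change.
    """

    labeling_degree: float = 1.0
    pmt_v1: float = 1.0
    pmt_v2: float = 1.0
    alpha: float = 0.0
    n_dynodes: int = 0

    def __post_init__(self):
        if not 0 < self.labeling_degree <= 1:
            raise InvalidParameterError(
                f"labeling_degree must be in (0, 1], got {self.labeling_degree}"
            )
        if not (self.pmt_v1 > 0 and self.pmt_v2 > 0):
            raise InvalidParameterError("PMT voltages must be > 0")

    @property
    def gain(self) -> float:
        return gain_correction(self)


def gain_correction(cal: ChannelCalibration) -> float:
    """PMT gain correction factor ``(V2/V1)**(alpha * n)``."""
    return (cal.pmt_v2 / cal.pmt_v1) ** (cal.alpha * cal.n_dynodes)


def corrected_intensity(i_obs, i_back, labeling_degree: float = 1.0, gain: float = 1.0):
    """Background-, labeling- and gain-corrected ROI intensity.

    ``(i_obs / labeling_degree) * gain - i_back * gain``.  The result may be
    negative (sheet dimmer than background); callers flag such sheets as
    ``dim`` rather than clipping.
    """
    i_obs = np.asarray(i_obs, dtype=float)
    i_back = np.asarray(i_back, dtype=float)
    if np.any(i_obs < 0) or np.any(i_back < 0):
        raise InvalidParameterError("intensities must be >= 0")
    if not 0 < labeling_degree <= 1:
        raise InvalidParameterError("labeling_degree must be in (0, 1]")
    val = (i_obs / labeling_degree) * gain - i_back * gain
    return float(val) if val.ndim == 0 else val


def normalized_binding(ligand_corr: float, receptor_corr: float) -> float:
    """Fractional binding: corrected ligand intensity over corrected receptor."""
    if receptor_corr <= 0:
        raise UndefinedValueError(
            f"receptor corrected intensity must be > 0, got {receptor_corr}"
        )
    if ligand_corr < 0:
        raise InvalidParameterError("ligand corrected intensity must be >= 0")
    return ligand_corr / receptor_corr


def _validate_roi(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ROI_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"ROI table is missing columns {missing}")
    if np.any(df["i_obs"] < 0) or np.any(df["i_back"] < 0):
        raise DataError("ROI intensities must be >= 0")
    return df


def qc_filter(df: pd.DataFrame, sigma_mult: float = 2.0) -> pd.DataFrame:
    """Flag each sheet ``pass`` / ``saturated`` / ``dim``.

    A sheet is ``saturated`` if any of its channels has the saturation flag
    set, else ``dim`` if any channel's ``i_obs`` falls below
    ``i_back + sigma_mult * sd`` where ``sd`` is the standard deviation of
    the background across sheets in the same channel, else ``pass``.
    Returns the table with a ``qc_status`` column added; idempotent (an
    existing ``qc_status`` column is recomputed).
    """
    if sigma_mult < 0:
        raise InvalidParameterError("sigma_mult must be >= 0")
    if len(df) == 0:
        warnings.warn("qc_filter called on an empty ROI table", stacklevel=2)
        out = df.copy()
        out["qc_status"] = pd.Series(dtype=object)
        return out
    df = _validate_roi(df)
    out = df.copy()
    back_sd = df.groupby("ch")["i_back"].transform(lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
    dim_row = out["i_obs"] < out["i_back"] + sigma_mult * back_sd if sigma_mult > 0 else out["i_obs"] < out["i_back"]
    sat_sheet = out.groupby("sheet_id")["saturated"].transform("any")
    dim_sheet = dim_row.groupby(out["sheet_id"]).transform("any")
    status = np.where(sat_sheet, "saturated", np.where(dim_sheet, "dim", "pass"))
    out["qc_status"] = status
    return out


def qc_counts(df: pd.DataFrame) -> dict:
    """Per-sheet QC tally {'pass': n, 'saturated': n, 'dim': n}."""
    per_sheet = df.drop_duplicates("sheet_id")
    counts = per_sheet["qc_status"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("pass", "saturated", "dim")}


def quantify_table(
    df: pd.DataFrame,
    ligand_cal: ChannelCalibration,
    receptor_cal: ChannelCalibration,
    *,
    ligand_channel: str = "ligand",
    receptor_channel: str = "receptor",
    sigma_mult: float = 2.0,
) -> pd.DataFrame:
    """Full per-sheet pipeline: QC filter, correct both channels, ratio.

    Input is the long-format ROI table (one row per sheet x channel);
    output has one row per sheet with columns ``sheet_id``, ``condition``,
    ``conc_nM``, ``ratio`` (NaN unless QC passes) and ``qc_status``.  A
    sheet whose corrected ligand intensity is negative is reflagged ``dim``.
    """
    flagged = qc_filter(df, sigma_mult=sigma_mult)
    if len(flagged) == 0:
        return pd.DataFrame(columns=["sheet_id", "condition", "conc_nM", "ratio", "qc_status"])
    cals = {ligand_channel: ligand_cal, receptor_channel: receptor_cal}
    rows = []
    for sheet_id, grp in flagged.groupby("sheet_id", sort=False):
        status = grp["qc_status"].iloc[0]
        rec = {
            "sheet_id": sheet_id,
            "condition": grp["condition"].iloc[0],
            "conc_nM": grp["conc_nM"].iloc[0],
            "ratio": float("nan"),
            "qc_status": status,
        }
        if status == "pass":
            corr = {}
            for ch, cal in cals.items():
                sub = grp[grp["ch"] == ch]
                if len(sub) != 1:
                    raise DataError(
                        f"sheet {sheet_id!r} needs exactly one {ch!r} row, got {len(sub)}"
                    )
                corr[ch] = corrected_intensity(
                    sub["i_obs"].iloc[0], sub["i_back"].iloc[0],
                    cal.labeling_degree, cal.gain,
                )
            if corr[ligand_channel] < 0 or corr[receptor_channel] <= 0:
                rec["qc_status"] = "dim"
            else:
                rec["ratio"] = normalized_binding(
                    corr[ligand_channel], corr[receptor_channel]
                )
        rows.append(rec)
    return pd.DataFrame(rows)
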