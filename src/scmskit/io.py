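"""Configuration and CSV plumbing.

Configuration files are flat ``key: value`` text (also accepts ``key =
value``); ``#`` starts a comment.  Concentrations are nanomolar at every
file interface and molar internally; times are minutes; the reach radius is
ångström.

Recognized rate-parameter keys::

    k1_per_M_min:  1.85e5
    k_off_per_min: 0.0085
    r_angstrom:    180
    f:             185
    k2_per_min:    0.136       # optional; overrides the derived k1*[L]/f

Calibration keys are prefixed per channel, e.g. ``ligand_labeling_degree``,
``receptor_pmt_v1`` ...
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ConfigError, DataError
from .kinetics import RateParameters
from .quant import ChannelCalibration

RATE_KEYS = {"k1_per_M_min", "k_off_per_min", "r_angstrom", "f", "k2_per_min"}


def parse_flat_config(path) -> dict:
    """Parse a flat key/value text config into a dict of strings."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    out = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ConfigError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if not key or not val:
            raise ConfigError(f"{path}:{lineno}: empty key or value in {raw!r}")
        out[key] = val
    return out


def _as_float(cfg: dict, key: str, where: str):
    try:
        return float(cfg[key])
    except KeyError:
        raise ConfigError(f"{where}: missing required field {key!r}") from None
    except ValueError:
        raise ConfigError(f"{where}: field {key!r} is not a number: {cfg[key]!r}") from None


def rate_parameters_from_config(path) -> RateParameters:
    """Load :class:`~scmskit.kinetics.RateParameters` from a flat config file.

    An explicit ``k2_per_min`` overrides the derived composite rate; a
    mismatch above 1 % between the two triggers a warning (in
    ``RateParameters``).
    """
    cfg = parse_flat_config(path)
    where = str(path)
    kwargs = dict(
        k1=_as_float(cfg, "k1_per_M_min", where),
        k_off=_as_float(cfg, "k_off_per_min", where),
    )
    if "r_angstrom" in cfg:
        kwargs["r"] = _as_float(cfg, "r_angstrom", where)
    if "f" in cfg:
        kwargs["f"] = _as_float(cfg, "f", where)
    if "k2_per_min" in cfg:
        kwargs["k2_override"] = _as_float(cfg, "k2_per_min", where)
    return RateParameters(**kwargs)


def calibration_from_config(cfg: dict, prefix: str) -> ChannelCalibration:
    """Build a per-channel calibration from prefixed flat-config keys."""
    def get(key, default):
        full = f"{prefix}_{key}"
        if full not in cfg:
            return default
        try:
            return float(cfg[full])
        except ValueError:
            raise ConfigError(f"field {full!r} is not a number: {cfg[full]!r}") from None

    return ChannelCalibration(
        labeling_degree=get("labeling_degree", 1.0),
        pmt_v1=get("pmt_v1", 1.0),
        pmt_v2=get("pmt_v2", 1.0),
        alpha=get("alpha", 0.0),
        n_dynodes=int(get("n_dynodes", 0)),
    )


def read_table(path, required: tuple, what: str = "input") -> pd.DataFrame:
    """Read a CSV table, validating that the required columns are present."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{what} file not found: {path}")
    if path.stat().st_size == 0:
        raise DataError(f"{what} file is empty: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{what} file is empty: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(
            f"{what} file {path} is missing column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    if len(df) == 0:
        raise DataError(f"{what} file {path} contains a header but no rows")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a CSV deterministically (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
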