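"""Config files and tabular output.

Channel configurations travel as YAML (maximal conductances, component
fractions, modulation flags); results leave as CSV tables with a JSON
provenance sidecar where the table alone would be ambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .channels import (
    ChannelModel,
    ModulationState,
    channel_set_from_config,
    channel_set_to_config,
)
from .linear_response import ImpedanceSpectrum
from .membrane import OperatingPoint

__all__ = [
    "load_channel_config",
    "save_channel_config",
    "operating_points_frame",
    "write_spectrum",
]


def load_channel_config(path: str | Path) -> tuple[tuple[ChannelModel, ...], ModulationState]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return channel_set_from_config(cfg)


def save_channel_config(
    path: str | Path,
    channels: tuple[ChannelModel, ...],
    modulation: ModulationState,
) -> None:
    cfg = channel_set_to_config(channels, modulation)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def operating_points_frame(ops: Sequence[OperatingPoint]) -> pd.DataFrame:
    """Tidy table of a sweep: voltage, light conductance, pump and
    exchanger currents, per-channel conductances and gate values."""
    rows = []
    for op in ops:
        row: dict[str, float] = {
            "V_mV": op.V,
            "g_light_nS": op.g_light,
            "I_P_pA": op.I_P,
            "I_E_pA": op.I_E,
            "feasible": op.feasible,
        }
        for name, g in op.conductances.items():
            row[f"g_{name}_nS"] = g
        for name, gates in op.gates.items():
            for gate, val in gates.items():
                row[f"{name}_{gate}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_spectrum(path: str | Path, spectrum: ImpedanceSpectrum) -> None:
    """CSV spectrum (f, Re Z, Im Z, |Z|) plus a JSON provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "f_Hz": spectrum.f,
            "Re_Z_GOhm": np.real(spectrum.Z),
            "Im_Z_GOhm": np.imag(spectrum.Z),
            "abs_Z_MOhm": np.abs(spectrum.Z) * 1e3,
        }
    )
    df.to_csv(path, index=False)
    meta = {k: _jsonable(v) for k, v in dict(spectrum.meta).items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
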