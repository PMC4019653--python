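"""File formats: expression-profile CSV, parameter JSON/YAML, trajectory CSV.

Delimited text is comma-separated UTF-8 with a mandatory header row and
'.' decimal; datasets carry a JSON sidecar (``<name>.meta.json``) with
the seed, phase boundaries and noise level so every artifact can be
regenerated exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import PARAM_NAMES, ParameterSet, UnknownParameterError
from .synth import CHANNELS, PhaseBoundaries, ReferenceDataset

__all__ = [
    "ProfileParseError",
    "read_profiles",
    "write_profiles",
    "read_parameters",
    "write_parameters",
    "write_trajectory",
]


class ProfileParseError(ValueError):
    """A profile file failed schema validation; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


_EXPECTED = ("time_fraction",) + CHANNELS


def read_profiles(path) -> ReferenceDataset:
    """Read an expression-profile CSV (and its metadata sidecar if present).

    Header names are matched case-insensitively; time must be strictly
    increasing; every cell must parse as a number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ProfileParseError(f"could not parse {path}: {exc}") from exc
    colmap = {c.lower(): c for c in df.columns}
    missing = [c for c in _EXPECTED if c.lower() not in colmap]
    if missing:
        raise ProfileParseError(f"missing column(s): {', '.join(missing)}")
    data = {}
    for want in _EXPECTED:
        col = df[colmap[want.lower()]]
        vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ProfileParseError(
                f"non-numeric value {col.iloc[bad[0]]!r} in column {want}",
                line=int(bad[0]) + 2)  # +1 header, +1 one-based
        data[want] = vals
    t = data["time_fraction"]
    nonmono = np.nonzero(np.diff(t) <= 0)[0]
    if nonmono.size:
        raise ProfileParseError("time_fraction not strictly increasing",
                                line=int(nonmono[0]) + 3)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    noise_sd, seed, bounds = 0.0, None, PhaseBoundaries()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        noise_sd = float(meta.get("noise_sd", 0.0))
        seed = meta.get("seed")
        if "boundaries" in meta:
            bounds = PhaseBoundaries(**meta["boundaries"])
    return ReferenceDataset(times=t, cyclinA2=data["cyclinA2"],
                            cyclinB1=data["cyclinB1"], PHH3=data["PHH3"],
                            DNA=data["DNA"], noise_sd=noise_sd, seed=seed,
                            boundaries=bounds)


def write_profiles(ds: ReferenceDataset, path) -> None:
    """Write a dataset as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    ds.to_frame().to_csv(path, index=False, lineterminator="\n")
    meta = {
        "noise_sd": ds.noise_sd,
        "seed": ds.seed,
        "boundaries": {"g1s": ds.boundaries.g1s, "sg2": ds.boundaries.sg2,
                       "g2m": ds.boundaries.g2m},
        "n_points": int(len(ds)),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1) + "\n", encoding="utf-8")


def read_parameters(path) -> ParameterSet:
    """Read a parameter file (JSON or YAML by extension).

    The file must contain exactly the model's kinetic constants; missing
    or extra names are reported explicitly.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        try:
            payload = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ProfileParseError(f"malformed YAML in {path}: {exc}") from exc
    else:
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProfileParseError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(payload, dict) or "constants" not in payload:
        raise ProfileParseError(f"{path}: expected an object with a 'constants' map")
    constants = payload["constants"]
    missing = sorted(set(PARAM_NAMES) - set(constants))
    extra = sorted(set(constants) - set(PARAM_NAMES))
    if missing or extra:
        raise UnknownParameterError(
            f"{path}: parameter set must list exactly {len(PARAM_NAMES)} "
            f"constants; missing={missing} extra={extra}")
    return ParameterSet.from_dict(payload)


def write_parameters(params: ParameterSet, path) -> None:
    """Write a parameter set losslessly (JSON or YAML by extension)."""
    path = Path(path)
    payload = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def write_trajectory(traj, path) -> None:
    """Write a trajectory as CSV: time_fraction then the 25 state columns."""
    traj.to_frame().to_csv(path, index=False, lineterminator="\n")
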