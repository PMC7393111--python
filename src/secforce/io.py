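"""CSV/YAML/JSON I/O, run configuration and loading-rate estimation.

Rip tables are plain CSV with the header
``molecule_id,condition,rip_force_pN,loading_rate_pN_s,delta_extension_nm,trap_velocity_nm_s,censored``;
a missing loading rate is filled from ``stiffness x trap_velocity`` when a
trap stiffness is supplied. Trace CSVs carry two columns ``time_s,rlu``
preceded by ``# key: value`` comment lines holding the metadata
(``t_dtt_s``, ``condition``, ``replicate_id``, ``sampling_rate_hz``).
Floats are written with ``repr``-faithful formatting so regeneration with
the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import NU_DEFAULT, RipEvent, events_to_frame
from .polymer import KBT_ROOM, PolymerModel
from .translocation import LuminescenceTrace

RIP_COLUMNS = [
    "molecule_id", "condition", "rip_force_pN", "loading_rate_pN_s",
    "delta_extension_nm", "trap_velocity_nm_s", "censored",
]


def write_rip_csv(events, path) -> None:
    """Write rip events in the standard dialect (deterministic formatting)."""
    # default float formatting is the shortest round-trip repr: exact and stable
    df = events_to_frame(events)
    df.to_csv(path, index=False)


def read_rip_csv(path, stiffness: float | None = None) -> list[RipEvent]:
    """Read a rip table; fill missing loading rates from stiffness x velocity."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    events = []
    for i, row in df.iterrows():
        r = row["loading_rate_pN_s"]
        if pd.isna(r):
            v = row["trap_velocity_nm_s"]
            if stiffness is None or pd.isna(v):
                raise ValueError(
                    f"{path} line {i + 2}: loading_rate_pN_s missing and no "
                    "stiffness/trap_velocity to reconstruct it"
                )
            r = stiffness * v
        try:
            events.append(
                RipEvent(
                    molecule_id=str(row["molecule_id"]),
                    condition=str(row["condition"]),
                    rip_force=float(row["rip_force_pN"]),
                    loading_rate=float(r),
                    delta_extension=None if pd.isna(row["delta_extension_nm"]) else float(row["delta_extension_nm"]),
                    trap_velocity=None if pd.isna(row["trap_velocity_nm_s"]) else float(row["trap_velocity_nm_s"]),
                    censored=bool(row["censored"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return events


def write_trace_csv(trace: LuminescenceTrace, path) -> None:
    """Write a trace as '# key: value' metadata lines plus time_s,rlu columns."""
    lines = [
        f"# t_dtt_s: {trace.t_dtt!r}",
        f"# condition: {trace.condition}",
        f"# replicate_id: {trace.replicate_id}",
        f"# sampling_rate_hz: {trace.sampling_rate!r}",
        "time_s,rlu",
    ]
    lines += [f"{t:.10g},{y:.10g}" for t, y in zip(trace.time, trace.rlu)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_csv(path) -> LuminescenceTrace:
    """Read a trace CSV written by :func:`write_trace_csv`."""
    meta = {}
    rows_start = 0
    text = Path(path).read_text().splitlines()
    for i, line in enumerate(text):
        if line.startswith("#"):
            try:
                key, val = line.lstrip("# ").split(":", 1)
            except ValueError as exc:
                raise ValueError(f"{path} line {i + 1}: malformed metadata line") from exc
            meta[key.strip()] = val.strip()
        else:
            rows_start = i
            break
    df = pd.read_csv(path, skiprows=rows_start, float_precision="round_trip")
    if list(df.columns) != ["time_s", "rlu"]:
        raise ValueError(f"{path}: expected columns time_s,rlu, got {list(df.columns)}")
    if "t_dtt_s" not in meta:
        raise ValueError(f"{path}: metadata line '# t_dtt_s: <seconds>' required")
    return LuminescenceTrace(
        time=df["time_s"].to_numpy(),
        rlu=df["rlu"].to_numpy(),
        t_dtt=float(meta["t_dtt_s"]),
        condition=meta.get("condition", ""),
        replicate_id=meta.get("replicate_id", ""),
        sampling_rate=float(meta.get("sampling_rate_hz", 0.2)),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (YAML-backed)."""

    thermal_energy: float = KBT_ROOM  # pN*nm
    nu: float = NU_DEFAULT
    polymer: PolymerModel = field(default_factory=PolymerModel)
    stiffness: float = 0.1  # pN/nm, used to reconstruct missing loading rates
    n_bootstrap: int = 200
    seed: int = 0
    bounds: tuple = ((0.0, 12.0), (0.05, 10.0), (1.0, 50.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["polymer"] = asdict(self.polymer)
        d["bounds"] = [list(b) for b in self.bounds]
        return d


_KNOWN_KEYS = {"thermal_energy", "nu", "polymer", "stiffness", "n_bootstrap", "seed", "bounds"}
_POLYMER_KEYS = {"persistence_length", "contour_per_residue", "native_end_to_end"}


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(_KNOWN_KEYS)})")
    kwargs = dict(raw)
    if "polymer" in kwargs:
        p = kwargs["polymer"]
        bad = set(p) - _POLYMER_KEYS
        if bad:
            raise ValueError(f"unknown polymer keys: {sorted(bad)}")
        kwargs["polymer"] = PolymerModel(**p)
    if "bounds" in kwargs:
        kwargs["bounds"] = tuple(tuple(b) for b in kwargs["bounds"])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# loading-rate estimation from raw force-time segments


def estimate_loading_rate(times, forces, window: float = 1.0):
    """Local loading rate (pN/s) from the trailing window of a force ramp.

    Least-squares slope of F(t) over the last ``window`` seconds before the
    rip, returned with the residual SD. Requires at least five samples in
    the window; a non-positive slope is returned but flagged with a warning.
    """
    import warnings

    t = np.asarray(times, dtype=float)
    f = np.asarray(forces, dtype=float)
    sel = t >= t[-1] - window
    if sel.sum() < 5:
        raise ValueError("fewer than 5 samples in the trailing window")
    tt, ff = t[sel], f[sel]
    slope, intercept = np.polyfit(tt, ff, 1)
    resid_sd = float(np.std(ff - (slope * tt + intercept), ddof=2))
    if slope <= 0:
        warnings.warn("non-positive loading rate estimated; segment flagged")
    return float(slope), resid_sd
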