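"""Readers and writers for the pipeline's file formats.

GPS fixes travel as Movebank-dialect CSV (``timestamp`` ISO-8601 UTC,
``location-long``, ``location-lat``, ``individual-local-identifier``);
acceleration bursts as long-format CSV with one row per sample; encounter
histories as plain text, one digit string plus a strategy group per line.
All writers are deterministic and all readers invert the writers on valid
files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .accel import AccelBurst, InputError
from .multievent import EncounterHistory
from .trajectory import Geography

__all__ = [
    "MOVEBANK_COLUMNS",
    "read_fixes",
    "write_fixes",
    "read_bursts",
    "write_bursts",
    "read_histories",
    "write_histories",
    "write_table",
    "PipelineConfig",
    "load_config",
    "save_config",
]

log = logging.getLogger("ciconia")

MOVEBANK_COLUMNS = {
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "individual-local-identifier": "individual",
}


class FormatError(ValueError):
    """Raised for files that do not match the expected dialect."""


def read_fixes(path, alias_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a Movebank-dialect fix CSV into the internal fix table.

    Malformed rows (unparseable timestamp or coordinates) are dropped and
    counted in a warning.  Timestamps are normalized to UTC and fixes
    sorted per individual.
    """
    columns = dict(MOVEBANK_COLUMNS)
    if alias_map:
        columns.update(alias_map)
    raw = pd.read_csv(path, dtype=str)
    if len(raw) == 0:
        log.warning("empty fix file %s", path)
        return pd.DataFrame(columns=["individual", "timestamp", "lon", "lat"])
    missing = set(columns) - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    df = raw.rename(columns=columns)[["individual", "timestamp", "lon", "lat"]].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad = df[["timestamp", "lon", "lat"]].isna().any(axis=1)
    if bad.any():
        log.warning("%s: dropped %d malformed rows", path, int(bad.sum()))
    df = df[~bad]
    return df.sort_values(["individual", "timestamp"]).reset_index(drop=True)


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write the internal fix table as Movebank-dialect CSV."""
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(fixes["timestamp"], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "location-long": fixes["lon"].map("{:.6f}".format),
            "location-lat": fixes["lat"].map("{:.6f}".format),
            "individual-local-identifier": fixes["individual"],
        }
    )
    out.to_csv(path, index=False)


def write_bursts(bursts: Sequence[AccelBurst], path) -> None:
    """Write bursts as long-format CSV, one row per tri-axial sample."""
    frames = []
    for b in bursts:
        n = b.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": pd.to_datetime(b.timestamp, utc=True).strftime(
                        "%Y-%m-%dT%H:%M:%SZ"
                    ),
                    "individual-local-identifier": b.individual,
                    "tag-type": b.tag_type,
                    "sample-index": np.arange(n),
                    "acc-x": [f"{v:.6f}" for v in b.surge],
                    "acc-y": [f"{v:.6f}" for v in b.sway],
                    "acc-z": [f"{v:.6f}" for v in b.heave],
                }
            )
        )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "timestamp",
                "individual-local-identifier",
                "tag-type",
                "sample-index",
                "acc-x",
                "acc-y",
                "acc-z",
            ]
        )
    )
    out.to_csv(path, index=False)


def read_bursts(path, rate_hz: float = 1.0) -> list[AccelBurst]:
    """Read a long-format burst CSV back into burst objects.

    The sampling rate is not stored in the file (the tags emit it in
    their configuration, not the data stream) and must be supplied.
    """
    raw = pd.read_csv(path)
    if len(raw) == 0:
        log.warning("empty burst file %s", path)
        return []
    required = {"timestamp", "individual-local-identifier", "sample-index", "acc-x", "acc-y", "acc-z"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    bursts = []
    has_tag = "tag-type" in raw.columns
    for (ts, ind), grp in raw.groupby(
        ["timestamp", "individual-local-identifier"], sort=True
    ):
        grp = grp.sort_values("sample-index")
        bursts.append(
            AccelBurst(
                individual=str(ind),
                timestamp=pd.to_datetime(ts, utc=True).to_pydatetime(),
                surge=grp["acc-x"].to_numpy(float),
                sway=grp["acc-y"].to_numpy(float),
                heave=grp["acc-z"].to_numpy(float),
                rate=rate_hz,
                tag_type=str(grp["tag-type"].iloc[0]) if has_tag else "default",
            )
        )
    bursts.sort(key=lambda b: (b.individual, b.timestamp))
    return bursts


def write_histories(histories: Sequence[EncounterHistory], path) -> None:
    """Write encounter histories as text: digit string, group, id."""
    with open(path, "w") as fh:
        for h in histories:
            digits = "".join(str(e) for e in h.events)
            fh.write(f"{digits}\t{h.group}\t{h.individual}\n")


def read_histories(path) -> list[EncounterHistory]:
    """Read an encounter-history text file (digits TAB group [TAB id])."""
    histories = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'digits<TAB>group'")
            digits, group = parts[0], parts[1]
            individual = parts[2] if len(parts) > 2 else f"line-{lineno}"
            if not digits or any(c not in "0123" for c in digits):
                raise FormatError(
                    f"{path}:{lineno}: invalid event character in {digits!r}"
                )
            histories.append(
                EncounterHistory(
                    individual=individual,
                    events=np.array([int(c) for c in digits]),
                    group=group,
                )
            )
    return histories


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a tidy table as CSV with a deterministic column order."""
    df.to_csv(path, index=False, float_format=float_format)


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline in one round-trippable bag."""

    seed: int = 0
    n_individuals: int = 40
    year: int = 2018
    gps_interval_min: float = 20.0
    burst_rate_hz: float = 1.0
    burst_duration_s: float = 9.0
    geography: Geography = field(default_factory=Geography)
    c_hat: float = 2.52
    survival_occasions: int = 6

    def validate(self) -> None:
        geo = self.geography
        for name in (
            "local_radius_km",
            "migration_daily_km",
            "nest_radius_m",
            "speed_cap_kmh",
        ):
            if getattr(geo, name) <= 0:
                raise InputError(f"geography.{name} must be positive")
        if geo.migration_run_days < 1:
            raise InputError("migration_run_days must be >= 1")


def save_config(cfg: PipelineConfig, path) -> None:
    data = asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    geo = Geography(**data.pop("geography", {}))
    cfg = PipelineConfig(geography=geo, **data)
    cfg.validate()
    return cfg
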