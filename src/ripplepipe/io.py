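"""Readers and writers for the pipeline's minimal text/binary formats.

Formats (deliberately dependency-light dialects, documented bit-exactly):

* spike files — two-column plain text ``time_s unit_id`` (header optional);
* LFP — flat interleaved little-endian int16 plus a YAML sidecar declaring
  ``n_channels``, ``sampling_rate``, ``channel_roles`` and ``scale``;
* event / pulse tables — CSV with an ``onset,offset,label`` header;
* session manifests — CSV with ``name,kind,start,end,condition`` columns.

Comment lines starting with ``#`` are ignored on read; writers stamp each
text file with the software version and the configuration hash when one is
supplied.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    ChannelRole,
    EventProvenance,
    LfpRecording,
    PulseIntensity,
    PulseMode,
    PulseTrain,
    RippleEventTable,
    SpikeTrainSet,
)

SESSION_KINDS = (
    "presleep", "exploration1", "sleep_block", "exploration2", "postsleep",
    "laser_control_sleep",
)


def config_hash(config: Any) -> str:
    """Stable short hash of a (nested) configuration mapping."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(extra: dict[str, Any] | None = None) -> str:
    items = {"ripplepipe": __version__}
    if extra:
        items.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in items.items())



def _split_header(path: Path) -> tuple[dict[str, str], "io_.StringIO"]:
    """Separate leading ``#`` comment lines from the CSV body."""
    import io as io_

    meta: dict[str, str] = {}
    body: list[str] = []
    in_header = True
    with open(path) as fh:
        for line in fh:
            if in_header and line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
            else:
                in_header = False
                body.append(line)
    return meta, io_.StringIO("".join(body))


# ---------------------------------------------------------------- spikes

def read_spike_file(path: str | Path, session: str = "") -> SpikeTrainSet:
    """Two-column text (time_s, unit_id); times are sorted per unit."""
    path = Path(path)
    times: list[float] = []
    units: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if not times and not _is_number(parts[0]):
                continue  # header row
            try:
                times.append(float(parts[0]))
                units.append(int(float(parts[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse spike row "
                                 f"{line!r}") from exc
    trains: dict[int, list[float]] = {}
    for t, u in zip(times, units):
        trains.setdefault(u, []).append(t)
    return SpikeTrainSet({u: np.sort(v) for u, v in trains.items()}, {}, session)


def write_spike_file(spikes: SpikeTrainSet, path: str | Path,
                     cfg_hash: str | None = None) -> None:
    path = Path(path)
    rows = [(t, u) for u in spikes.unit_ids for t in spikes.trains[u]]
    rows.sort()
    with open(path, "w") as fh:
        fh.write(_header_lines({"config": cfg_hash} if cfg_hash else None))
        fh.write("time_s\tunit_id\n")
        for t, u in rows:
            fh.write(f"{t:.6f}\t{u}\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------- LFP

def write_lfp(rec: LfpRecording, path: str | Path,
              sidecar: str | Path | None = None,
              cfg_hash: str | None = None) -> None:
    """Interleaved little-endian int16; metadata in a YAML sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    interleaved = rec.samples.T.reshape(-1).astype("<i2")
    interleaved.tofile(path)
    meta = {
        "n_channels": rec.n_channels,
        "sampling_rate": float(rec.sampling_rate),
        "channel_roles": [r.value for r in rec.channel_roles],
        "scale": float(rec.scale),
        "ripplepipe": __version__,
    }
    if cfg_hash:
        meta["config"] = cfg_hash
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_lfp(path: str | Path, sidecar: str | Path | None = None) -> LfpRecording:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path, dtype="<i2")
    if len(raw) % n_ch:
        expected = (len(raw) // n_ch + 1) * n_ch * 2
        raise ValueError(
            f"{path}: {len(raw) * 2} bytes is not a whole number of "
            f"{n_ch}-channel frames (next whole size {expected} bytes)")
    samples = raw.reshape(-1, n_ch).T
    return LfpRecording(samples, float(meta["sampling_rate"]),
                        [ChannelRole(r) for r in meta["channel_roles"]],
                        float(meta.get("scale", 1e-6)))


# ---------------------------------------------------------------- positions

def write_positions(traj, path: str | Path, cfg_hash: str | None = None) -> None:
    """Tracking CSV with a ``t,x,y`` header; arena geometry goes in the
    comment header so the trajectory round-trips."""
    from .core import Trajectory  # local import to avoid cycle at module load

    assert isinstance(traj, Trajectory)
    path = Path(path)
    meta = {"kind": "positions", "arena_shape": traj.arena.shape.value,
            "arena_dimensions": ",".join(str(d) for d in traj.arena.dimensions)}
    if cfg_hash:
        meta["config"] = cfg_hash
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        pd.DataFrame({"t": traj.times, "x": traj.positions[:, 0],
                      "y": traj.positions[:, 1]}).to_csv(fh, index=False)


def read_positions(path: str | Path, arena=None):
    """Read a tracking CSV; the arena comes from the comment header, an
    explicit argument, or (last resort) the data's bounding box."""
    from .core import Arena, ArenaShape, Trajectory

    path = Path(path)
    meta, body = _split_header(path)
    df = pd.read_csv(body)
    if arena is None:
        if "arena_shape" in meta:
            dims = tuple(float(d) for d in meta["arena_dimensions"].split(","))
            arena = Arena(ArenaShape(meta["arena_shape"]), dims)
        else:
            w = 2 * np.abs(df["x"]).max() + 1e-6
            h = 2 * np.abs(df["y"]).max() + 1e-6
            arena = Arena(ArenaShape.RECTANGLE, (float(w), float(h)))
    return Trajectory(df["t"].to_numpy(), df[["x", "y"]].to_numpy(), arena)


# ---------------------------------------------------------------- events

def write_events(table: RippleEventTable | PulseTrain, path: str | Path,
                 cfg_hash: str | None = None) -> None:
    path = Path(path)
    if isinstance(table, PulseTrain):
        df = pd.DataFrame({
            "onset": table.onsets,
            "offset": table.offsets,
            "label": "pulse",
        })
        meta = {"kind": "pulse_train", "mode": table.mode.value,
                "intensity": table.intensity.value,
                "duration": table.duration, "delay": table.delay}
    else:
        df = table.events.copy()
        df["label"] = "ripple"
        meta = {"kind": "ripple_events", "provenance": table.provenance.value}
    if cfg_hash:
        meta["config"] = cfg_hash
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=False)


def read_events(path: str | Path) -> RippleEventTable | PulseTrain:
    """Dispatch on the ``# kind:`` comment written by :func:`write_events`;
    a plain CSV without one is read as a ripple table."""
    path = Path(path)
    meta, body = _split_header(path)
    df = pd.read_csv(body)
    if (df["onset"] >= df["offset"]).any():
        raise ValueError(f"{path}: rows with onset >= offset")
    if meta.get("kind") == "pulse_train":
        return PulseTrain(df["onset"].to_numpy(), float(meta["duration"]),
                          PulseMode(meta.get("mode", "direct")),
                          PulseIntensity(meta.get("intensity", "full")),
                          float(meta.get("delay", 0.0)))
    prov = EventProvenance(meta.get("provenance", "offline"))
    cols = {c: df[c].to_numpy() for c in
            ("peak_time", "peak_frequency", "amplitude") if c in df}
    return RippleEventTable.from_arrays(df["onset"].to_numpy(),
                                        df["offset"].to_numpy(),
                                        provenance=prov, **cols)


# ---------------------------------------------------------------- manifest

@dataclass
class SessionManifest:
    """Ordered, non-overlapping sessions of one recording day."""

    sessions: pd.DataFrame   # columns: name, kind, start, end
    condition: str = "control"   # blockade | control
    files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.sessions).reset_index(drop=True)
        required = {"name", "kind", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        bad = set(df["kind"]) - set(SESSION_KINDS)
        if bad:
            raise ValueError(f"unknown session kinds: {sorted(bad)}")
        if not (df["start"] < df["end"]).all():
            raise ValueError("sessions need start < end")
        df = df.sort_values("start").reset_index(drop=True)
        if (df["start"].values[1:] < df["end"].values[:-1]).any():
            raise ValueError("sessions must not overlap")
        if self.condition not in ("blockade", "control"):
            raise ValueError("condition must be 'blockade' or 'control'")
        self.sessions = df

    def bounds(self, kind: str) -> tuple[float, float]:
        rows = self.sessions[self.sessions["kind"] == kind]
        if rows.empty:
            raise KeyError(f"manifest has no session of kind {kind!r}")
        return float(rows.iloc[0]["start"]), float(rows.iloc[0]["end"])

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.sessions[self.sessions["kind"] == kind]


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines({"kind": "session_manifest",
                                "condition": manifest.condition}))
        manifest.sessions.to_csv(fh, index=False)


def read_manifest(path: str | Path) -> SessionManifest:
    meta, body = _split_header(Path(path))
    df = pd.read_csv(body)
    return SessionManifest(df, meta.get("condition", "control"))
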