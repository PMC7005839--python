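"""File formats, configuration and run manifests.

Event logs are persisted as a single cohort CSV (comma-separated, UTF-8, '.'
decimal, mandatory header) with the columns::

    mouse_id, session_index, session_kind, time_s, event_type, countable

``time_s`` is written with millisecond precision; ``countable`` is ``true`` /
``false`` on press events and empty otherwise.  A write -> read -> write
round trip is byte-identical.  Cohort composition (group labels, traits) goes
to a JSON manifest next to the CSV; group/protocol configuration is read from
a YAML file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .cohort import GroupSpec, ProtocolConfig, ProtocolDataset
from .schedules import Event, EventLog, SessionConfig

__all__ = [
    "EVENTLOG_COLUMNS",
    "write_eventlogs",
    "read_eventlogs",
    "write_cohort",
    "read_cohort",
    "read_config",
    "RunManifest",
]

EVENTLOG_COLUMNS = (
    "mouse_id",
    "session_index",
    "session_kind",
    "time_s",
    "event_type",
    "countable",
)

_TIME_FORMAT = "{:.3f}"


def write_eventlogs(logs: Iterable[EventLog], path: str | Path) -> None:
    """Serialize event logs of a cohort to one CSV file."""
    path = Path(path)
    lines = [",".join(EVENTLOG_COLUMNS)]
    for log in logs:
        for e in log.events:
            countable = "" if e.countable is None else str(bool(e.countable)).lower()
            lines.append(
                f"{log.mouse_id},{log.session_index},{log.session_kind},"
                f"{_TIME_FORMAT.format(e.time_s)},{e.event_type},{countable}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_eventlogs(path: str | Path) -> list[EventLog]:
    """Read a cohort event-log CSV back into per-session EventLog objects."""
    df = pd.read_csv(
        path,
        dtype={
            "mouse_id": str,
            "session_index": int,
            "session_kind": str,
            "time_s": float,
            "event_type": str,
            "countable": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in EVENTLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event-log CSV is missing columns {missing} in {path}")
    logs: list[EventLog] = []
    for (mouse_id, session_index, kind), sub in df.groupby(
        ["mouse_id", "session_index", "session_kind"], sort=False
    ):
        events = [
            Event(
                float(row.time_s),
                row.event_type,
                None if row.countable == "" else row.countable == "true",
            )
            for row in sub.itertuples()
        ]
        logs.append(
            EventLog(str(mouse_id), int(session_index), kind, config_hash="",
                     events=events)
        )
    return logs


def write_cohort(dataset: ProtocolDataset, outdir: str | Path) -> dict[str, Path]:
    """Persist a simulated cohort: event CSV + manifest JSON.  Returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_path = outdir / "eventlog.csv"
    manifest_path = outdir / "cohort.json"
    all_logs = [lg for mid in dataset.mouse_ids for lg in dataset.logs[mid]]
    write_eventlogs(all_logs, events_path)
    manifest = {
        "protocol": asdict(dataset.protocol),
        "session_config": asdict(dataset.session_config),
        "mice": dataset.mice.reset_index().to_dict(orient="records"),
    }
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"events": events_path, "manifest": manifest_path}


def read_cohort(outdir: str | Path) -> ProtocolDataset:
    """Reconstruct a ProtocolDataset from ``write_cohort`` output.

    Session configs are rebuilt from the manifest; FR logs with a session
    index below ``n_fr1_sessions`` are attributed to the FR1 stage.
    """
    outdir = Path(outdir)
    manifest = json.loads((outdir / "cohort.json").read_text(encoding="utf-8"))
    protocol = ProtocolConfig(**manifest["protocol"])
    fr5_cfg = SessionConfig(**manifest["session_config"])
    fr1_cfg = SessionConfig(**{**manifest["session_config"], "fixed_ratio": 1})
    pr_cfg = SessionConfig(**{**manifest["session_config"], "session_kind": "pr"})
    shock_cfg = SessionConfig(
        **{**manifest["session_config"], "session_kind": "shock"}
    )
    logs = read_eventlogs(outdir / "eventlog.csv")
    by_mouse: dict[str, list[EventLog]] = {}
    for log in logs:
        if log.session_kind == "fr":
            cfg = fr1_cfg if log.session_index < protocol.n_fr1_sessions else fr5_cfg
        elif log.session_kind == "pr":
            cfg = pr_cfg
        else:
            cfg = shock_cfg
        log.config = cfg
        log.config_hash = cfg.config_hash()
        by_mouse.setdefault(log.mouse_id, []).append(log)
    for mouse_logs in by_mouse.values():
        mouse_logs.sort(key=lambda lg: lg.session_index)
    mice = pd.DataFrame(manifest["mice"]).set_index("mouse_id")
    return ProtocolDataset(mice=mice, logs=by_mouse, protocol=protocol,
                           session_config=fr5_cfg)


def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration into group specs and protocol objects.

    Schema::

        seed: 1
        groups:
          - label: control
            n: 25
            traits: {active_rate: [6.0, 0.4], ...}   # [location, scale]
        protocol: {n_fr1_sessions: 2, n_fr5_sessions: 3}
        session: {pellet_period_1_s: 1500.0, ...}    # optional overrides
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        groups = [
            GroupSpec(
                label=g["label"],
                n=int(g["n"]),
                traits={k: (float(v[0]), float(v[1]))
                        for k, v in (g.get("traits") or {}).items()},
            )
            for g in raw.get("groups", [])
        ]
        protocol = ProtocolConfig(
            **{**raw.get("protocol", {}), "seed": int(raw.get("seed", 0))}
        )
        session = SessionConfig(session_kind="fr", **(raw.get("session") or {}))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed configuration {path}: {exc}") from exc
    if not groups:
        raise ValueError(f"configuration {path} defines no groups")
    return {
        "groups": groups,
        "protocol": protocol,
        "session": session,
        "control": raw.get("control", groups[0].label),
        "seed": int(raw.get("seed", 0)),
    }


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seed, versions, outputs."""

    seed: int
    config: Mapping = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_output(self, stage: str, path: str | Path) -> None:
        self.outputs[stage] = str(path)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        missing = [p for p in self.outputs.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"manifest references missing outputs: {missing}")
        payload = {
            "seed": self.seed,
            "config": _jsonable(self.config),
            "outputs": self.outputs,
            "software_version": self.software_version,
            "timestamp": self.timestamp,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj
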