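"""Reading and writing event tables, protocol configs and curve exports.

Event tables are UTF-8 CSV with header ``cell_id,granule_id,time,event,
diabetic``; the stimulation protocol travels separately as a small YAML
config (keys ``pulse_starts``, ``pulse_duration``, ``observation_end``),
never inferred from the data.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .model import EventDataset, StimulusProtocol, SurvivalCurve


def read_protocol(path) -> StimulusProtocol:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    try:
        return StimulusProtocol(
            tuple(cfg["pulse_starts"]),
            float(cfg["pulse_duration"]),
            float(cfg["observation_end"]),
        )
    except KeyError as exc:  # pragma: no cover - error path
        raise ValueError(f"protocol config missing key {exc}") from exc


def write_protocol(protocol: StimulusProtocol, path) -> None:
    cfg = {
        "pulse_starts": list(protocol.pulse_starts),
        "pulse_duration": protocol.pulse_duration,
        "observation_end": protocol.observation_end,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh)


def read_events(path, protocol: StimulusProtocol) -> EventDataset:
    df = pd.read_csv(path)
    return EventDataset(df, protocol)


def write_events(dataset: EventDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def write_curves(curves: dict[str, SurvivalCurve], path,
                 covariate: int | None = None) -> None:
    """Export a set of curves as long-format CSV (time, value, component
    [, covariate])."""
    frames = []
    for name, curve in curves.items():
        frame = pd.DataFrame({
            "time": curve.times,
            "value": curve.values,
            "component": name or curve.label,
        })
        if covariate is not None:
            frame["covariate"] = covariate
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
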