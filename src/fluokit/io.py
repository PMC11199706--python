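"""Delimited-text and TIFF readers/writers for the package's data types.

Recordings, schedules, dose tables and processed traces travel as plain
CSV with a key-value sidecar ('<path>.meta') carrying the sampling rate,
seed and any ground-truth parameters; imaging stacks and ROI masks use
TIFF via tifffile.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import RoiMask
from .photometry import ProcessedTrace
from .simulate import EventSchedule, PixelStack, TwoChannelRecording

__all__ = [
    "write_recording", "read_recording",
    "write_schedule", "read_schedule",
    "write_stack", "read_stack",
    "write_mask", "read_mask",
    "write_dose_table", "read_dose_table",
    "write_processed_trace", "read_processed_trace",
]


def _write_meta(path: Path, meta: dict) -> None:
    lines = [f"{k}: {v}" for k, v in meta.items()]
    Path(str(path) + ".meta").write_text("\n".join(lines) + "\n")


def _read_meta(path: Path) -> dict:
    p = Path(str(path) + ".meta")
    meta = {}
    if p.exists():
        for line in p.read_text().splitlines():
            if ":" in line:
                k, v = line.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_schedule(schedule: EventSchedule, path) -> None:
    df = pd.DataFrame(list(schedule.events),
                      columns=["time_s", "label", "duration_s"])
    df.to_csv(path, index=False)
    _write_meta(Path(path), {"session_length": schedule.session_length,
                             "variant": schedule.variant})


def read_schedule(path) -> EventSchedule:
    df = pd.read_csv(path)
    meta = _read_meta(Path(path))
    events = [(float(r.time_s), str(r.label), float(r.duration_s))
              for r in df.itertuples()]
    length = float(meta.get("session_length",
                            max((t + d for t, _, d in events), default=0.0)))
    return EventSchedule(events, length, meta.get("variant", "custom"))


def write_recording(rec: TwoChannelRecording, path, events_path=None) -> None:
    df = pd.DataFrame({"time_s": rec.t, "signal": rec.signal,
                       "control": rec.control})
    df.to_csv(path, index=False)
    meta = {"rate": rec.rate}
    meta.update(rec.meta)
    _write_meta(Path(path), meta)
    if events_path is not None:
        write_schedule(rec.events, events_path)


def read_recording(path, events_path=None) -> TwoChannelRecording:
    df = pd.read_csv(path)
    meta = _read_meta(Path(path))
    t = df["time_s"].to_numpy()
    rate = float(meta.get("rate", 1.0 / np.median(np.diff(t))))
    if events_path is not None:
        events = read_schedule(events_path)
    else:
        events = EventSchedule((), float(t[-1] + 1.0 / rate))
    extra = {k: v for k, v in meta.items() if k != "rate"}
    return TwoChannelRecording(rate=rate, t=t,
                               signal=df["signal"].to_numpy(),
                               control=df["control"].to_numpy(),
                               events=events, meta=extra)


def write_stack(stack: PixelStack, path) -> None:
    """Write a pixels x frames stack as a TIFF (reference as a 2nd series)."""
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {"rate": stack.rate}
    if stack.membrane_mask_truth is not None:
        meta["membrane_mask_truth"] = "".join(
            "1" if m else "0" for m in stack.membrane_mask_truth)
    _write_meta(Path(path), meta)
    if stack.reference is not None:
        ref_path = Path(path).with_suffix(".ref.tif")
        tifffile.imwrite(ref_path, stack.reference.astype(np.float32))


def read_stack(path) -> PixelStack:
    data = np.asarray(tifffile.imread(path), dtype=float)
    meta = _read_meta(Path(path))
    rate = float(meta.get("rate", 1.0))
    truth = None
    if "membrane_mask_truth" in meta:
        truth = np.array([c == "1" for c in meta["membrane_mask_truth"]])
    ref_path = Path(path).with_suffix(".ref.tif")
    ref = np.asarray(tifffile.imread(ref_path), dtype=float) if ref_path.exists() else None
    return PixelStack(data=data, rate=rate, membrane_mask_truth=truth,
                      reference=ref)


def write_mask(mask: RoiMask, path) -> None:
    tifffile.imwrite(path, mask.selected.astype(np.uint8))
    _write_meta(Path(path), {"method": mask.method,
                             "threshold_used": mask.threshold_used})


def read_mask(path) -> RoiMask:
    sel = np.asarray(tifffile.imread(path)).astype(bool)
    meta = _read_meta(Path(path))
    return RoiMask(selected=sel, method=meta.get("method", "unknown"),
                   threshold_used=float(meta.get("threshold_used", "nan")))


def write_dose_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
    _write_meta(Path(path), {"normalized": table.attrs.get("normalized", False)})


def read_dose_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    meta = _read_meta(Path(path))
    df.attrs["normalized"] = meta.get("normalized", "False") == "True"
    return df


def write_processed_trace(trace: ProcessedTrace, path) -> None:
    pd.DataFrame({"time_s": trace.t, "value": trace.value}).to_csv(path, index=False)
    sidecar = {
        "variant": trace.variant,
        "unit": trace.unit,
        "baseline_window": list(trace.baseline_window) if trace.baseline_window else None,
        "provenance": trace.provenance,
    }
    Path(str(path) + ".provenance.json").write_text(json.dumps(sidecar, indent=2))


def read_processed_trace(path) -> ProcessedTrace:
    df = pd.read_csv(path)
    sidecar = json.loads(Path(str(path) + ".provenance.json").read_text())
    bw = sidecar.get("baseline_window")
    return ProcessedTrace(t=df["time_s"].to_numpy(), value=df["value"].to_numpy(),
                          variant=sidecar["variant"], unit=sidecar["unit"],
                          baseline_window=tuple(bw) if bw else None,
                          provenance=sidecar.get("provenance", []))
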