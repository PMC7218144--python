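"""Reading and writing multichannel ECoG recordings with task annotations.

A recording on disk is the signal container (CSV, HDF5 or EDF) plus a JSON
sidecar carrying the sampling rate, the alternating control/active block
annotations (shared by every channel, since the task is synchronized across
the grid) and optional ground-truth channel labels::

    {"fs": 1200,
     "blocks": [{"condition": "active", "story_id": 1,
                 "start_sample": 36000, "end_sample": 72000}, ...],
     "labels": {"ch01": "PRC", ...}}

Sample indexing is 0-based and block intervals are half-open ``[start, end)``.
Amplitudes are carried as-is (nominally microvolts); nothing is rescaled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .errors import FormatError, ValidationError

PRC = "PRC"
NRC = "NRC"

Condition = Literal["control", "active"]
Label = Literal["PRC", "NRC"]


@dataclass(frozen=True)
class BlockAnnotation:
    """One task block: condition, optional story identity, sample interval.

    ``start_sample`` is inclusive, ``end_sample`` exclusive. Active blocks
    carry a ``story_id`` (1-5 in the default paradigm); control blocks do not.
    """

    condition: Condition
    start_sample: int
    end_sample: int
    story_id: Optional[int] = None

    def __post_init__(self):
        if self.condition not in ("control", "active"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.start_sample < 0 or self.end_sample <= self.start_sample:
            raise ValidationError(
                f"bad block interval [{self.start_sample}, {self.end_sample})"
            )
        if self.condition == "control" and self.story_id is not None:
            raise ValidationError("control blocks must not carry a story_id")
        if self.condition == "active" and self.story_id is None:
            raise ValidationError("active blocks must carry a story_id")

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def shifted(self, offset: int) -> "BlockAnnotation":
        return replace(
            self,
            start_sample=self.start_sample + offset,
            end_sample=self.end_sample + offset,
        )


@dataclass
class AnnotatedRecording:
    """One channel's continuous signal plus its task annotations.

    Fields
    ------
    channel_id : str
    samples : 1-D float array, amplitudes in the units of the source file
    fs : sampling rate in Hz (> 0), nominally 1200
    annotations : block annotations, non-overlapping and sorted by start
    truth_label : optional "PRC"/"NRC" ground truth (from stimulation mapping)
    """

    channel_id: str
    samples: np.ndarray
    fs: float
    annotations: list[BlockAnnotation] = field(default_factory=list)
    truth_label: Optional[Label] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.truth_label not in (None, PRC, NRC):
            raise ValidationError(f"unknown truth label {self.truth_label!r}")
        validate_annotations(self.annotations, n_samples=len(self.samples))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def validate_annotations(
    annotations: Sequence[BlockAnnotation], n_samples: int | None = None
) -> None:
    """Check ordering, non-overlap and bounds of a block annotation list."""
    for prev, cur in zip(annotations, annotations[1:]):
        if cur.start_sample < prev.start_sample:
            raise ValidationError(
                f"annotations out of order: block at {cur.start_sample} follows "
                f"block at {prev.start_sample}"
            )
        if cur.start_sample < prev.end_sample:
            raise ValidationError(
                f"overlapping annotations: [{prev.start_sample}, {prev.end_sample}) "
                f"and [{cur.start_sample}, {cur.end_sample})"
            )
    if n_samples is not None and annotations:
        last = max(a.end_sample for a in annotations)
        if last > n_samples:
            raise ValidationError(
                f"annotation end {last} exceeds signal length {n_samples}"
            )


# ---------------------------------------------------------------------------
# sidecar


def sidecar_path(path: Path | str) -> Path:
    return Path(str(path) + ".json")


def _blocks_to_json(annotations: Iterable[BlockAnnotation]) -> list[dict]:
    out = []
    for a in annotations:
        d = {
            "condition": a.condition,
            "start_sample": int(a.start_sample),
            "end_sample": int(a.end_sample),
        }
        if a.story_id is not None:
            d["story_id"] = int(a.story_id)
        out.append(d)
    return out


def _blocks_from_json(blocks: Iterable[dict]) -> list[BlockAnnotation]:
    return [
        BlockAnnotation(
            condition=b["condition"],
            start_sample=int(b["start_sample"]),
            end_sample=int(b["end_sample"]),
            story_id=b.get("story_id"),
        )
        for b in blocks
    ]


def write_sidecar(
    path: Path | str,
    fs: float,
    annotations: Sequence[BlockAnnotation],
    labels: dict[str, str] | None = None,
) -> Path:
    sc = sidecar_path(path)
    payload = {"fs": fs, "blocks": _blocks_to_json(annotations)}
    if labels:
        payload["labels"] = dict(labels)
    sc.write_text(json.dumps(payload, indent=1))
    return sc


def read_sidecar(path: Path | str) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        return {}
    payload = json.loads(sc.read_text())
    if "blocks" in payload:
        payload["blocks"] = _blocks_from_json(payload["blocks"])
    return payload


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(
    path: Path | str, format: Literal["edf", "csv", "hdf5"]
) -> list[AnnotatedRecording]:
    """Read a multichannel recording; returns one record per channel.

    CSV and HDF5 round-trip samples exactly; EDF is subject to its 16-bit
    quantization. Annotations and labels come from the JSON sidecar when
    present and may be attached later otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read recording: no such file {path}")
    side = read_sidecar(path)
    blocks = side.get("blocks", [])
    labels = side.get("labels", {})

    if format == "csv":
        channel_ids, data, fs = _read_csv(path, side)
    elif format == "hdf5":
        channel_ids, data, fs = _read_hdf5(path)
    elif format == "edf":
        channel_ids, data, fs = _read_edf(path)
    else:
        raise FormatError(f"unknown recording format {format!r}")

    if not fs or fs <= 0:
        raise FormatError(f"missing or non-positive sampling rate in {path}")

    return [
        AnnotatedRecording(
            channel_id=cid,
            samples=sig,
            fs=fs,
            annotations=list(blocks),
            truth_label=labels.get(cid),
        )
        for cid, sig in zip(channel_ids, data)
    ]


def _read_csv(path: Path, side: dict):
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    fs = side.get("fs")
    if fs is None:
        raise FormatError(f"csv recordings need fs in the sidecar: {sidecar_path(path)}")
    return list(df.columns), [df[c].to_numpy(dtype=np.float64) for c in df.columns], float(fs)


def _read_hdf5(path: Path):
    import h5py

    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"{path} lacks the /signals group")
        grp = f["signals"]
        fs = grp.attrs.get("fs", f.attrs.get("fs"))
        if fs is None:
            raise FormatError(f"{path} lacks an fs attribute")
        # insertion (creation) order preserves the written channel order
        ids = list(grp.keys())
        order = grp.attrs.get("channel_order")
        if order is not None:
            ids = [s if isinstance(s, str) else s.decode() for s in order]
        data = [np.asarray(grp[c][()], dtype=np.float64) for c in ids]
    return ids, data, float(fs)


def _read_edf(path: Path):
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # mne scales EDF voltages to volts; restore microvolts, the package unit
    data = [sig * 1e6 for sig in raw.get_data()]
    return list(raw.ch_names), data, fs


def write_recording(
    recordings: Sequence[AnnotatedRecording],
    path: Path | str,
    format: Literal["csv", "hdf5"],
) -> None:
    """Write channels to a CSV or HDF5 container plus a JSON sidecar.

    All recordings must share one sampling rate. Annotations are taken from
    the first channel (the task is grid-synchronized); truth labels, where
    set, go to the sidecar's label map.
    """
    if not recordings:
        raise ValidationError("no recordings to write")
    fs = {r.fs for r in recordings}
    if len(fs) != 1:
        raise ValidationError(f"mixed sampling rates {sorted(fs)}; write one file per rate")
    fs = fs.pop()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if format == "csv":
        import pandas as pd

        # 17 significant digits round-trips IEEE doubles exactly
        pd.DataFrame({r.channel_id: r.samples for r in recordings}).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            grp = f.create_group("signals")
            grp.attrs["fs"] = fs
            grp.attrs["channel_order"] = [r.channel_id for r in recordings]
            for r in recordings:
                grp.create_dataset(r.channel_id, data=r.samples)
    else:
        raise FormatError(f"unsupported write format {format!r}")

    labels = {r.channel_id: r.truth_label for r in recordings if r.truth_label}
    write_sidecar(path, fs, recordings[0].annotations, labels)
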