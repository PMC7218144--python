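"""Step 1: trim to the task interval, cut uniform blocks, slide windows.

The task paradigm alternates 30 s "control" (broadband noise) and "active"
(story listening) blocks at a nominal 1200 Hz, so a default recording carries
10 x 30 s x 1200 = 360,000 samples once the spontaneous lead-in and trailing
activity are discarded. Windows never straddle block boundaries and windows
that would run past the end of a block are dropped rather than padded, which
keeps per-window statistics unbiased and makes the window count exactly
``floor((L - width) / stride) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .signal_io import AnnotatedRecording, BlockAnnotation

#: defaults of the story-listening paradigm
BLOCK_DURATION_S = 30.0
WINDOW_WIDTH = 600
WINDOW_STRIDE = 100
EXPECTED_BLOCKS = 10


def trim_to_task(rec: AnnotatedRecording) -> AnnotatedRecording:
    """Crop a recording to [first block start, last block end).

    Spontaneous activity before the first annotated block and trailing signal
    after the last one are discarded; annotations are re-indexed to the new
    origin. Idempotent on already-trimmed recordings.
    """
    if not rec.annotations:
        raise ValidationError(f"channel {rec.channel_id}: no annotations to trim to")
    start = rec.annotations[0].start_sample
    end = max(a.end_sample for a in rec.annotations)
    return AnnotatedRecording(
        channel_id=rec.channel_id,
        samples=rec.samples[start:end],
        fs=rec.fs,
        annotations=[a.shifted(-start) for a in rec.annotations],
        truth_label=rec.truth_label,
    )


@dataclass
class BlockSet:
    """Per-block sample slices of one channel, in annotation order."""

    channel_id: str
    fs: float
    blocks: list[tuple[BlockAnnotation, np.ndarray]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.blocks)

    def active(self) -> list[tuple[BlockAnnotation, np.ndarray]]:
        return [(a, x) for a, x in self.blocks if a.condition == "active"]

    def control(self) -> list[tuple[BlockAnnotation, np.ndarray]]:
        return [(a, x) for a, x in self.blocks if a.condition == "control"]


def extract_blocks(
    rec: AnnotatedRecording, require_uniform: bool = True
) -> BlockSet:
    """Slice a trimmed recording into its annotated blocks.

    With ``require_uniform`` every block must have the same length (the
    paradigm guarantees this after trimming); a ragged block raises and
    names the offending index.
    """
    if not rec.annotations:
        raise ValidationError(f"channel {rec.channel_id}: no annotations")
    lengths = {a.n_samples for a in rec.annotations}
    if require_uniform and len(lengths) != 1:
        bad = next(
            i
            for i, a in enumerate(rec.annotations)
            if a.n_samples != rec.annotations[0].n_samples
        )
        raise ValidationError(
            f"channel {rec.channel_id}: ragged block lengths {sorted(lengths)} "
            f"(first mismatch at block {bad})"
        )
    blocks = [
        (a, rec.samples[a.start_sample : a.end_sample]) for a in rec.annotations
    ]
    return BlockSet(channel_id=rec.channel_id, fs=rec.fs, blocks=blocks)


@dataclass
class WindowSet:
    """Overlapping fixed-width windows fully contained in one block."""

    width: int
    stride: int
    start_indices: np.ndarray
    windows: np.ndarray  # shape (n_windows, width), a view where possible

    def __len__(self) -> int:
        return len(self.start_indices)


def n_windows(length: int, width: int, stride: int) -> int:
    """Number of full windows of `width` at spacing `stride` in `length` samples."""
    if width > length:
        return 0
    return (length - width) // stride + 1


def sliding_windows(
    block: np.ndarray, width: int = WINDOW_WIDTH, stride: int = WINDOW_STRIDE
) -> WindowSet:
    """Cut one block into overlapping windows (no padding, no straddling).

    The default 600-sample width at 1200 Hz is 0.5 s of signal advanced in
    100-sample (1/12 s) steps, giving 355 windows per 36,000-sample block.
    """
    block = np.asarray(block)
    if width < 1 or stride < 1:
        raise ValidationError(f"width and stride must be >= 1, got {width}, {stride}")
    if width > len(block):
        raise ValidationError(
            f"window width {width} exceeds block length {len(block)}"
        )
    count = n_windows(len(block), width, stride)
    starts = np.arange(count) * stride
    view = np.lib.stride_tricks.sliding_window_view(block, width)[::stride][:count]
    return WindowSet(width=width, stride=stride, start_indices=starts, windows=view)
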