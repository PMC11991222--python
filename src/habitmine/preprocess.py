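"""Turning labelled event streams into fixed-size index-encoded windows.

The front end treats sensor events like words in a text corpus: each event
is tokenized to ``sensor_id + value`` (``"M011ON"``), tokens are indexed by
descending frequency (most frequent token -> index 1; 0 is reserved for
padding), and the stream is cut into fixed-length sensor-event windows
(SEW) that advance one event at a time, left-padded with zeros while the
history is still short.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .casas import SensorEvent

PAD_INDEX = 0
PAD_TOKEN = "<PAD>"
UNK_TOKEN = "<UNK>"

#: Default width (in sensor units, e.g. degrees C) of the bins used to
#: discretise numeric sensor values before tokenization.
DEFAULT_NUMERIC_BIN_WIDTH = 5.0


def tokenize_event(event: SensorEvent, *, numeric_bin_width: float = DEFAULT_NUMERIC_BIN_WIDTH) -> str:
    """Tokenize one event, ignoring its timestamp.

    Categorical values concatenate directly (``("M011","ON") -> "M011ON"``).
    Numeric values (temperature sensors) are discretised into fixed-width
    bins: ``("T001","21.5")`` with bin width 5 -> ``"T001_B4"``.
    """
    try:
        numeric = float(event.value)
    except ValueError:
        return f"{event.sensor_id}{event.value}"
    bin_index = math.floor(numeric / numeric_bin_width)
    return f"{event.sensor_id}_B{bin_index}"


class Vocabulary:
    """Frequency-ordered token index map.

    Index 0 is reserved for padding; indices ``1..V`` are assigned by
    descending token frequency with lexicographic tie-breaks, so the map is
    deterministic for a fixed input. Unknown tokens at encode time map to
    the reserved UNK index ``V + 1``. Build it from the training split only.
    """

    def __init__(self, token_to_index: dict[str, int], frequencies: dict[str, int]):
        self.token_to_index = dict(token_to_index)
        self.frequencies = dict(frequencies)
        self._index_to_token = {i: t for t, i in self.token_to_index.items()}

    @classmethod
    def from_tokens(cls, tokens: Iterable[str]) -> "Vocabulary":
        counts = Counter(tokens)
        if not counts:
            raise ValueError("cannot build a vocabulary from an empty token stream")
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        mapping = {token: i for i, (token, _) in enumerate(ordered, start=1)}
        return cls(mapping, dict(counts))

    @property
    def size(self) -> int:
        """Number of known tokens V (excluding padding and UNK)."""
        return len(self.token_to_index)

    @property
    def unk_index(self) -> int:
        return self.size + 1

    @property
    def n_indices(self) -> int:
        """Total index range: padding + V tokens + UNK."""
        return self.size + 2

    def encode(self, token: str) -> int:
        return self.token_to_index.get(token, self.unk_index)

    def encode_sequence(self, tokens: Sequence[str]) -> np.ndarray:
        return np.fromiter((self.encode(t) for t in tokens), dtype=np.int64, count=len(tokens))

    def decode(self, index: int) -> str:
        if index == PAD_INDEX:
            return PAD_TOKEN
        if index == self.unk_index:
            return UNK_TOKEN
        return self._index_to_token[index]

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("token\tindex\tcount\n")
            for token, index in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{index}\t{self.frequencies.get(token, 0)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        freqs: dict[str, int] = {}
        with Path(path).open("r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                token, index, count = line.rstrip("\n").split("\t")
                mapping[token] = int(index)
                freqs[token] = int(count)
        return cls(mapping, freqs)


@dataclass(frozen=True)
class EventWindow:
    """One fixed-length index-encoded window with its activity label."""

    indices: np.ndarray       # shape (W,), zeros only as a contiguous prefix
    label: str
    end_timestamp: datetime


class WindowSet:
    """A batch of sensor-event windows stored as flat arrays.

    ``X`` is an ``(N, W)`` integer matrix (rows are windows, left-padded
    with zeros), ``labels`` the per-window activity labels and
    ``end_timestamps`` the time of each window's last real event.
    """

    def __init__(self, X: np.ndarray, labels: list[str], end_timestamps: list[datetime]):
        if not (len(X) == len(labels) == len(end_timestamps)):
            raise ValueError("X, labels and end_timestamps must have equal length")
        self.X = X
        self.labels = labels
        self.end_timestamps = end_timestamps

    def __len__(self) -> int:
        return len(self.X)

    def __getitem__(self, i: int) -> EventWindow:
        return EventWindow(self.X[i], self.labels[i], self.end_timestamps[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def window_size(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self):
        """Flat integer matrix + label column, for inspection/export."""
        import pandas as pd

        df = pd.DataFrame(self.X, columns=[f"e{i}" for i in range(self.window_size)])
        df["label"] = self.labels
        df["end_timestamp"] = [t.isoformat() for t in self.end_timestamps]
        return df


def segment_windows(
    labelled_events: Sequence[tuple[SensorEvent, str]],
    vocabulary: Vocabulary,
    window_size: int,
    *,
    step: int = 1,
    label_mode: str = "last",
    numeric_bin_width: float = DEFAULT_NUMERIC_BIN_WIDTH,
) -> WindowSet:
    """Cut a labelled event stream into sensor-event windows.

    One window ends at every ``step``-th event counted backwards from the
    final event (for step 1, at every event — recognition fires each time a
    new event arrives), holding the ``window_size`` most recent event
    indices, left-padded with zeros when fewer events precede. The window
    count is ``ceil(N / step)``.

    ``label_mode="last"`` (default) labels a window with its last event's
    activity — the activity being recognised *now*; ``"majority"`` uses the
    most common label in the window (ties broken by the later label).
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if label_mode not in ("last", "majority"):
        raise ValueError(f"unknown label_mode {label_mode!r}")

    n = len(labelled_events)
    if n == 0:
        return WindowSet(np.zeros((0, window_size), dtype=np.int64), [], [])

    tokens = [tokenize_event(ev, numeric_bin_width=numeric_bin_width) for ev, _ in labelled_events]
    indices = vocabulary.encode_sequence(tokens)
    padded = np.concatenate([np.zeros(window_size - 1, dtype=np.int64), indices])
    # all candidate windows: row k ends at event k
    all_windows = np.lib.stride_tricks.sliding_window_view(padded, window_size)

    # windows end at events N-1, N-1-step, ... (0-based), emitted in time order
    ends = list(range(n - 1, -1, -step))[::-1]

    X = all_windows[ends].copy()
    end_ts = [labelled_events[e][0].timestamp for e in ends]
    if label_mode == "last":
        labels = [labelled_events[e][1] for e in ends]
    else:
        labels = []
        for e in ends:
            lo = max(0, e - window_size + 1)
            window_labels = [labelled_events[i][1] for i in range(lo, e + 1)]
            best = max(Counter(window_labels).items(),
                       key=lambda kv: (kv[1], len(window_labels) - 1 - window_labels[::-1].index(kv[0])))
            labels.append(best[0])
    return WindowSet(X, labels, end_ts)
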