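"""Fixed-length windowing, one-hot encoding, and prediction stitching.

Long RNAs are cut into windows of length ``L`` (default 200) with a
configurable step; the last window is right-padded with ``-`` and a
validity mask marks real bases.  Windows are encoded as 5xL one-hot
matrices with channel order ``-``, ``U``, ``G``, ``C``, ``A`` (so an
``A`` column reads ``00001`` and a padding column ``10000``).  Labels
come from the exterior-loop labeling of the parent structure, sliced
per window, with padding labeled 0 under mask 0.  Per-window
probabilities are stitched back onto the parent: padding is discarded
and a base covered by several windows receives the arithmetic mean of
its predictions.

Dataset construction defaults to non-overlapping windows
(``step = L``); inference defaults to half-overlapping windows with
averaging (``step = L // 2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exterior import label_exterior
from .struct_io import SecondaryStructure

__all__ = [
    "Window",
    "WindowSet",
    "make_windows",
    "encode_onehot",
    "decode_onehot",
    "encode_window_set",
    "build_labels",
    "stitch_predictions",
    "CHANNELS",
    "PAD",
]

PAD = "-"
#: One-hot channel order; channel index of a symbol is its position here.
CHANNELS = "-UGCA"
_SYM_TO_CHANNEL = {s: k for k, s in enumerate(CHANNELS)}


@dataclass
class Window:
    offset: int
    sequence: str  # padded to window length, over {A,C,G,U,-}
    mask: np.ndarray  # uint8, 1 on real bases


@dataclass
class WindowSet:
    parent_length: int
    window_length: int
    step: int
    windows: list[Window]

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(sequence: str, L: int = 200, step: int | None = None) -> WindowSet:
    """Cut a sequence into length-``L`` windows at stride ``step``.

    Windows start at 0, step, 2*step, ... while the start is inside the
    sequence; the final window is right-padded with ``-``.  A sequence
    shorter than ``L`` yields a single padded window.
    """
    if not sequence:
        raise ValueError("cannot window an empty sequence")
    if step is None:
        step = L
    if not 1 <= step <= L:
        raise ValueError(f"step must satisfy 1 <= step <= L, got {step}")
    n = len(sequence)
    windows = []
    for offset in range(0, n, step):
        chunk = sequence[offset : offset + L]
        pad = L - len(chunk)
        mask = np.ones(L, dtype=np.uint8)
        if pad:
            mask[len(chunk) :] = 0
            chunk = chunk + PAD * pad
        windows.append(Window(offset, chunk, mask))
    return WindowSet(n, L, step, windows)


def encode_onehot(window: Window) -> np.ndarray:
    """5xL one-hot encoding of one window (channels ``-UGCA``)."""
    L = len(window.sequence)
    mat = np.zeros((len(CHANNELS), L), dtype=np.float32)
    for k, sym in enumerate(window.sequence):
        try:
            mat[_SYM_TO_CHANNEL[sym], k] = 1.0
        except KeyError:
            raise ValueError(f"unknown symbol {sym!r} at window position {k}") from None
    return mat


def decode_onehot(mat: np.ndarray) -> str:
    """Inverse of :func:`encode_onehot`."""
    if mat.shape[0] != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channels, got {mat.shape[0]}")
    if not np.all(mat.sum(axis=0) == 1):
        raise ValueError("not a one-hot matrix: some column does not sum to 1")
    return "".join(CHANNELS[k] for k in mat.argmax(axis=0))


def encode_window_set(ws: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Stacked encodings (n_windows, 5, L) and masks (n_windows, L)."""
    x = np.stack([encode_onehot(w) for w in ws.windows])
    m = np.stack([w.mask for w in ws.windows])
    return x, m


def build_labels(
    structure: SecondaryStructure, window_set: WindowSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window exterior labels and masks for a known structure.

    Returns ``(labels, masks)`` each of shape (n_windows, L); padding
    positions carry label 0 and mask 0.
    """
    if len(structure.sequence) != window_set.parent_length:
        raise ValueError(
            f"structure length {len(structure.sequence)} != window-set "
            f"parent length {window_set.parent_length}"
        )
    full = label_exterior(structure)
    L = window_set.window_length
    labels = np.zeros((len(window_set), L), dtype=np.int8)
    masks = np.zeros((len(window_set), L), dtype=np.uint8)
    for wi, w in enumerate(window_set.windows):
        chunk = full[w.offset : w.offset + L]
        labels[wi, : len(chunk)] = chunk
        masks[wi] = w.mask
    return labels, masks


def stitch_predictions(
    window_probs: np.ndarray, window_set: WindowSet
) -> np.ndarray:
    """Average per-window probabilities back onto the parent sequence.

    ``window_probs`` has shape (n_windows, L); output has length
    ``parent_length``.  Padding positions are discarded; a base covered
    by k windows gets the mean of its k predictions.
    """
    window_probs = np.asarray(window_probs, dtype=float)
    if window_probs.shape != (len(window_set), window_set.window_length):
        raise ValueError(
            f"window_probs shape {window_probs.shape} != "
            f"({len(window_set)}, {window_set.window_length})"
        )
    n = window_set.parent_length
    total = np.zeros(n)
    count = np.zeros(n)
    for wi, w in enumerate(window_set.windows):
        real = int(w.mask.sum())
        sl = slice(w.offset, w.offset + real)
        total[sl] += window_probs[wi, :real]
        count[sl] += 1
    if np.any(count == 0):
        missing = int(np.flatnonzero(count == 0)[0])
        raise ValueError(f"coverage gap: position {missing} not in any window")
    return total / count
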