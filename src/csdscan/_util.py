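"""Shared helpers: seeded random streams, genomic windows, interval math."""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, *names) -> np.random.Generator:
    """Return a named random stream derived deterministically from one seed.

    Every source of randomness in the package draws from a stream obtained
    here, so a single integer seed reproduces any stage in isolation.
    """
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def windows(chrom_length: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Tile ``[0, chrom_length)`` with half-open sliding windows.

    Returns an ``(n, 2)`` int array of 0-based ``[start, end)`` pairs; the last
    window is clipped to the chromosome end.
    """
    if step_bp <= 0 or window_bp < step_bp:
        raise ValueError("require window_bp >= step_bp > 0")
    if chrom_length <= 0:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.arange(0, chrom_length, step_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, chrom_length)
    return np.stack([starts, ends], axis=1)


def sites_in_window(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Boolean mask of 1-based positions falling in 0-based ``[start, end)``."""
    pos0 = np.asarray(pos) - 1
    return (pos0 >= start) & (pos0 < end)


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the overlap of two 0-based half-open intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def jaccard(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Jaccard similarity of two 0-based half-open intervals (bp)."""
    inter = interval_overlap(a_start, a_end, b_start, b_end)
    union = (a_end - a_start) + (b_end - b_start) - inter
    return inter / union if union > 0 else 0.0
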