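"""Shared helpers: seeded substreams and window/index conversions."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "window_slice", "check_window"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent RNG derived from a master seed and a stream name.

    Every source of randomness in the package (session synthesis, artifact
    placement, class balancing, cross-validation splits, permutations) draws
    from its own named substream so that changing one stage never perturbs
    the draws of another.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def window_slice(times: np.ndarray, window: tuple[float, float]) -> slice:
    """Slice of ``times`` (ms) covering ``window = (t_lo, t_hi)``, inclusive."""
    lo, hi = float(window[0]), float(window[1])
    if hi < lo:
        raise ValueError(f"window has t_hi < t_lo: {window}")
    idx = np.nonzero((times >= lo) & (times <= hi))[0]
    if idx.size == 0:
        raise ValueError(f"window {window} ms contains no samples "
                         f"(epoch spans {times[0]:g}..{times[-1]:g} ms)")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def check_window(times: np.ndarray, window: tuple[float, float], name: str = "window") -> None:
    # tolerate a window edge within one sample step of the epoch limits
    dt = float(times[1] - times[0]) if times.size > 1 else 0.0
    if window[0] < times[0] - dt or window[1] > times[-1] + dt:
        raise ValueError(
            f"{name} {tuple(window)} ms exceeds the epoch "
            f"({times[0]:g}..{times[-1]:g} ms)")
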