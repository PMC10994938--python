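"""Streaming glue: the frame -> SR -> tracking message contract.

Mirrors the deployed reconstruction chain in-process: frames arrive as
ordered :class:`FrameMessage` objects, an up-sampling method is applied
to each, per-frame wall time is logged, and every processed message is
handed to a sink exactly once.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np

from .image import GrayImage
from .sr_core import EDSR, ModelBundle, forward_sr, upsample_bicubic, upsample_nearest

__all__ = ["FrameMessage", "StreamError", "stream_process"]


@dataclass(frozen=True)
class FrameMessage:
    """One reconstructed frame plus the metadata the tracker needs."""

    frame: GrayImage
    timestamp: float
    index: int
    displacement: tuple[float, float, float] | None = None

    @property
    def spacing(self) -> tuple[float, float]:
        return self.frame.spacing


class StreamError(RuntimeError):
    """Sink failure; carries the partial timing log as ``.log``."""

    def __init__(self, msg: str, log: list):
        super().__init__(msg)
        self.log = log


def _resolve_method(sr_method, factor: int):
    if sr_method in (None, "none", "identity"):
        return lambda im: im
    if sr_method == "nearest":
        return lambda im: upsample_nearest(im, factor)
    if sr_method == "bicubic":
        return lambda im: upsample_bicubic(im, factor)
    if isinstance(sr_method, (EDSR, ModelBundle)):
        model = sr_method.build() if isinstance(sr_method, ModelBundle) else sr_method
        return lambda im: forward_sr(model, im)
    if callable(sr_method):
        return sr_method
    raise ValueError(f"unknown sr_method {sr_method!r}")


def stream_process(frames, sr_method, sink, factor: int = 4
                   ) -> tuple[list[FrameMessage], list[dict]]:
    """Process frames strictly in order; log wall time per frame.

    Returns (processed messages, timing log).  A sink exception halts
    the stream and re-raises as :class:`StreamError` with the partial
    log attached.
    """
    method = _resolve_method(sr_method, factor)
    out: list[FrameMessage] = []
    log: list[dict] = []
    last_index = None
    for msg in frames:
        if last_index is not None and msg.index <= last_index:
            raise ValueError("frame indices must be strictly increasing")
        last_index = msg.index
        t0 = time.perf_counter()
        processed = replace(msg, frame=method(msg.frame))
        elapsed = time.perf_counter() - t0
        try:
            sink(processed)
        except Exception as exc:
            raise StreamError(f"sink failed at frame {msg.index}: {exc}", log) from exc
        out.append(processed)
        log.append({"index": msg.index, "wall_time_s": max(elapsed, 1e-9),
                    "out_shape": processed.frame.shape})
    return out, log
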