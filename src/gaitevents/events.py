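"""Typed gait events shared by the detectors, simulator and evaluation code."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

HS = "HS"
TO = "TO"


@dataclass(frozen=True)
class GaitEvent:
    """A timestamped gait event.

    Parameters
    ----------
    kind
        ``"HS"`` (heel strike, start of stance) or ``"TO"`` (toe off,
        start of swing).
    t
        Event time in seconds from the start of the trial.
    stride
        Index of the gait cycle the event belongs to (``-1`` if not yet
        assigned to a cycle).
    source
        ``"detector"``, ``"reference"`` (insole-pressure labeling) or
        ``"truth"`` (simulator ground truth).
    """

    kind: str
    t: float
    stride: int = -1
    source: str = "detector"

    def __post_init__(self) -> None:
        if self.kind not in (HS, TO):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.t < 0:
            raise ValueError("event time must be nonnegative")


def times(events: Iterable[GaitEvent], kind: str) -> list[float]:
    """Times of all events of one kind, in order."""
    return [e.t for e in events if e.kind == kind]


def check_strictly_increasing(events: Sequence[GaitEvent]) -> None:
    """Raise if per-kind event times are not strictly increasing."""
    for kind in (HS, TO):
        ts = times(events, kind)
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValueError(f"{kind} event times not strictly increasing")
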