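"""Discrete events and the global event queue.

Components exchange timestamped messages over named ports.  The queue is
a priority queue ordered by event time; events that share a timestamp are
delivered in insertion (FIFO) order, which is what sample-then-react
sensor semantics require.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Any


class SchedulingError(ValueError):
    """Raised when an event is scheduled in the past."""


@dataclass(frozen=True)
class SimEvent:
    """A timestamped message on a component port.

    time is in minutes; value may be a real number or a symbolic token
    (e.g. a pump mode name).
    """

    time: float
    source: str
    port: str
    value: Any = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time!r}")


@dataclass
class EventQueue:
    """Time-ordered event queue with FIFO tie-breaking."""

    _heap: list[tuple[float, int, SimEvent]] = field(default_factory=list)
    _counter: int = 0

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, event: SimEvent, *, now: float = 0.0) -> None:
        if event.time < now:
            raise SchedulingError(
                f"component {event.source!r} scheduled an event at t={event.time} "
                f"but the clock is already at t={now}"
            )
        heapq.heappush(self._heap, (event.time, self._counter, event))
        self._counter += 1

    def pop(self) -> SimEvent:
        return heapq.heappop(self._heap)[2]

    def peek_time(self) -> float | None:
        return self._heap[0][0] if self._heap else None

    def as_list(self) -> list[SimEvent]:
        """Events in delivery order (non-destructive)."""
        return [e for _, _, e in sorted(self._heap, key=lambda x: (x[0], x[1]))]


def schedule_event(queue: EventQueue, event: SimEvent, *, now: float = 0.0) -> EventQueue:
    """Insert ``event`` into ``queue`` keeping (time, insertion) order."""
    queue.push(event, now=now)
    return queue
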