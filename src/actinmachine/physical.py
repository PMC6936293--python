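"""Back-of-envelope physical throughput of a droplet machine.

Signals in actin bundle networks travel as mechanical or electrical
localizations with propagation speeds of order 1e5–1e8 um/s (the low end,
1e5 um/s, being the conservative action-potential-like estimate).  For a
droplet of maximum linear size ~250 um this gives ~400 parallel input
strings processed per second; a network that stays structurally fixed for
a 10 s stability window can then execute ~4e3 computation cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhysicalEstimate", "machine_state_count", "throughput_estimate"]


@dataclass(frozen=True)
class PhysicalEstimate:
    """Signal speed (um/s), machine linear size (um), stability window (s)."""

    signal_speed: float = 1e5
    machine_size: float = 250.0
    stability_window: float = 10.0

    def __post_init__(self) -> None:
        if self.signal_speed <= 0 or self.machine_size <= 0:
            raise ValueError("speed and size must be positive")
        if self.stability_window < 0:
            raise ValueError("stability window must be non-negative")


def machine_state_count(k: int) -> int:
    """Number of machine states |S| = 2**k for a k-electrode machine."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2**k


def throughput_estimate(est: PhysicalEstimate) -> tuple[float, float]:
    """(inputs processed per second, computation cycles within the window)."""
    inputs_per_second = est.signal_speed / est.machine_size
    return inputs_per_second, inputs_per_second * est.stability_window
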