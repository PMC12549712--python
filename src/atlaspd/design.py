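"""Block-design timing for task-evoked fNIRS sessions.

A session is a pre-task baseline followed by repeated rest/task/rest cycles.
The reference protocol uses a 10 s pre-task screen, then cycles of 30 s rest,
30 s task, 50 s rest, sampled at 100 Hz for a total of 840 s.  The total
duration is authoritative: cycles that do not fill it are padded with trailing
rest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["BlockDesign", "default_design"]


@dataclass(frozen=True)
class BlockDesign:
    """Timing of a block-design session.

    Parameters
    ----------
    pre_task_s : float
        Initial baseline (blank screen) duration in seconds.
    rest_before_s, task_s, rest_after_s : float
        Durations of the rest/task/rest phases of one cycle, in seconds.
    n_cycles : int
        Number of task cycles.
    total_s : float
        Total session duration.  Must be at least long enough to contain
        the pre-task phase and all cycles; any residual is trailing rest.
    sampling_hz : float
        Sampling rate of the recording.
    """

    pre_task_s: float = 10.0
    rest_before_s: float = 30.0
    task_s: float = 30.0
    rest_after_s: float = 50.0
    n_cycles: int = 7
    total_s: float = 840.0
    sampling_hz: float = 100.0

    def __post_init__(self) -> None:
        for name in ("pre_task_s", "rest_before_s", "task_s", "rest_after_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.task_s <= 0:
            raise ValueError("task_s must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.total_s < self.pre_task_s + self.n_cycles * self.cycle_s:
            raise ValueError(
                "total_s shorter than pre-task phase plus the requested cycles"
            )
        n = self.total_s * self.sampling_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_s * sampling_hz must be an integer")

    @property
    def cycle_s(self) -> float:
        return self.rest_before_s + self.task_s + self.rest_after_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.sampling_hz))

    @classmethod
    def full(
        cls,
        pre_task_s: float = 10.0,
        rest_before_s: float = 30.0,
        task_s: float = 30.0,
        rest_after_s: float = 50.0,
        n_cycles: int = 7,
        sampling_hz: float = 100.0,
    ) -> "BlockDesign":
        """Design whose total duration is exactly pre-task + cycles."""
        total = pre_task_s + n_cycles * (rest_before_s + task_s + rest_after_s)
        return cls(pre_task_s, rest_before_s, task_s, rest_after_s,
                   n_cycles, total, sampling_hz)

    def with_sampling(self, sampling_hz: float) -> "BlockDesign":
        return replace(self, sampling_hz=sampling_hz)

    def task_onsets_s(self) -> np.ndarray:
        """Start time of every task phase, in seconds."""
        starts = self.pre_task_s + self.rest_before_s + np.arange(self.n_cycles) * self.cycle_s
        return starts

    def task_mask(self, sampling_hz: float | None = None) -> np.ndarray:
        """Boolean mask over samples that fall inside a task phase."""
        fs = self.sampling_hz if sampling_hz is None else sampling_hz
        n = int(round(self.total_s * fs))
        mask = np.zeros(n, dtype=bool)
        for t0 in self.task_onsets_s():
            i0 = int(round(t0 * fs))
            i1 = int(round((t0 + self.task_s) * fs))
            mask[i0:min(i1, n)] = True
        return mask

    def rest_mask(self, sampling_hz: float | None = None) -> np.ndarray:
        """Samples outside the task phases and after the pre-task baseline."""
        fs = self.sampling_hz if sampling_hz is None else sampling_hz
        mask = ~self.task_mask(fs)
        mask[: int(round(self.pre_task_s * fs))] = False
        return mask

    def boxcar(self, sampling_hz: float | None = None) -> np.ndarray:
        """Task regressor: 1 during task phases, 0 elsewhere."""
        return self.task_mask(sampling_hz).astype(float)


def default_design(sampling_hz: float = 100.0) -> BlockDesign:
    """The reference 840 s protocol (10 s pre-task, 7 cycles of 30/30/50 s)."""
    return BlockDesign(sampling_hz=sampling_hz)
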