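"""Breath-hold protocol timing and phase-window construction.

The experimental protocol alternates voluntary apnea (breath-hold) episodes
with normal-breathing recovery periods over a five-minute recording.  Apnea
onsets are fixed by the protocol; the instants at which each subject resumes
breathing vary and are supplied as annotations.  Phase windows are expressed
as sample-index ranges at the analysis rate (1 Hz after preprocessing) and
exclude the first ``p + 1`` samples after each transition so that, for an
order-``p`` autoregressive model, no regressor reaches across a phase
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProtocolSchedule", "PhaseWindows", "build_phase_windows"]

#: Protocol apnea onsets in seconds for the five breath-hold episodes.
DEFAULT_APNEA_ONSETS = (8.0, 50.0, 110.0, 170.0, 230.0)
#: Default breath-resume instants (25 s apnea episodes).
DEFAULT_BREATH_RESUMES = (33.0, 75.0, 135.0, 195.0, 255.0)
#: Total recording length in seconds.
DEFAULT_DURATION = 300.0


@dataclass(frozen=True)
class ProtocolSchedule:
    """Timing of a breath-hold recording.

    Parameters
    ----------
    apnea_onsets
        Instants (seconds) at which each apnea episode starts, strictly
        increasing.
    breath_resumes
        Instant (seconds) at which the subject resumed normal breathing
        after each apnea; one per onset, ``O_i < B_i < O_{i+1}``.
    total_duration
        Recording length in seconds; also the end of the last breath window.
    """

    apnea_onsets: tuple[float, ...] = DEFAULT_APNEA_ONSETS
    breath_resumes: tuple[float, ...] = DEFAULT_BREATH_RESUMES
    total_duration: float = DEFAULT_DURATION

    def __post_init__(self) -> None:
        onsets = np.asarray(self.apnea_onsets, dtype=float)
        resumes = np.asarray(self.breath_resumes, dtype=float)
        if onsets.ndim != 1 or onsets.size == 0:
            raise ValueError("apnea_onsets must be a non-empty 1-D sequence")
        if resumes.shape != onsets.shape:
            raise ValueError(
                f"need one breath resume per apnea onset "
                f"({onsets.size} onsets, {resumes.size} resumes)"
            )
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("apnea_onsets must be strictly increasing")
        next_onsets = np.append(onsets[1:], self.total_duration)
        if np.any(resumes <= onsets) or np.any(resumes >= next_onsets):
            raise ValueError("each breath resume must satisfy O_i < B_i < O_{i+1}")
        if self.total_duration < resumes[-1]:
            raise ValueError("total_duration must cover the last breath window")
        object.__setattr__(self, "apnea_onsets", tuple(onsets))
        object.__setattr__(self, "breath_resumes", tuple(resumes))

    @property
    def n_episodes(self) -> int:
        return len(self.apnea_onsets)

    def onsets_extended(self) -> np.ndarray:
        """Apnea onsets followed by the total duration (the window sentinel)."""
        return np.append(np.asarray(self.apnea_onsets), self.total_duration)

    def condition_at(self, t: np.ndarray | float) -> np.ndarray:
        """Label each time (seconds) as ``'apnea'`` or ``'breath'``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        label = np.full(t.shape, "breath", dtype=object)
        for onset, resume in zip(self.apnea_onsets, self.breath_resumes):
            label[(t >= onset) & (t < resume)] = "apnea"
        return label

    def to_dict(self) -> dict:
        return {
            "apnea_onsets": list(self.apnea_onsets),
            "breath_resumes": list(self.breath_resumes),
            "total_duration": self.total_duration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSchedule":
        return cls(
            apnea_onsets=tuple(d["apnea_onsets"]),
            breath_resumes=tuple(d["breath_resumes"]),
            total_duration=float(d["total_duration"]),
        )


@dataclass(frozen=True)
class PhaseWindows:
    """Disjoint apnea and breath sample-index windows at the analysis rate.

    ``apnea[i]`` covers ``[O_i + p + 1, B_i - 1]`` and ``breath[i]`` covers
    ``[B_i + p + 1, O_{i+1} - 1]`` (inclusive, in samples), where the last
    "onset" is the end of the recording.
    """

    apnea: tuple[np.ndarray, ...]
    breath: tuple[np.ndarray, ...]
    lag_margin: int
    rate: float
    schedule: ProtocolSchedule = field(repr=False)

    def windows(self, condition: str) -> tuple[np.ndarray, ...]:
        if condition == "apnea":
            return self.apnea
        if condition == "breath":
            return self.breath
        raise ValueError(f"unknown condition {condition!r}")

    @property
    def conditions(self) -> tuple[str, str]:
        return ("apnea", "breath")


def build_phase_windows(
    schedule: ProtocolSchedule, p: int = 4, rate: float = 1.0
) -> PhaseWindows:
    """Build apnea/breath index windows with an order-``p`` lag margin.

    Raises ``ValueError`` if any window is empty (an apnea episode shorter
    than ``p + 2`` samples leaves no usable sample).
    """
    if p < 0:
        raise ValueError("lag margin p must be non-negative")
    onsets = np.round(np.asarray(schedule.apnea_onsets) * rate).astype(int)
    resumes = np.round(np.asarray(schedule.breath_resumes) * rate).astype(int)
    end = int(round(schedule.total_duration * rate))
    next_onsets = np.append(onsets[1:], end)

    apnea, breath, empty = [], [], []
    for i, (o, b, o_next) in enumerate(zip(onsets, resumes, next_onsets)):
        m = np.arange(o + p + 1, b)  # [O_i+(p+1), ..., B_i-1]
        l = np.arange(b + p + 1, o_next)  # [B_i+(p+1), ..., O_{i+1}-1]
        if m.size == 0:
            empty.append(f"apnea window {i + 1} (O={o}, B={b})")
        if l.size == 0:
            empty.append(f"breath window {i + 1} (B={b}, next O={o_next})")
        apnea.append(m)
        breath.append(l)
    if empty:
        raise ValueError("empty phase windows: " + "; ".join(empty))
    return PhaseWindows(
        apnea=tuple(apnea),
        breath=tuple(breath),
        lag_margin=p,
        rate=rate,
        schedule=schedule,
    )
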