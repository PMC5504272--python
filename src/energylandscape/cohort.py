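"""Cohort containers shared by the synthetic generator, IO and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocess import BinaryTimeSeries, NetworkTimeSeries

__all__ = ["Participant", "CohortDataset"]


@dataclass
class Participant:
    """One participant: group label, time series and behavioural scores.

    ``binary`` may be absent when only continuous series were loaded (the
    pipeline binarizes on demand); ``truth`` carries generator ground truth
    for synthetic participants and is None for real data.
    """

    participant_id: str
    group: str  # "td" | "asd"
    continuous: NetworkTimeSeries | None = None
    binary: BinaryTimeSeries | None = None
    scores: dict[str, float] = field(default_factory=dict)
    truth: dict | None = None


@dataclass
class CohortDataset:
    """A set of participants with group labels and optional ground truth."""

    participants: list[Participant]
    network_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def group(self, label: str) -> list[Participant]:
        return [p for p in self.participants if p.group == label]

    @property
    def n(self) -> int:
        return len(self.participants)
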