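"""Ordered meiotic stage series.

The synchronized meiosis time course is described by nine ordered stages:
vegetative growth (V), pre-meiotic (P), pachytene (T0), end of prophase I
(T1), metaphase I (T2), anaphase I (T3), metaphase II (T4), anaphase II
(T5) and meiotic exit (T6).  Every stage-resolved statistic in the package
(pairwise reactivity correlations, antisense-ratio trajectories, activation
intervals, pulse windows) is oriented by this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_STAGE_LABELS: tuple[str, ...] = (
    "V", "P", "T0", "T1", "T2", "T3", "T4", "T5", "T6",
)


@dataclass(frozen=True)
class StageSeries:
    """An ordered, unique set of stage labels with 0-based ranks."""

    labels: tuple[str, ...] = DEFAULT_STAGE_LABELS
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        if len(labels) < 2:
            raise ValueError("a stage series needs at least 2 stages")
        if len(set(labels)) != len(labels):
            raise ValueError("stage labels must be unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "index", {s: i for i, s in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.index

    def __iter__(self):
        return iter(self.labels)

    def rank(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"unknown stage label {label!r}; known: {self.labels}")

    def intervals(self) -> list[tuple[str, str]]:
        """Consecutive-stage intervals, e.g. (V,P), (P,T0), ..."""
        return list(zip(self.labels[:-1], self.labels[1:]))

    def slice(self, start: str, stop: str) -> tuple[str, ...]:
        """Stages from ``start`` through ``stop`` inclusive."""
        i, j = self.rank(start), self.rank(stop)
        if i > j:
            raise ValueError(f"stage window out of order: {start}..{stop}")
        return self.labels[i : j + 1]


DEFAULT_STAGES = StageSeries()
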