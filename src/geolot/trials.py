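"""Observed trials: (anchor, sequence) pairs over the octagon alphabet."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = ["Trial", "TrialDataset"]


@dataclass(frozen=True)
class Trial:
    """One observed concept: a start position and the emitted point sequence."""

    subject_id: str
    trial_id: str
    anchor: int
    sequence: tuple[int, ...]

    def __post_init__(self):
        if not 0 <= self.anchor <= 7:
            raise ValueError(f"anchor must be in 0..7, got {self.anchor}")
        seq = tuple(int(p) for p in self.sequence)
        if len(seq) < 1:
            raise ValueError("sequence must be non-empty")
        if any(not 0 <= p <= 7 for p in seq):
            raise ValueError(f"positions must be in 0..7, got {seq}")
        object.__setattr__(self, "sequence", seq)

    @property
    def key(self) -> tuple[int, tuple[int, ...]]:
        return (self.anchor, self.sequence)


@dataclass
class TrialDataset:
    """The observed data D = (d_1, ..., d_n)."""

    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i) -> Trial:
        return self.trials[i]

    def unique_keys(self) -> list[tuple[int, tuple[int, ...]]]:
        return sorted(set(t.key for t in self.trials))

    def to_frame(self):
        import pandas as pd

        max_len = max((len(t.sequence) for t in self.trials), default=0)
        rows = []
        for t in self.trials:
            row = {"subject_id": t.subject_id, "trial_id": t.trial_id, "anchor": t.anchor}
            for k in range(max_len):
                row[f"p{k + 1}"] = t.sequence[k] if k < len(t.sequence) else None
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_keys(cls, keys: Sequence[tuple[int, Sequence[int]]], subject_id: str = "s1"):
        return cls(
            [
                Trial(subject_id, f"t{i + 1}", anchor, tuple(seq))
                for i, (anchor, seq) in enumerate(keys)
            ]
        )
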