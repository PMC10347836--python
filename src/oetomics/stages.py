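"""Developmental stage axis.

The study profiles seven ordered stages of mouse oocyte maturation and
pre-implantation development: fully grown oocyte (FGO), metaphase-II oocyte
(MII), then 1-cell, 2-cell, 4-cell, 8-cell embryos and the blastocyst (BL).
No physical time axis is attached to the stages in the source data, so the
default time coordinate is simply the stage index (0..6); rates inferred by
the kinetics module are then "per stage transition".  A different grid
(e.g. hours post-hCG) can be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError

DEFAULT_STAGES: tuple[str, ...] = ("FGO", "MII", "1C", "2C", "4C", "8C", "BL")

#: Embryo stages, i.e. post-fertilization; used for allele-specific calls.
EMBRYO_STAGES: tuple[str, ...] = ("1C", "2C", "4C", "8C", "BL")


@dataclass(frozen=True)
class StageSeries:
    """Ordered stage labels with a numeric time coordinate per stage."""

    labels: tuple[str, ...] = DEFAULT_STAGES
    times: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if self.times is None:
            object.__setattr__(self, "times", tuple(float(i) for i in range(len(labels))))
        else:
            object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(set(labels)) != len(labels):
            raise InputError("stage labels must be unique")
        if len(self.times) != len(labels):
            raise InputError("times and labels must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("stage times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown stage label: {label!r}") from None

    def time_of(self, label: str) -> float:
        return self.times[self.index(label)]

    @property
    def transitions(self) -> tuple[str, ...]:
        """Labels for consecutive stage transitions, e.g. 'FGO->MII'."""
        return tuple(
            f"{a}->{b}" for a, b in zip(self.labels[:-1], self.labels[1:])
        )

    def subset(self, labels: Sequence[str]) -> "StageSeries":
        idx = [self.index(l) for l in labels]
        return StageSeries(tuple(labels), tuple(self.times[i] for i in idx))


DEFAULT_SERIES = StageSeries()
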