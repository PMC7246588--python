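"""Stimulation protocol annotation for a continuous-cytometry run.

A run consists of a quiescent baseline, an optional agonist addition
(ADP, TRAP or CRP), a 1 uM ionomycin addition that saturates the calcium
indicator and drives fibrinogen binding to its reference level, and a
final 10 mM EGTA addition that buffers free calcium to a known mark.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .exceptions import InvalidSpecError

AGONISTS = ("ADP", "TRAP", "CRP", "none")


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing of reagent additions in a continuous run.

    Times are seconds from the start of acquisition.  Invariant:
    ``0 < baseline_end_s <= agonist_time_s < ionomycin_time_s <
    egta_time_s < run_end_s``.
    """

    baseline_end_s: float = 50.0
    agonist: str = "ADP"
    agonist_time_s: float = 50.0
    ionomycin_time_s: float = 350.0
    egta_time_s: float = 950.0
    run_end_s: float = 1010.0

    def __post_init__(self) -> None:
        if self.agonist not in AGONISTS:
            raise InvalidSpecError(f"unknown agonist {self.agonist!r}")
        ok = (
            0 < self.baseline_end_s <= self.agonist_time_s
            < self.ionomycin_time_s < self.egta_time_s < self.run_end_s
        )
        if not ok:
            raise InvalidSpecError(
                "protocol times must satisfy 0 < baseline_end <= agonist "
                "< ionomycin < EGTA < run_end"
            )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))
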