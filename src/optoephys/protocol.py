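"""Stimulation protocol: ordered photostimulation epochs."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class StimEpoch:
    onset_s: float
    offset_s: float
    freq_hz: float
    pulse_width_ms: float = 5.0
    repeat_idx: int = 1

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class StimProtocol:
    """Presentation-ordered, non-overlapping stimulation epochs.

    ``repeat_idx`` counts occurrences of each frequency in presentation
    order (1-based), matching a pseudorandomized design in which every
    drive frequency is repeated a fixed number of times.
    """

    epochs: list[StimEpoch]

    def __post_init__(self) -> None:
        eps = sorted(self.epochs, key=lambda e: e.onset_s)
        for a, b in zip(eps, eps[1:]):
            if b.onset_s < a.offset_s:
                raise DataError(
                    f"epochs overlap: [{a.onset_s}, {a.offset_s}) and "
                    f"[{b.onset_s}, {b.offset_s})"
                )
        for e in eps:
            if e.freq_hz <= 0:
                raise DataError(f"freq_hz must be positive, got {e.freq_hz}")
            if e.repeat_idx < 1:
                raise DataError(f"repeat_idx must be >= 1, got {e.repeat_idx}")
        self.epochs = eps

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def freqs_hz(self) -> list[float]:
        return sorted({e.freq_hz for e in self.epochs})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "onset_s": e.onset_s,
                    "offset_s": e.offset_s,
                    "freq_hz": e.freq_hz,
                    "pulse_width_ms": e.pulse_width_ms,
                    "repeat_idx": e.repeat_idx,
                }
                for e in self.epochs
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimProtocol":
        df = pd.read_csv(path)
        required = {"onset_s", "offset_s", "freq_hz"}
        if not required.issubset(df.columns):
            raise DataError(f"{path}: protocol CSV needs columns {sorted(required)}")
        epochs = [
            StimEpoch(
                onset_s=float(r.onset_s),
                offset_s=float(r.offset_s),
                freq_hz=float(r.freq_hz),
                pulse_width_ms=float(getattr(r, "pulse_width_ms", 5.0)),
                repeat_idx=int(getattr(r, "repeat_idx", 1)),
            )
            for r in df.itertuples()
        ]
        return cls(epochs)
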