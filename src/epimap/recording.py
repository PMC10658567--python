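"""The multichannel unipolar electrogram container and its on-disk format.

A recording directory holds ``header.json`` (sample rate, channel ids,
units, provenance), ``signals.csv`` (wide table, one column per channel,
one row per sample, mV), optionally ``reference.csv`` (a body-surface-ECG
-like lead used for ventricular beat detection) and ``layout.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .layout import ElectrodeLayout

__all__ = ["ElectrogramRecording"]


@dataclass(frozen=True)
class ElectrogramRecording:
    """Sampled unipolar electrograms V(t), one row per channel, in mV."""

    sample_rate: float                  # Hz
    signals: np.ndarray                 # (n_channels, n_samples), mV
    channel_ids: np.ndarray
    reference: np.ndarray | None = None  # optional reference lead, mV

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        ids = np.asarray(self.channel_ids, dtype=int)
        if self.sample_rate <= 0:
            raise InvalidArgumentError("sample_rate must be positive")
        if sig.ndim != 2 or sig.shape[0] != ids.size:
            raise InvalidArgumentError("signals must be (n_channels, n_samples)")
        if not np.all(np.isfinite(sig)):
            raise InvalidArgumentError("signals must be finite")
        if np.unique(ids).size != ids.size:
            raise InvalidArgumentError("channel ids must be unique")
        object.__setattr__(self, "signals", sig)
        object.__setattr__(self, "channel_ids", ids)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (sig.shape[1],):
                raise InvalidArgumentError("reference lead length must match signals")
            object.__setattr__(self, "reference", ref)

    @property
    def n_channels(self) -> int:
        return int(self.signals.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.signals.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate * 1000.0

    def channel(self, channel_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.channel_ids == channel_id)[0])
        return self.signals[idx]

    def with_signals(self, signals: np.ndarray) -> "ElectrogramRecording":
        return replace(self, signals=signals)

    # ------------------------------------------------------------------ I/O
    def save(self, out_dir, layout: ElectrodeLayout | None = None,
             provenance: dict | None = None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = {
            "sample_rate_hz": self.sample_rate,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "channel_ids": [int(c) for c in self.channel_ids],
            "units": "mV",
            "has_reference": self.reference is not None,
        }
        if provenance:
            header["provenance"] = provenance
        (out / "header.json").write_text(json.dumps(header, indent=2, sort_keys=True))
        df = pd.DataFrame(self.signals.T, columns=[str(c) for c in self.channel_ids])
        df.to_csv(out / "signals.csv", index=False, float_format="%.6g")
        if self.reference is not None:
            pd.DataFrame({"reference_mv": self.reference}).to_csv(
                out / "reference.csv", index=False, float_format="%.6g"
            )
        if layout is not None:
            layout.to_csv(out / "layout.csv")

    @classmethod
    def load(cls, in_dir) -> "ElectrogramRecording":
        src = Path(in_dir)
        header = json.loads((src / "header.json").read_text())
        df = pd.read_csv(src / "signals.csv")
        signals = df.to_numpy(float).T
        channel_ids = np.array([int(c) for c in df.columns])
        reference = None
        if header.get("has_reference") and (src / "reference.csv").exists():
            reference = pd.read_csv(src / "reference.csv")["reference_mv"].to_numpy(float)
        return cls(
            sample_rate=float(header["sample_rate_hz"]),
            signals=signals,
            channel_ids=channel_ids,
            reference=reference,
        )
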