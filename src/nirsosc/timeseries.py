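"""Uniformly sampled multi-channel chromophore concentration series.

The central in-memory container of the package: named concentration-change
channels (µM from baseline) on a shared, strictly uniform time axis.  The
canonical channels are the three chromophores resolved by broadband NIRS —
oxidised cytochrome-c-oxidase (``oxCCO``), oxygenated haemoglobin (``HbO2``)
and deoxygenated haemoglobin (``HHb``) — plus the two derived haemodynamic
composites:

* ``HbT = HHb + HbO2`` — total haemoglobin, a blood-volume proxy;
* ``HbDiff = HbO2 - HHb`` — haemoglobin difference, an oxygenation /
  oxygen-delivery proxy.

Composites are always *derived*, never stored independently, so the defining
identities hold to machine precision by construction.

Serialisation is plain delimited text (tab-separated): one ``time_s`` column
plus one column per channel, with ``#``-prefixed header lines carrying units
and provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import ChannelError, DataFormatError

#: channels the unmixing stage produces directly
CHROMOPHORE_CHANNELS = ("oxCCO", "HbO2", "HHb")
#: channels derived from the chromophores by fixed linear identities
COMPOSITE_CHANNELS = ("HbT", "HbDiff")

_TIME_UNIFORMITY_TOL = 1e-6  # seconds


@dataclass
class ChromophoreTimeSeries:
    """Named concentration-change channels on a uniform time axis.

    Parameters
    ----------
    time
        Sample times in seconds, strictly uniform (tolerance 1e-6 s).
    channels
        Mapping channel name -> 1-D array of concentration changes (µM).
        All channels must share the time axis length.
    metadata
        Free-form provenance; synthetic generators echo their ground-truth
        parameters here.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise DataFormatError("time axis must be 1-D with at least 2 samples")
        dt = np.diff(self.time)
        if np.any(np.abs(dt - dt[0]) > _TIME_UNIFORMITY_TOL):
            bad = int(np.argmax(np.abs(dt - dt[0]) > _TIME_UNIFORMITY_TOL)) + 1
            raise DataFormatError(
                f"time axis is not uniform: step deviates at row {bad} "
                f"(dt[{bad - 1}]={dt[bad - 1]!r} vs dt[0]={dt[0]!r})"
            )
        if dt[0] <= 0:
            raise DataFormatError("time axis must be strictly increasing")
        self.channels = {str(k): np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, values in self.channels.items():
            if values.shape != self.time.shape:
                raise DataFormatError(
                    f"channel {name!r} has length {values.size}, expected {self.time.size}"
                )
            if not np.all(np.isfinite(values)):
                bad = int(np.argmax(~np.isfinite(values)))
                raise DataFormatError(
                    f"channel {name!r} contains a non-finite sample at row {bad}"
                )

    # -- basic protocol ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Record length in seconds (first to last sample)."""
        return float(self.time[-1] - self.time[0])

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise ChannelError(
                f"channel {channel!r} not present; have {sorted(self.channels)}"
            ) from None

    def require(self, *names: str) -> None:
        """Raise :class:`ChannelError` naming the first missing channel."""
        for name in names:
            if name not in self.channels:
                raise ChannelError(
                    f"required channel {name!r} is missing; have {sorted(self.channels)}"
                )

    def replace_channels(self, new: Mapping[str, np.ndarray], **meta) -> "ChromophoreTimeSeries":
        """Return a copy with channels replaced and metadata extended."""
        merged = dict(self.metadata)
        merged.update(meta)
        return ChromophoreTimeSeries(self.time.copy(), dict(new), merged)

    # -- composites ----------------------------------------------------
    def with_composites(self) -> "ChromophoreTimeSeries":
        """Add HbT and HbDiff derived from HbO2 / HHb (idempotent)."""
        self.require("HbO2", "HHb")
        chans = {k: v.copy() for k, v in self.channels.items()}
        chans["HbT"] = chans["HHb"] + chans["HbO2"]
        chans["HbDiff"] = chans["HbO2"] - chans["HHb"]
        return ChromophoreTimeSeries(self.time.copy(), chans, dict(self.metadata))

    # -- dataframe / text I/O -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time})
        for name, values in self.channels.items():
            df[name] = values
        return df

    def write(self, path: str | Path) -> None:
        """Write as tab-separated text with a ``#`` metadata header."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# units: time_s=s channels=uM\n")
            if self.metadata:
                fh.write("# metadata: " + json.dumps(self.metadata, default=_json_default) + "\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ChromophoreTimeSeries":
        """Read a series written by :meth:`write` (validates schema)."""
        path = Path(path)
        metadata: dict = {}
        with path.open() as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    if line.startswith("# metadata:"):
                        metadata = json.loads(line.split(":", 1)[1])
                    pos = fh.tell()
                    continue
                fh.seek(pos)
                break
            df = pd.read_csv(fh, sep="\t")
        if "time_s" not in df.columns:
            raise DataFormatError(f"{path}: missing required 'time_s' column")
        if df.isna().any().any():
            row = int(df.isna().any(axis=1).idxmax())
            raise DataFormatError(f"{path}: NaN value at row {row}")
        channels = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
        if not channels:
            raise DataFormatError(f"{path}: no channel columns found")
        return cls(df["time_s"].to_numpy(), channels, metadata)


def derive_composites(series: ChromophoreTimeSeries) -> ChromophoreTimeSeries:
    """Functional alias for :meth:`ChromophoreTimeSeries.with_composites`."""
    return series.with_composites()


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
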