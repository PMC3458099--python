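"""Epoched multichannel trial data: containers, text I/O and artifact rejection.

The pipeline's universal currency is the :class:`EpochSet`: a
(trial, channel, sample) array of potentials in microvolts with sampling and
condition metadata.  Sample 0 corresponds to ``epoch_start`` (seconds relative
to the stimulus, negative); the stimulus sits at sample
``round(-epoch_start * rate)``.  All public times are seconds.

On disk an EpochSet is a tab-separated numeric file (one row per sample, one
column per trial x channel, trial-major) plus a flat key=value sidecar at
``<path>.meta``.  Floats are written with 17 significant digits so the
round-trip is bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    EmptyResultError,
    EpochConsistencyError,
    EpochFormatError,
    EpochParseError,
    DataError,
)

__all__ = ["SamplingSpec", "EpochSet", "read_epochs", "write_epochs", "artifact_reject"]


@dataclass(frozen=True)
class SamplingSpec:
    """Sampling grid of an epoch: rate in Hz and window in seconds around the stimulus."""

    rate: float
    epoch_start: float
    epoch_end: float

    def __post_init__(self):
        if not self.rate > 0:
            raise DataError(f"sampling rate must be positive, got {self.rate}")
        if not (self.epoch_start < 0.0 < self.epoch_end):
            raise DataError(
                "epoch window must straddle the stimulus: "
                f"epoch_start={self.epoch_start}, epoch_end={self.epoch_end}"
            )
        if self.n_samples < 2:
            raise DataError("epoch must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_end - self.epoch_start) * self.rate))

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def stimulus_index(self) -> int:
        """Sample index of the stimulus (time 0)."""
        return int(round(-self.epoch_start * self.rate))

    def times(self) -> np.ndarray:
        """Time of every sample in seconds relative to the stimulus."""
        return self.epoch_start + np.arange(self.n_samples) / self.rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.epoch_start) * self.rate))

    def window_slice(self, t_lo: float, t_hi: float) -> slice:
        """Slice of samples with t_lo <= t < t_hi, clipped to the epoch."""
        lo = max(0, self.index_of(t_lo))
        hi = min(self.n_samples, self.index_of(t_hi))
        if hi <= lo:
            raise DataError(f"window [{t_lo}, {t_hi}] s lies outside the epoch")
        return slice(lo, hi)


@dataclass
class EpochSet:
    """Trials x channels x samples of potentials (microvolts) with metadata."""

    data: np.ndarray
    channel_labels: list[str]
    condition_labels: list[str]
    sampling: SamplingSpec

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise EpochConsistencyError(
                f"data must be (trials, channels, samples), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise DataError("epoch data contain non-finite values")
        n_tr, n_ch, n_s = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise EpochConsistencyError(
                f"{len(self.channel_labels)} channel labels for {n_ch} channels"
            )
        if len(self.condition_labels) != n_tr:
            raise EpochConsistencyError(
                f"{len(self.condition_labels)} condition labels for {n_tr} trials"
            )
        if n_s != self.sampling.n_samples:
            raise EpochConsistencyError(
                f"data has {n_s} samples but sampling spec implies {self.sampling.n_samples}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times(self) -> np.ndarray:
        return self.sampling.times()

    def select_trials(self, index) -> "EpochSet":
        idx = np.asarray(index)
        return EpochSet(
            data=self.data[idx],
            channel_labels=list(self.channel_labels),
            condition_labels=[self.condition_labels[i] for i in np.atleast_1d(idx)],
            sampling=self.sampling,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            self.sampling == other.sampling
            and self.channel_labels == other.channel_labels
            and self.condition_labels == other.condition_labels
            and self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
        )


def _sidecar_path(path: str) -> str:
    return str(path) + ".meta"


def write_epochs(e: EpochSet, path: str) -> None:
    """Write an EpochSet as TSV samples plus a ``<path>.meta`` sidecar."""
    n_tr, n_ch, n_s = e.data.shape
    # column order is trial-major: (trial 0, ch 0), (trial 0, ch 1), ...
    flat = e.data.transpose(2, 0, 1).reshape(n_s, n_tr * n_ch)
    with open(path, "w") as fh:
        for row in flat:
            fh.write("\t".join(format(v, ".17g") for v in row))
            fh.write("\n")
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"rate_hz={format(e.sampling.rate, '.17g')}\n")
        fh.write(f"epoch_start_s={format(e.sampling.epoch_start, '.17g')}\n")
        fh.write(f"epoch_end_s={format(e.sampling.epoch_end, '.17g')}\n")
        fh.write(f"channels={','.join(e.channel_labels)}\n")
        fh.write(f"conditions={','.join(e.condition_labels)}\n")


def _read_sidecar(path: str) -> dict:
    meta_path = _sidecar_path(path)
    if not os.path.exists(meta_path):
        raise EpochFormatError(f"missing metadata sidecar: {meta_path}")
    meta = {}
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise EpochFormatError(f"malformed sidecar line: {line!r}")
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    for key in ("rate_hz", "epoch_start_s", "epoch_end_s", "channels", "conditions"):
        if key not in meta:
            raise EpochFormatError(f"sidecar is missing required key {key!r}")
    return meta


def read_epochs(path: str) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`.

    Raises EpochFormatError for a missing/malformed sidecar, EpochParseError
    (with row/column) for non-numeric cells, and EpochConsistencyError when
    the file dimensions disagree with the sidecar.
    """
    meta = _read_sidecar(path)
    sampling = SamplingSpec(
        rate=float(meta["rate_hz"]),
        epoch_start=float(meta["epoch_start_s"]),
        epoch_end=float(meta["epoch_end_s"]),
    )
    channels = [c for c in meta["channels"].split(",") if c != ""]
    conditions = [c for c in meta["conditions"].split(",") if c != ""]
    n_ch, n_tr = len(channels), len(conditions)

    rows = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            tokens = line.split("\t")
            row = np.empty(len(tokens))
            for c, tok in enumerate(tokens):
                try:
                    row[c] = float(tok)
                except ValueError:
                    raise EpochParseError(row=r, column=c, token=tok) from None
            rows.append(row)
    if not rows:
        raise EpochFormatError(f"epoch file {path} is empty")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise EpochConsistencyError("rows have inconsistent column counts")
    flat = np.vstack(rows)
    if flat.shape[1] != n_tr * n_ch:
        raise EpochConsistencyError(
            f"file has {flat.shape[1]} columns but sidecar declares "
            f"{n_tr} trials x {n_ch} channels = {n_tr * n_ch}"
        )
    if flat.shape[0] != sampling.n_samples:
        raise EpochConsistencyError(
            f"file has {flat.shape[0]} rows but sidecar implies "
            f"{sampling.n_samples} samples"
        )
    data = flat.reshape(sampling.n_samples, n_tr, n_ch).transpose(1, 2, 0)
    return EpochSet(
        data=data,
        channel_labels=channels,
        condition_labels=conditions,
        sampling=sampling,
    )


def artifact_reject(e: EpochSet, limit: float = 120.0) -> EpochSet:
    """Drop trials with any sample outside [-limit, +limit] microvolts.

    The bound is inclusive (|v| <= limit is retained); rejection is joint over
    all channels.  Trial order is preserved.  Raises EmptyResultError when no
    trial survives.
    """
    if not limit > 0:
        raise DataError(f"rejection limit must be positive, got {limit}")
    keep = np.flatnonzero(np.abs(e.data).max(axis=(1, 2)) <= limit)
    if keep.size == 0:
        raise EmptyResultError(f"artifact rejection at +/-{limit} uV removed every trial")
    return e.select_trials(keep)
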