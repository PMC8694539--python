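"""Shared domain types: recordings, segments, and sensor-noise models.

Conventions
-----------
* Channel order is fixed: ``MIC`` (contact microphone), ``AP``
  (anterior-posterior), ``SI`` (superior-inferior), ``ML`` (medial-lateral).
* All sample indices are 0-based, half-open ``[onset, offset)``.
* AR models are in prediction form ``x_t = sum_k a_k x_{t-k} + e_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

CHANNELS: Tuple[str, ...] = ("MIC", "AP", "SI", "ML")

#: accelerometer axes; the microphone is not detrended for head motion
ACCEL_CHANNELS: Tuple[str, ...] = ("AP", "SI", "ML")


@dataclass(frozen=True)
class ARNoiseModel:
    """Autoregressive model of a sensor's zero-input (baseline) noise.

    Parameters
    ----------
    order : int
        Model order ``p >= 0``; ``p = 0`` means white noise.
    coefficients : tuple of float
        ``a_1 .. a_p`` in prediction form ``x_t = sum a_k x_{t-k} + e_t``.
    noise_variance : float
        Innovation variance ``sigma_e**2`` in squared sensor units.
    channel : str, optional
        Which sensor the model describes.
    """

    order: int
    coefficients: Tuple[float, ...] = ()
    noise_variance: float = 1.0
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        if self.order != len(self.coefficients):
            raise ValueError(
                f"order {self.order} does not match {len(self.coefficients)} coefficients"
            )
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        if not self.is_stable():
            raise ValueError(
                f"unstable AR model: characteristic roots outside the unit circle "
                f"(coefficients {self.coefficients})"
            )

    def is_stable(self) -> bool:
        """True when all characteristic roots lie strictly inside the unit circle."""
        if self.order == 0:
            return True
        # roots of z^p - a_1 z^{p-1} - ... - a_p
        poly = np.r_[1.0, -np.asarray(self.coefficients, dtype=float)]
        return bool(np.all(np.abs(np.roots(poly)) < 1.0))

    @property
    def ar_polynomial(self) -> np.ndarray:
        """Denominator polynomial ``[1, -a_1, ..., -a_p]`` (also the whitening FIR)."""
        return np.r_[1.0, -np.asarray(self.coefficients, dtype=float)]


@dataclass
class RecordingChannelSet:
    """One trial's four synchronized sensor channels at a common sampling rate."""

    channels: Dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        lengths = {len(self.channels[c]) for c in CHANNELS}
        if len(lengths) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNELS[0]])

    def as_array(self) -> np.ndarray:
        """Stack channels into an ``(n_samples, 4)`` array in canonical order."""
        return np.column_stack([self.channels[c] for c in CHANNELS])


@dataclass
class SwallowSegment:
    """A labeled, bounded excerpt of an HRCA recording.

    ``onset_sample``/``offset_sample`` bound the stored excerpt within its
    source recording; for generator output they are 0 and the excerpt length.
    ``true_onset_sample``/``true_offset_sample`` are the ground-truth swallow
    bounds, known only for synthetic data.  For barium swallows (frame-accurate
    videofluoroscopic segmentation) the segment bounds coincide with the true
    bounds; for water swallows (pushbutton segmentation) the segment strictly
    contains them.
    """

    participant_id: str
    material: str
    channels: Dict[str, np.ndarray]
    fs: float
    onset_sample: int = 0
    offset_sample: int = 0
    true_onset_sample: Optional[int] = None
    true_offset_sample: Optional[int] = None
    swallow_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.offset_sample == 0:
            self.offset_sample = self.n_samples
        if not (0 <= self.onset_sample < self.offset_sample):
            raise ValueError("require 0 <= onset < offset")
        if self.true_onset_sample is not None and self.true_offset_sample is not None:
            if not (
                self.onset_sample
                <= self.true_onset_sample
                <= self.true_offset_sample
                <= self.offset_sample
            ):
                raise ValueError("true swallow bounds must lie within the segment")

    @property
    def n_samples(self) -> int:
        return len(self.channels[CHANNELS[0]])

    @property
    def duration_s(self) -> float:
        return (self.offset_sample - self.onset_sample) / self.fs

    def with_channels(self, channels: Dict[str, np.ndarray], fs: float) -> "SwallowSegment":
        """Copy of this segment with replaced signal content and rate.

        Sample indices are rescaled to the new rate.
        """
        scale = fs / self.fs
        new = replace(
            self,
            channels=channels,
            fs=fs,
            onset_sample=int(round(self.onset_sample * scale)),
            offset_sample=int(round(self.onset_sample * scale)) + len(channels[CHANNELS[0]]),
            true_onset_sample=(
                None
                if self.true_onset_sample is None
                else int(round(self.true_onset_sample * scale))
            ),
            true_offset_sample=(
                None
                if self.true_offset_sample is None
                else int(round(self.true_offset_sample * scale))
            ),
            meta=dict(self.meta),
        )
        return new
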