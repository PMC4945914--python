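"""Recording containers and the epoching / cleaning / filtering protocol.

The default pipeline follows the typical resting-EEG protocol: segment into
non-overlapping 1-second epochs, reject epochs on an absolute voltage
threshold (100 uV) and a sample-to-sample transition threshold (50 uV),
re-reference to the common average, and band-pass to the alpha band (7-13 Hz)
with a zero-phase FIR filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


class ValidationError(ValueError):
    """Raised when a container or parameter violates its contract."""


class NoCleanEpochsError(RuntimeError):
    """Raised when artifact rejection leaves no usable epochs."""


@dataclass
class Recording:
    """One subject's channels x samples matrix, in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    fs_hz : float
        Sampling rate.
    channel_labels : list of str
    subject_id : str
    group : str
        Group label ("unknown" when absent).
    artifact_epochs : ndarray or None
        Ground-truth contaminated 1-s epoch indices, set by
        :func:`fconnet.synth.inject_artifacts` for validation fixtures.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "subject"
    group: str = "unknown"
    artifact_epochs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data: expected a channels x samples matrix")
        if self.data.shape[0] < 2:
            raise ValidationError("data: at least 2 channels required")
        if np.isnan(self.data).any():
            raise ValidationError("data: NaN values are not allowed")
        if not self.fs_hz > 0:
            raise ValidationError("fs_hz: must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError("channel_labels: length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class EpochSet:
    """Segmented (optionally cleaned and filtered) data for one subject.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch); the
    boolean ``artifact_mask`` is True for contaminated epochs, which every
    downstream average excludes.  ``log`` records the processing steps applied,
    in order.
    """

    epochs: np.ndarray
    fs_hz: float
    epoch_len_s: float
    artifact_mask: np.ndarray = None  # type: ignore[assignment]
    band_hz: tuple[float, float] | None = None
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "subject"
    group: str = "unknown"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs: expected epoch x channel x sample array")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.epochs.shape[0], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.epochs.shape[0],):
            raise ValidationError("artifact_mask: one boolean per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def clean_epochs(self) -> np.ndarray:
        """Epochs not flagged as artifact, shape (n_clean, n_channels, T)."""
        return self.epochs[~self.artifact_mask]

    @property
    def n_clean(self) -> int:
        return int((~self.artifact_mask).sum())


def segment_epochs(rec: Recording, epoch_len_s: float = 1.0) -> EpochSet:
    """Cut a recording into non-overlapping fixed-length epochs.

    Trailing samples that do not fill a whole epoch are discarded.
    """
    if epoch_len_s <= 0:
        raise ValidationError("epoch_len_s: must be positive")
    samples_per_epoch = int(round(epoch_len_s * rec.fs_hz))
    if abs(samples_per_epoch - epoch_len_s * rec.fs_hz) > 1e-9:
        raise ValidationError("epoch_len_s: epoch_len_s * fs_hz must be integral")
    n_epochs = rec.n_samples // samples_per_epoch
    if n_epochs < 1:
        raise ValidationError(
            f"epoch_len_s: recording ({rec.duration_s:g} s) shorter than one epoch"
        )
    used = rec.data[:, : n_epochs * samples_per_epoch]
    epochs = used.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    epochs = np.transpose(epochs, (1, 0, 2))
    return EpochSet(
        epochs=epochs.copy(),
        fs_hz=rec.fs_hz,
        epoch_len_s=epoch_len_s,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
        group=rec.group,
        log=[f"segment(epoch_len_s={epoch_len_s})"],
    )


def reject_artifacts(
    es: EpochSet,
    abs_thresh_uV: float = 100.0,
    trans_thresh_uV: float = 50.0,
    transition: str = "adjacent",
) -> EpochSet:
    """Flag epochs exceeding an absolute or transition voltage threshold.

    An epoch is marked as artifact when any channel exceeds ``abs_thresh_uV``
    in absolute value, or when a voltage transition exceeds ``trans_thresh_uV``.
    ``transition="adjacent"`` (default) compares consecutive samples;
    ``transition="peak_to_peak"`` uses the epoch-wise per-channel range.

    Raises
    ------
    NoCleanEpochsError
        If every epoch ends up rejected.
    """
    if abs_thresh_uV <= 0 or trans_thresh_uV <= 0:
        raise ValidationError("thresholds must be positive")
    if transition not in ("adjacent", "peak_to_peak"):
        raise ValidationError("transition: must be 'adjacent' or 'peak_to_peak'")
    over_abs = (np.abs(es.epochs) > abs_thresh_uV).any(axis=(1, 2))
    if transition == "adjacent":
        steps = np.abs(np.diff(es.epochs, axis=2))
        over_trans = (steps > trans_thresh_uV).any(axis=(1, 2))
    else:
        ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)
        over_trans = (ptp > trans_thresh_uV).any(axis=1)
    mask = es.artifact_mask | over_abs | over_trans
    if mask.all():
        raise NoCleanEpochsError("no clean epochs: every epoch exceeded a threshold")
    return replace(
        es,
        epochs=es.epochs.copy(),
        artifact_mask=mask,
        log=es.log
        + [
            f"reject(abs={abs_thresh_uV}uV, trans={trans_thresh_uV}uV, "
            f"mode={transition}, n_rejected={int(mask.sum())})"
        ],
    )


def design_fir(
    low_hz: float, high_hz: float, fs_hz: float, order: int | None = None
) -> np.ndarray:
    """Band-pass FIR taps (Hamming window design).

    ``order`` is the number of taps minus one.  When None, a practical default
    of ``2 * fs / low`` taps (forced odd) is used; very small literal orders
    (e.g. 5) are accepted but cannot isolate a narrow band.
    """
    if not (0 < low_hz < high_hz < fs_hz / 2):
        raise ValidationError("band_hz: need 0 < low < high < fs/2 (Nyquist)")
    if order is None:
        numtaps = int(2 * fs_hz / low_hz) | 1
    else:
        if order < 2:
            raise ValidationError("order: must be >= 2")
        numtaps = order + 1
        if numtaps % 2 == 0:
            numtaps += 1  # odd tap count keeps a type-I linear-phase band-pass
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs_hz)


def bandpass_fir(
    es: EpochSet,
    low_hz: float = 7.0,
    high_hz: float = 13.0,
    order: int | None = None,
) -> EpochSet:
    """Zero-phase band-pass each channel of each epoch.

    The FIR filter is applied forward-backward (``filtfilt``) so that phases
    extracted downstream by the Hilbert transform carry no group delay.
    """
    taps = design_fir(low_hz, high_hz, es.fs_hz, order=order)
    padlen = min(3 * (len(taps) - 1), es.n_samples - 1)
    filtered = signal.filtfilt(taps, [1.0], es.epochs, axis=2, padlen=padlen)
    return replace(
        es,
        epochs=filtered,
        band_hz=(low_hz, high_hz),
        log=es.log + [f"bandpass_fir(band=({low_hz},{high_hz})Hz, taps={len(taps)})"],
    )


def rereference_common_average(es: EpochSet) -> EpochSet:
    """Subtract the across-channel mean at every sample (common average)."""
    if es.n_channels < 2:
        raise ValidationError("common average reference needs >= 2 channels")
    data = es.epochs - es.epochs.mean(axis=1, keepdims=True)
    return replace(es, epochs=data, log=es.log + ["rereference(common_average)"])


_DEFAULT_ORDER = ("segment", "reject", "rereference", "bandpass")


def preprocess(
    rec: Recording,
    epoch_len_s: float = 1.0,
    abs_thresh_uV: float = 100.0,
    trans_thresh_uV: float = 50.0,
    band_hz: tuple[float, float] = (7.0, 13.0),
    fir_order: int | None = None,
    order: tuple[str, ...] = _DEFAULT_ORDER,
) -> EpochSet:
    """Run the full cleaning pipeline; the applied order is recorded in the log."""
    if order[0] != "segment":
        raise ValidationError("order: pipeline must start with 'segment'")
    es = segment_epochs(rec, epoch_len_s)
    for step in order[1:]:
        if step == "reject":
            es = reject_artifacts(es, abs_thresh_uV, trans_thresh_uV)
        elif step == "rereference":
            es = rereference_common_average(es)
        elif step == "bandpass":
            es = bandpass_fir(es, band_hz[0], band_hz[1], order=fir_order)
        else:
            raise ValidationError(f"order: unknown pipeline step {step!r}")
    return es
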