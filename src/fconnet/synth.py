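"""Synthetic resting-EEG cohorts with known ground-truth coupling.

Each channel is an alpha-band (default 10 Hz centre) narrowband stochastic
oscillation plus white Gaussian sensor noise.  Pairwise coupling is planted by
a common-drive construction: every coupling edge (i, j, s) contributes a
shared unit-variance latent oscillation to both endpoint channels with mixing
weight s, so that the noise-free Pearson correlation of a single coupled pair
is s**2 and uncoupled channels are asymptotically uncorrelated.  Subjects in a
group share the coupling topology; oscillator phases and noise are drawn
independently per subject so that cross-subject averages are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from fconnet.preproc import Recording, ValidationError


@dataclass
class CouplingSpec:
    """Ground-truth generative model for one subject's multichannel recording.

    Parameters
    ----------
    n_channels : int
        Number of sensors (>= 2).
    coupling_edges : list of (i, j, strength)
        Planted coupling graph; strengths in [0, 1].
    oscillator_freq_hz : float
        Centre frequency of the narrowband oscillators (alpha band, 7-13 Hz,
        by default 10 Hz).
    oscillator_bw_hz : float
        Total bandwidth of the stochastic oscillators.
    osc_amplitude_uV : float
        RMS amplitude of the oscillatory part of each channel, microvolts.
    noise_sd : float
        Standard deviation of the additive white sensor noise, microvolts.
    fs_hz, duration_s, seed
        Sampling rate, recording length, RNG seed.
    """

    n_channels: int = 16
    coupling_edges: list[tuple[int, int, float]] = field(default_factory=list)
    oscillator_freq_hz: float = 10.0
    oscillator_bw_hz: float = 4.0
    osc_amplitude_uV: float = 10.0
    noise_sd: float = 5.0
    fs_hz: float = 500.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValidationError("n_channels: must be >= 2")
        if self.fs_hz <= 2 * self.oscillator_freq_hz:
            raise ValidationError("fs_hz: must exceed 2 * oscillator_freq_hz")
        if self.oscillator_bw_hz <= 0:
            raise ValidationError("oscillator_bw_hz: must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be non-negative")
        if self.duration_s <= 0:
            raise ValidationError("duration_s: must be positive")
        seen = set()
        for i, j, s in self.coupling_edges:
            if i == j:
                raise ValidationError(f"coupling_edges: self-coupling ({i},{j})")
            if not (0 <= min(i, j) and max(i, j) < self.n_channels):
                raise ValidationError(f"coupling_edges: node out of range ({i},{j})")
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"coupling_edges: strength {s} outside [0,1]")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"coupling_edges: duplicate edge {key}")
            seen.add(key)


@dataclass
class CohortSpec:
    """Two groups of subjects, each group sharing one CouplingSpec topology."""

    group_a: tuple[int, CouplingSpec]
    group_b: tuple[int, CouplingSpec]
    seed: int = 0
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        for name, (n, spec) in (("group_a", self.group_a), ("group_b", self.group_b)):
            if n < 2:
                raise ValidationError(f"{name}: needs >= 2 subjects (group statistics)")
            if not isinstance(spec, CouplingSpec):
                raise ValidationError(f"{name}: second element must be a CouplingSpec")


def _narrowband(
    rng: np.random.Generator, n: int, f0: float, bw: float, fs: float
) -> np.ndarray:
    """Unit-variance stochastic oscillation band-limited to f0 +- bw/2."""
    lo, hi = f0 - bw / 2.0, f0 + bw / 2.0
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not leave the returned segment
    pad = int(4 * fs / lo)
    x = rng.standard_normal(n + 2 * pad)
    y = signal.sosfiltfilt(sos, x)[pad : pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_coupled_channels(spec: CouplingSpec) -> Recording:
    """Simulate one subject's channels x samples matrix from a CouplingSpec.

    Channel i mixes its incident edge latents (weight s each) with a private
    oscillator weighted ``sqrt(max(0, 1 - sum(s^2)))``; when the incident
    couplings alone exceed unit power the mixture is renormalized.  The
    oscillatory part is scaled to ``osc_amplitude_uV`` RMS and independent
    Gaussian noise of ``noise_sd`` is added.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    f0, bw, fs = spec.oscillator_freq_hz, spec.oscillator_bw_hz, spec.fs_hz

    latents = {}
    for i, j, s in spec.coupling_edges:
        latents[(min(i, j), max(i, j))] = _narrowband(rng, n, f0, bw, fs)

    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        incident = [
            (s, latents[(min(i, j), max(i, j))])
            for (i, j, s) in spec.coupling_edges
            if ch in (i, j)
        ]
        coupled_power = sum(s * s for s, _ in incident)
        own_w = np.sqrt(max(0.0, 1.0 - coupled_power))
        osc = own_w * _narrowband(rng, n, f0, bw, fs)
        for s, z in incident:
            osc = osc + s * z
        norm = np.sqrt(max(1.0, coupled_power))
        data[ch] = spec.osc_amplitude_uV * osc / norm
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    return Recording(
        data=data,
        fs_hz=fs,
        subject_id=f"synth-{spec.seed}",
        group="unknown",
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """One Recording per subject; per-subject seeds derived from the cohort seed.

    Subjects within a group share the coupling topology and differ only in
    their oscillator/noise realizations.
    """
    root = np.random.SeedSequence(spec.seed)
    n_a = spec.group_a[0]
    n_total = n_a + spec.group_b[0]
    child_seeds = [int(ss.generate_state(1)[0] % (2**31)) for ss in root.spawn(n_total)]
    recordings = []
    for k in range(n_total):
        group_label = spec.label_a if k < n_a else spec.label_b
        base = spec.group_a[1] if k < n_a else spec.group_b[1]
        sub_spec = CouplingSpec(
            n_channels=base.n_channels,
            coupling_edges=list(base.coupling_edges),
            oscillator_freq_hz=base.oscillator_freq_hz,
            oscillator_bw_hz=base.oscillator_bw_hz,
            osc_amplitude_uV=base.osc_amplitude_uV,
            noise_sd=base.noise_sd,
            fs_hz=base.fs_hz,
            duration_s=base.duration_s,
            seed=child_seeds[k],
        )
        rec = generate_coupled_channels(sub_spec)
        rec.subject_id = f"{group_label}{k:02d}"
        rec.group = group_label
        recordings.append(rec)
    return recordings


def inject_artifacts(
    recording: Recording,
    n_events: int,
    amplitude_uV: float = 150.0,
    seed: int = 0,
    epoch_len_s: float = 1.0,
) -> Recording:
    """Insert rectangular voltage transients into randomly chosen epochs.

    Returns a copy with ``artifact_epochs`` holding the ground-truth
    contaminated epoch indices, against which downstream artifact rejection
    can be validated.  ``n_events=0`` is the identity (with an empty index
    list).
    """
    if n_events < 0:
        raise ValidationError("n_events: must be >= 0")
    samples_per_epoch = int(round(epoch_len_s * recording.fs_hz))
    n_epochs = recording.n_samples // samples_per_epoch
    if n_events > n_epochs:
        raise ValidationError(
            f"n_events: {n_events} exceeds the {n_epochs} available epochs"
        )
    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    chosen = np.sort(rng.choice(n_epochs, size=n_events, replace=False))
    width = max(1, samples_per_epoch // 10)
    for ep in chosen:
        ch = int(rng.integers(recording.n_channels))
        start = ep * samples_per_epoch + int(
            rng.integers(samples_per_epoch - width + 1)
        )
        data[ch, start : start + width] += amplitude_uV
    return Recording(
        data=data,
        fs_hz=recording.fs_hz,
        channel_labels=list(recording.channel_labels),
        subject_id=recording.subject_id,
        group=recording.group,
        artifact_epochs=chosen,
    )


def modular_coupling_spec(
    coupling: float,
    n_channels: int = 16,
    module_size: int = 4,
    seed: int = 0,
    **kwargs,
) -> CouplingSpec:
    """Modular planted topology: channels partitioned into cliques of
    ``module_size``, every within-module pair coupled at ``coupling``.

    This is the default study condition for two-group experiments: groups
    share the modular topology and differ only in coupling strength.
    """
    if n_channels % module_size != 0:
        raise ValidationError("n_channels: must be a multiple of module_size")
    edges = []
    for m0 in range(0, n_channels, module_size):
        members = range(m0, m0 + module_size)
        edges.extend(
            (i, j, coupling) for i in members for j in members if i < j
        )
    return CouplingSpec(
        n_channels=n_channels, coupling_edges=edges, seed=seed, **kwargs
    )
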