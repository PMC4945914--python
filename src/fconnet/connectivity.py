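"""Four pairwise dependency estimators for multichannel epoched data.

Estimators
----------
``correlation``
    Absolute Pearson correlation per epoch, averaged over clean epochs.
``coherence``
    Magnitude-squared coherence |G_ij(f)|^2 / (G_ii(f) G_jj(f)), with auto-
    and cross-spectra estimated per epoch and pooled across clean epochs
    (epochs act as the realizations of the spectral estimator; single-segment
    coherence is identically 1), then averaged over the frequency bins inside
    the analysis band.
``phase_order``
    Phase order parameter |< exp(i (phi_u - phi_v)) >_t| of the instantaneous
    Hilbert phases, per epoch over non-edge samples, averaged over epochs.
``sync_likelihood``
    Synchronization likelihood: after time-delay embedding (lag L, dimension
    e), the conditional likelihood that channel i's state vectors are
    recurrent (closer than a critical radius calibrated so that the
    correlation integral equals P_ref) given that channel j's simultaneously
    are.  Theiler correction excludes temporally close vector pairs.  For
    independent series the measure equals P_ref; for identical series it is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.distance import pdist, squareform

from fconnet.preproc import EpochSet, ValidationError

ESTIMATORS = ("correlation", "coherence", "phase_order", "sync_likelihood")

#: fraction of samples at each epoch edge excluded from phase averages
#: (Hilbert transform edge effects)
PHASE_EDGE_FRACTION = 0.1


@dataclass
class SLParams:
    """Synchronization-likelihood parameters.

    p_ref : reference probability calibrating the critical radii (default 0.01)
    lag_L : embedding lag in samples (default 10)
    embed_e : embedding dimension (default 10)
    theiler_w : Theiler exclusion, as a fraction of the number of embedded
        vectors by default; set ``theiler_in_samples=True`` to read it as an
        absolute sample count.
    """

    p_ref: float = 0.01
    lag_L: int = 10
    embed_e: int = 10
    theiler_w: float = 0.1
    theiler_in_samples: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_ref < 1):
            raise ValidationError("p_ref: must lie in (0, 1)")
        if self.lag_L < 1:
            raise ValidationError("lag_L: must be >= 1")
        if self.embed_e < 1:
            raise ValidationError("embed_e: must be >= 1")
        if self.theiler_w < 0 or (not self.theiler_in_samples and self.theiler_w >= 1):
            raise ValidationError("theiler_w: fraction must lie in [0, 1)")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N weighted dependency matrix for one subject."""

    weights: np.ndarray
    estimator: str
    subject_id: str = "subject"
    group: str = "unknown"
    n_epochs_used: int = 0
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape != (n, n):
            raise ValidationError("weights: must be a square matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValidationError("weights: must be symmetric")
        np.fill_diagonal(self.weights, 0.0)
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(n)]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def _as_matrix(
    weights: np.ndarray, estimator: str, es: EpochSet | None = None
) -> ConnectivityMatrix:
    w = (weights + weights.T) / 2.0  # symmetrize away float asymmetry
    kwargs = {}
    if es is not None:
        kwargs = dict(
            subject_id=es.subject_id,
            group=es.group,
            channel_labels=list(es.channel_labels),
            n_epochs_used=es.n_clean,
        )
    return ConnectivityMatrix(weights=w, estimator=estimator, **kwargs)


# ---------------------------------------------------------------------------
# correlation


def pearson_matrix(epoch: np.ndarray, mode: str = "abs") -> np.ndarray:
    """Pearson correlation matrix of one channels x samples epoch.

    ``mode="abs"`` (default) returns |r| so that binarization, which ranks
    dependency strengths, treats anti-correlation as coupling; ``"positive"``
    clips negative r to 0.
    """
    epoch = np.asarray(epoch, dtype=float)
    var = epoch.var(axis=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValidationError(f"zero-variance channel(s): {dead.tolist()}")
    r = np.corrcoef(epoch)
    if mode == "abs":
        r = np.abs(r)
    elif mode == "positive":
        r = np.clip(r, 0.0, None)
    else:
        raise ValidationError("mode: must be 'abs' or 'positive'")
    np.fill_diagonal(r, 0.0)
    return r


# ---------------------------------------------------------------------------
# coherence


def _pooled_spectra(epochs: np.ndarray) -> np.ndarray:
    """Cross-spectral matrix (ch x ch x freq) pooled over epochs (Hann taper)."""
    n_ep, n_ch, n_t = epochs.shape
    win = signal.windows.hann(n_t, sym=False)
    demeaned = epochs - epochs.mean(axis=2, keepdims=True)
    spectra = np.fft.rfft(demeaned * win, axis=2)  # (ep, ch, f)
    # average X_i conj(X_j) over epochs
    return np.einsum("eif,ejf->ijf", spectra, np.conj(spectra)) / n_ep


def coherence_spectrum(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-pooled magnitude-squared coherence at every frequency bin.

    Returns ``(freqs, coh)`` with ``coh`` of shape (ch, ch, n_freqs), values
    in [0, 1] by the Cauchy-Schwarz inequality.  Requires at least two clean
    epochs: coherence of a single segment is identically 1 and carries no
    information.
    """
    clean = es.clean_epochs()
    if clean.shape[0] < 2:
        raise ValidationError("coherence requires multiple epochs (>= 2 clean)")
    G = _pooled_spectra(clean)
    auto = np.real(np.einsum("iif->if", G))  # (ch, f)
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(G) ** 2 / denom
    coh = np.nan_to_num(coh, nan=0.0)
    freqs = np.fft.rfftfreq(clean.shape[2], d=1.0 / es.fs_hz)
    return freqs, np.clip(coh, 0.0, 1.0)


def coherence_matrix(
    es: EpochSet, band_hz: tuple[float, float] | None = None
) -> np.ndarray:
    """Band-average coherence: mean over FFT bins whose centre lies in the band
    (endpoints inclusive)."""
    if band_hz is None:
        band_hz = es.band_hz if es.band_hz is not None else (7.0, 13.0)
    freqs, coh = coherence_spectrum(es)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValidationError("band_hz: no FFT bin falls inside the band")
    w = coh[:, :, in_band].mean(axis=2)
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# phase order parameter


def hilbert_phase(series: np.ndarray, unwrap: bool = False) -> np.ndarray:
    """Instantaneous phase of a band-limited series via the Hilbert transform.

    phi(t) = angle(y(t) + i * H[y](t)), in (-pi, pi] unless ``unwrap``.  The
    first and last 10% of samples are edge-unreliable; callers averaging over
    time should drop them (see :func:`phase_edge_slice`).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValidationError("series: expected a 1-D sample vector")
    if np.ptp(series) == 0:
        raise ValidationError("constant series: instantaneous phase undefined")
    phi = np.angle(signal.hilbert(series))
    return np.unwrap(phi) if unwrap else phi


def phase_edge_slice(n_samples: int, frac: float = PHASE_EDGE_FRACTION) -> slice:
    """Slice selecting the samples whose Hilbert phase is edge-reliable."""
    k = int(np.floor(frac * n_samples))
    return slice(k, n_samples - k)


def phase_order_pair(phi_u: np.ndarray, phi_v: np.ndarray) -> float:
    """Phase order parameter P = |mean_t exp(i(phi_u - phi_v))|, in [0, 1]."""
    return float(np.abs(np.mean(np.exp(1j * (phi_u - phi_v)))))


def phase_order_matrix(es: EpochSet) -> np.ndarray:
    """Pairwise phase order parameter, averaged over clean epochs."""
    clean = es.clean_epochs()
    if clean.shape[0] < 1:
        raise ValidationError("phase order requires >= 1 clean epoch")
    keep = phase_edge_slice(clean.shape[2])
    acc = np.zeros((es.n_channels, es.n_channels))
    for epoch in clean:
        phases = np.empty((es.n_channels, clean.shape[2]))
        for ch in range(es.n_channels):
            phases[ch] = hilbert_phase(epoch[ch])
        z = np.exp(1j * phases[:, keep])
        n_t = z.shape[1]
        p = np.abs(z @ np.conj(z.T)) / n_t
        acc += p
    w = acc / clean.shape[0]
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# synchronization likelihood


def embed(series: np.ndarray, params: SLParams) -> np.ndarray:
    """Time-delay embedding: N = T - (e-1)*L vectors of dimension e.

    Vector t is (y(t), y(t+L), ..., y(t+(e-1)L)).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValidationError("series: expected a 1-D sample vector")
    t_len = series.shape[0]
    span = (params.embed_e - 1) * params.lag_L
    if t_len <= span:
        raise ValidationError(
            f"series too short: need T > (e-1)*L = {span}, got T = {t_len}"
        )
    n = t_len - span
    idx = np.arange(n)[:, None] + params.lag_L * np.arange(params.embed_e)[None, :]
    return series[idx]


def _theiler_exclusion(n_vectors: int, params: SLParams) -> int:
    if params.theiler_in_samples:
        return int(params.theiler_w)
    return int(np.ceil(params.theiler_w * n_vectors))


def _admissible_mask(n_vectors: int, params: SLParams) -> np.ndarray:
    """Upper-triangle boolean mask of admissible (t, s) pairs, |t-s| > w."""
    w = _theiler_exclusion(n_vectors, params)
    t = np.arange(n_vectors)
    return (t[None, :] - t[:, None]) > w  # strictly upper triangle, gap > w


def correlation_integral(vectors: np.ndarray, r: float, params: SLParams) -> float:
    """Fraction of Theiler-admissible vector pairs closer (strictly) than r."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    mask = _admissible_mask(vectors.shape[0], params)
    n_pairs = int(mask.sum())
    if n_pairs < 2:
        raise ValidationError("no admissible vector pairs after Theiler exclusion")
    d = squareform(pdist(vectors))
    return float((d[mask] < r).sum() / n_pairs)


def critical_radius(vectors: np.ndarray, params: SLParams) -> float:
    """Radius r at which the correlation integral best matches p_ref.

    Found by sorting the admissible pair distances and taking the p_ref
    quantile, so that CI(r) is within 1/n_pairs of p_ref.  When p_ref falls
    below the 1/n_pairs resolution a warning is issued and the smallest
    nonzero distance is returned.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    mask = _admissible_mask(vectors.shape[0], params)
    d = np.sort(squareform(pdist(vectors))[mask])
    return _radius_from_sorted(d, params.p_ref)


def _radius_from_sorted(d_sorted: np.ndarray, p_ref: float) -> float:
    n_pairs = d_sorted.size
    if n_pairs < 2:
        raise ValidationError("no admissible vector pairs after Theiler exclusion")
    if p_ref < 1.0 / n_pairs:
        warnings.warn(
            f"p_ref={p_ref} below the 1/{n_pairs} resolution; "
            "using the smallest nonzero distance",
            stacklevel=2,
        )
        nonzero = d_sorted[d_sorted > 0]
        return float(nonzero[0]) if nonzero.size else float(d_sorted[-1]) + 1e-12
    k = int(round(p_ref * n_pairs))
    if k >= n_pairs:
        return float(d_sorted[-1]) * (1 + 1e-12) + 1e-300
    return float(d_sorted[k])


def sl_pair(
    vec_i: np.ndarray, vec_j: np.ndarray, params: SLParams
) -> float:
    """Synchronization likelihood of one channel pair from embedded vectors.

    SL_{i|j} = P(d_i < r_i | d_j < r_j) over admissible pairs, with r_i, r_j
    calibrated so CI = p_ref; the returned value is the mean of the two
    conditional directions.
    """
    vec_i = np.atleast_2d(vec_i)
    vec_j = np.atleast_2d(vec_j)
    if vec_i.shape[0] != vec_j.shape[0]:
        raise ValidationError("channel embeddings must have equal length")
    mask = _admissible_mask(vec_i.shape[0], params)
    if int(mask.sum()) < 2:
        raise ValidationError("no admissible vector pairs after Theiler exclusion")
    d_i = squareform(pdist(vec_i))[mask]
    d_j = squareform(pdist(vec_j))[mask]
    r_i = _radius_from_sorted(np.sort(d_i), params.p_ref)
    r_j = _radius_from_sorted(np.sort(d_j), params.p_ref)
    rec_i = d_i < r_i
    rec_j = d_j < r_j
    n_i = int(rec_i.sum())
    n_j = int(rec_j.sum())
    if n_i == 0 or n_j == 0:
        raise ValidationError("empty conditioning set: SL undefined")
    both = int((rec_i & rec_j).sum())
    return 0.5 * (both / n_j + both / n_i)


def sync_likelihood_matrix(es: EpochSet, params: SLParams | None = None) -> np.ndarray:
    """Pairwise synchronization likelihood, averaged over clean epochs.

    Per epoch, each channel is embedded once and its recurrence indicator over
    admissible pairs is formed; joint recurrence counts for every channel pair
    are then a single Gram-matrix product, which keeps the full matrix
    tractable at realistic channel counts.
    """
    if params is None:
        params = SLParams()
    clean = es.clean_epochs()
    if clean.shape[0] < 1:
        raise ValidationError("synchronization likelihood requires >= 1 clean epoch")
    n_ch = es.n_channels
    acc = np.zeros((n_ch, n_ch))
    for epoch in clean:
        vecs = [embed(epoch[ch], params) for ch in range(n_ch)]
        mask = _admissible_mask(vecs[0].shape[0], params)
        if int(mask.sum()) < 2:
            raise ValidationError("no admissible vector pairs after Theiler exclusion")
        rec = np.empty((n_ch, int(mask.sum())), dtype=np.float32)
        for ch in range(n_ch):
            d = squareform(pdist(vecs[ch]))[mask]
            r = _radius_from_sorted(np.sort(d), params.p_ref)
            rec[ch] = d < r
        counts = rec @ rec.T  # joint recurrence counts; diagonal = marginals
        marg = np.diag(counts).copy()
        if (marg == 0).any():
            raise ValidationError("empty conditioning set: SL undefined")
        sl = 0.5 * counts * (1.0 / marg[:, None] + 1.0 / marg[None, :])
        acc += sl
    w = acc / clean.shape[0]
    np.fill_diagonal(w, 0.0)
    return np.clip(w, 0.0, 1.0)


# ---------------------------------------------------------------------------
# subject-level dispatch


def subject_connectivity(
    es: EpochSet,
    estimator: str,
    params: SLParams | None = None,
    band_hz: tuple[float, float] | None = None,
    correlation_mode: str = "abs",
) -> ConnectivityMatrix:
    """Subject-level connectivity matrix for one estimator.

    Correlation, phase order and synchronization likelihood are computed per
    clean epoch and averaged elementwise; coherence pools spectra across the
    clean epochs (see :func:`coherence_spectrum`).
    """
    if estimator not in ESTIMATORS:
        raise ValidationError(
            f"unknown estimator {estimator!r}; valid: {', '.join(ESTIMATORS)}"
        )
    clean = es.clean_epochs()
    if clean.shape[0] < 1:
        raise ValidationError("no clean epochs available")
    if estimator == "correlation":
        w = np.mean(
            [pearson_matrix(ep, mode=correlation_mode) for ep in clean], axis=0
        )
    elif estimator == "coherence":
        w = coherence_matrix(es, band_hz=band_hz)
    elif estimator == "phase_order":
        w = phase_order_matrix(es)
    else:
        w = sync_likelihood_matrix(es, params)
    return _as_matrix(w, estimator, es)
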