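"""Signal conditioning: band-pass FIR, Infomax ICA artifact rejection,
Hjorth surface Laplacian, and average referencing.

The canonical order is bandpass → ICA rejection → Laplacian → average
reference; each step appends to the recording's provenance and
:func:`require_preprocessed` enforces the order at the feature stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .recording import EEGRecording

__all__ = [
    "bandpass",
    "ICADecomposition",
    "RankError",
    "PipelineOrderError",
    "decompose_ica",
    "RejectionCriteria",
    "reject_artifacts",
    "surface_laplacian",
    "to_average_reference",
    "require_preprocessed",
]


class RankError(ValueError):
    """Input covariance is rank deficient in a way ICA cannot tolerate."""


class PipelineOrderError(RuntimeError):
    """The conditioning steps were not applied in the canonical order."""


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

def bandpass(
    recording: EEGRecording,
    low: float = 0.5,
    high: float = 40.0,
    order: int = 100,
) -> EEGRecording:
    """Linear-phase FIR band-pass, applied in a single forward pass.

    The filter is a Hamming-windowed FIR of the given order (order + 1
    taps). Because the taps are symmetric, convolving in "same" mode
    compensates the group delay exactly; the first and last order/2
    samples are edge transients and are flagged in provenance. With the
    defaults the stop-band attenuation at 50 Hz exceeds 20 dB.

    Each channel's mean is removed before filtering: at this order a
    0.5 Hz low edge leaves residual DC gain, and amplifier offsets are
    not signal.
    """
    nyq = recording.sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band edges ({low}, {high}) outside (0, {nyq}) Hz")
    taps = sig.firwin(order + 1, [low, high], pass_zero=False, fs=recording.sample_rate)
    centred = recording.samples - recording.samples.mean(axis=1, keepdims=True)
    out = np.empty_like(recording.samples)
    for i in range(recording.n_channels):
        out[i] = sig.fftconvolve(centred[i], taps, mode="same")
    transient = (order // 2) / recording.sample_rate
    return recording.with_samples(
        out, f"bandpass({low}-{high}Hz,order={order},edge_transient={transient:.3f}s)"
    )


def _lowpass(x: np.ndarray, cutoff: float, fs: float, order: int = 100) -> np.ndarray:
    taps = sig.firwin(order + 1, cutoff, fs=fs)
    return sig.fftconvolve(x, taps, mode="same")


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

@dataclass
class ICADecomposition:
    """Infomax decomposition with canonical component ordering.

    ``sources = unmixing @ (X − mean)``; ``X̂ = mixing @ sources + mean``.
    Components are sorted by explained variance and sign-fixed so each
    column of ``mixing`` has a positive largest-magnitude entry. Channels
    with (near-)zero variance are excluded by reduced-rank whitening, so
    the retained subspace reconstructs the input to numerical tolerance.
    """

    mixing: np.ndarray  # (n_channels, n_components)
    unmixing: np.ndarray  # (n_components, n_channels)
    mean: np.ndarray  # (n_channels,)
    sources: np.ndarray  # (n_components, n_times)
    seed: int
    fitted_on: tuple[str, ...]  # provenance of the recording ICA was fit on
    rejected_components: set[int] = field(default_factory=set)
    rejection_criteria: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, reject: set[int] | None = None) -> np.ndarray:
        reject = set() if reject is None else set(reject)
        bad = reject - set(range(self.n_components))
        if bad:
            raise ValueError(f"unknown component indices: {sorted(bad)}")
        keep = [i for i in range(self.n_components) if i not in reject]
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def decompose_ica(
    recording: EEGRecording,
    seed: int = 0,
    extended: bool = False,
    max_iter: int = 200,
) -> ICADecomposition:
    """Infomax ICA after PCA whitening.

    Requires at least 30 × n_channels samples for a stable estimate.
    Duplicated channels (pairwise correlation ≈ 1) raise :class:`RankError`
    with the offending pair named; flat channels (e.g. the acquisition
    reference) are simply absorbed by the reduced-rank whitening.
    """
    from mne.preprocessing import infomax

    X = recording.samples
    n_ch, n_t = X.shape
    if n_t < 30 * n_ch:
        raise ValueError(
            f"need >= {30 * n_ch} samples for {n_ch} channels, got {n_t}"
        )
    sd = X.std(axis=1)
    live = sd > 0
    if live.sum() >= 2:
        corr = np.corrcoef(X[live])
        np.fill_diagonal(corr, 0.0)
        dup = np.argwhere(np.abs(corr) > 0.9999)
        if dup.size:
            names = np.asarray(recording.montage.channel_names)[live]
            i, j = dup[0]
            raise RankError(
                f"duplicated channels {names[i]!r} and {names[j]!r} "
                "(|correlation| ≈ 1); drop one before ICA"
            )
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = Xc @ Xc.T / n_t
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > max(evals.max(), 1e-30) * 1e-10
    evals, evecs = evals[keep][::-1], evecs[:, keep][:, ::-1]
    white = (evecs / np.sqrt(evals)).T  # (r, n_ch)
    Y = white @ Xc
    w_ica = infomax(
        Y.T, extended=extended, max_iter=max_iter,
        rng=np.random.default_rng(seed), verbose="error",
    )
    unmixing = w_ica @ white
    mixing = np.linalg.pinv(unmixing)
    sources = unmixing @ Xc

    # canonical order: explained variance, descending; canonical sign
    contrib = (mixing**2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(contrib)[::-1]
    mixing, unmixing, sources = mixing[:, order], unmixing[order], sources[order]
    flip = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
    flip[flip == 0] = 1.0
    mixing *= flip[None, :]
    unmixing *= flip[:, None]
    sources *= flip[:, None]

    return ICADecomposition(
        mixing=mixing,
        unmixing=unmixing,
        mean=mean,
        sources=sources,
        seed=seed,
        fitted_on=tuple(recording.provenance),
    )


@dataclass(frozen=True)
class RejectionCriteria:
    """Automatic ocular-component selection.

    A component is rejected when the absolute correlation of its time
    course with the low-passed (< ``lowpass_hz``) mean of the frontal-most
    channel pair exceeds ``corr_threshold``, or (when enabled) when its
    frontal/other scalp-weight ratio exceeds ``frontal_ratio_threshold``.
    """

    corr_threshold: float = 0.7
    lowpass_hz: float = 4.0
    frontal_channels: tuple[str, str] = ("Fp1", "Fp2")
    frontal_ratio_threshold: float | None = None  # disabled by default


def reject_artifacts(
    recording: EEGRecording,
    decomposition: ICADecomposition,
    criteria: RejectionCriteria = RejectionCriteria(),
) -> EEGRecording:
    """Rebuild the recording without components matching ``criteria``.

    Refuses (raises) when every component would be rejected, since that
    would zero the data. The rejected set and per-component statistics are
    logged in the decomposition and in the recording's provenance.
    """
    if tuple(recording.provenance) != decomposition.fitted_on:
        raise ValueError("decomposition was not fitted on this recording")
    m = recording.montage
    fp = recording.samples[m.indices(criteria.frontal_channels)].mean(axis=0)
    ref = _lowpass(fp, criteria.lowpass_hz, recording.sample_rate)
    frontal_idx = m.indices(m.frontal_set)
    other_idx = np.setdiff1d(np.arange(m.n_channels), frontal_idx)

    stats: dict[int, dict] = {}
    rejected: set[int] = set()
    for i in range(decomposition.n_components):
        s = decomposition.sources[i]
        r = (
            float(np.corrcoef(s, ref)[0, 1])
            if s.std() > 0 and ref.std() > 0
            else 0.0
        )
        col = np.abs(decomposition.mixing[:, i])
        other = col[other_idx].mean()
        ratio = float(col[frontal_idx].mean() / other) if other > 0 else np.inf
        stats[i] = {"frontal_corr": r, "frontal_ratio": ratio}
        if abs(r) > criteria.corr_threshold:
            rejected.add(i)
        elif (
            criteria.frontal_ratio_threshold is not None
            and ratio > criteria.frontal_ratio_threshold
        ):
            rejected.add(i)
    if len(rejected) == decomposition.n_components:
        raise ValueError(
            "criteria flag every component; refusing to zero the recording"
        )
    decomposition.rejected_components = rejected
    decomposition.rejection_criteria = stats
    cleaned = decomposition.reconstruct(reject=rejected)
    return recording.with_samples(
        cleaned, f"ica_reject(components={sorted(rejected)},seed={decomposition.seed})"
    )


# ---------------------------------------------------------------------------
# spatial filters / referencing
# ---------------------------------------------------------------------------

def surface_laplacian(recording: EEGRecording) -> EEGRecording:
    """Hjorth surface Laplacian: each channel minus the mean of its
    neighbours. A spatially uniform field maps to zero everywhere."""
    m = recording.montage
    out = np.empty_like(recording.samples)
    for i, name in enumerate(m.channel_names):
        nbrs = m.neighbours.get(name, ())
        if not nbrs:
            raise ValueError(f"channel {name!r} has no neighbours")
        out[i] = recording.samples[i] - recording.samples[m.indices(nbrs)].mean(axis=0)
    return recording.with_samples(out, "laplacian(hjorth,8nn)")


def to_average_reference(recording: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous across-channel mean; idempotent."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs >= 2 channels")
    if recording.reference_state == "average":
        return recording.copy()
    out = recording.samples - recording.samples.mean(axis=0, keepdims=True)
    return recording.with_samples(out, "average_reference", reference_state="average")


_CANONICAL = ("bandpass", "ica_reject", "laplacian", "average_reference")


def require_preprocessed(recording: EEGRecording) -> None:
    """Raise unless provenance shows the full chain in canonical order."""
    positions = []
    for tag in _CANONICAL:
        hits = [k for k, step in enumerate(recording.provenance) if step.startswith(tag)]
        if not hits:
            raise PipelineOrderError(f"missing conditioning step {tag!r}")
        positions.append(hits[0])
    if positions != sorted(positions):
        raise PipelineOrderError(
            f"conditioning steps out of order: {recording.provenance}"
        )
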