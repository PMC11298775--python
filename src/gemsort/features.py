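"""Low-dimensional spike features: PCA coefficients plus the channel position.

The PCA basis is trained once on a short initial batch of representative
spikes and frozen; each later spike is projected onto the first two
components.  The recording-channel index, scaled by ``channel_weight``, is
prepended so that similar-shaped spikes from different probe locations
land in separable feature regions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core import SpikeEvent


@dataclass
class PcaBasis:
    """Frozen PCA basis: orthonormal components, the training mean, and the
    per-component score SD used to standardise coefficients."""

    components: np.ndarray  # (n_components, W)
    mean_waveform: np.ndarray  # (W,)
    coeff_scale: np.ndarray  # (n_components,)
    training_count: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def window(self) -> int:
        return self.components.shape[1]


@dataclass
class FeatureVector:
    """One spike's feature point {scaled channel, a_0, a_1, ...}."""

    channel_feature: float
    coeffs: np.ndarray
    spike: SpikeEvent | None = None

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.channel_feature], np.asarray(self.coeffs, dtype=float)])


def align_waveform(waveform: np.ndarray) -> np.ndarray:
    """Shift a window so its interpolated |peak| sits exactly on the centre
    sample.

    The detector centres windows on the discrete extremum, which leaves up
    to half a sample of jitter (a full sample under noise); for narrow or
    oscillatory spikes that jitter dominates the within-cluster spread of
    the PCA coefficients.  The peak offset is estimated by parabolic
    interpolation through the three samples around the extremum and removed
    by linear resampling.
    """
    w = np.asarray(waveform, dtype=float)
    n = w.size
    m = int(np.argmax(np.abs(w)))
    delta = 0.0
    if 0 < m < n - 1:
        y0, y1, y2 = np.abs(w[m - 1]), np.abs(w[m]), np.abs(w[m + 1])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    shift = (m + delta) - n // 2
    if shift == 0.0:
        return w
    return np.interp(np.arange(n) + shift, np.arange(n), w, left=0.0, right=0.0)


def _waveforms(spikes: list[SpikeEvent] | np.ndarray, align: bool = True) -> np.ndarray:
    if isinstance(spikes, np.ndarray):
        stack = np.atleast_2d(spikes)
    else:
        stack = np.stack([s.waveform for s in spikes])
    if align:
        stack = np.stack([align_waveform(w) for w in stack])
    return stack


def fit_pca(training_spikes: list[SpikeEvent] | np.ndarray, n_components: int = 2) -> PcaBasis:
    """Mean-centred PCA on a training batch of equal-length waveforms.

    Components come out ordered by descending explained variance and
    mutually orthonormal.  Raises on degenerate input (too few spikes or a
    rank-0 covariance, e.g. identical waveforms).
    """
    X = _waveforms(training_spikes)
    if X.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} training spikes, got {X.shape[0]}"
        )
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate training set: zero waveform variance")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    scale = scores.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    return PcaBasis(
        components=pca.components_.copy(),
        mean_waveform=pca.mean_.copy(),
        coeff_scale=scale,
        training_count=X.shape[0],
    )


def project(spike: SpikeEvent | np.ndarray, basis: PcaBasis, align: bool = True) -> np.ndarray:
    """Coefficients a_n = <waveform - mean, f_n>, the discrete projection
    of the spike onto each principal component.

    ``align`` applies the same subsample peak alignment used when the
    basis was trained; disable it only for waveforms that are already
    aligned.
    """
    w = spike.waveform if isinstance(spike, SpikeEvent) else np.asarray(spike, dtype=float)
    if w.shape[-1] != basis.window:
        raise ValueError(
            f"waveform length {w.shape[-1]} does not match basis window {basis.window}"
        )
    if align and w.ndim == 1:
        w = align_waveform(w)
    return (w - basis.mean_waveform) @ basis.components.T


def build_feature(
    spike: SpikeEvent,
    coeffs: np.ndarray,
    channel_weight: float = 1.0,
    coeff_scale: np.ndarray | None = None,
    allow_zero_weight: bool = False,
) -> FeatureVector:
    """Prepend the scaled channel index to (optionally standardised) coefficients.

    ``channel_weight`` must be positive: a zero weight silently removes the
    positional information and is only permitted when explicitly requested
    for the shape-only ablation (``allow_zero_weight=True``).
    """
    if channel_weight <= 0 and not allow_zero_weight:
        raise ValueError(
            "channel_weight must be positive; pass allow_zero_weight=True for the "
            "shape-only ablation"
        )
    coeffs = np.asarray(coeffs, dtype=float)
    if coeff_scale is not None:
        coeffs = coeffs / np.asarray(coeff_scale, dtype=float)
    return FeatureVector(
        channel_feature=float(spike.channel * channel_weight),
        coeffs=coeffs,
        spike=spike,
    )
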