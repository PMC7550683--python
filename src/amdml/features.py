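"""Feature views for EEG segments: wavelet-packet, STFT band power, and KPCA.

Every extractor emits a fixed-length vector per segment; all views used in
one model must share a common dimensionality D because a single projection
H is applied to each view.  The dimension knobs are the WPD level
(2^level coefficients), the number of STFT bands, and the number of KPCA
components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.spatial.distance import pdist
from sklearn.decomposition import KernelPCA

from .data import EEGSegment, MultiViewDataset

#: Floor inside the log for energies, keeps all-zero signals finite.
LOG_FLOOR = 1e-12


def extract_wpd(
    segment: EEGSegment, wavelet: str = "db4", level: int = 3
) -> np.ndarray:
    """Log-energies of the terminal nodes of a full wavelet-packet tree.

    Returns 2**level values in frequency order (lowest band first), so
    coordinate b roughly covers frequencies [b, b+1] * rate / 2**(level+1).
    Energy of a node is the sum of squared coefficients; a floor of
    ``LOG_FLOOR`` inside the log keeps constant-zero segments finite.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    x = segment.samples
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"segment of {x.size} samples supports at most level {max_level} "
            f"for wavelet {wavelet!r}, requested {level}"
        )
    wp = pywt.WaveletPacket(x, wavelet=wavelet, maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    energies = np.array([np.sum(node.data**2) for node in nodes])
    return np.log(energies + LOG_FLOOR)


def extract_stft(
    segment: EEGSegment,
    window_length: int = 256,
    hop: int = 128,
    n_bands: int = 8,
) -> np.ndarray:
    """Per-band log mean power of the magnitude spectrogram.

    Frequencies 0..rate/2 are partitioned into ``n_bands`` equal bands;
    power in each band is averaged over frequency bins and time frames.
    """
    x = segment.samples
    if window_length > x.size:
        raise ValueError(
            f"window_length {window_length} exceeds segment length {x.size}"
        )
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    stft = sps.ShortTimeFFT(
        sps.windows.hann(window_length, sym=False),
        hop=hop,
        fs=segment.rate,
        scale_to="psd",
    )
    S = np.abs(stft.stft(x)) ** 2  # (freq bins, frames)
    power = S.mean(axis=1)
    freqs = stft.f
    edges = np.linspace(0.0, segment.rate / 2.0, n_bands + 1)
    out = np.empty(n_bands)
    for b in range(n_bands):
        hi_inclusive = b == n_bands - 1
        mask = (freqs >= edges[b]) & (
            (freqs <= edges[b + 1]) if hi_inclusive else (freqs < edges[b + 1])
        )
        out[b] = np.log(power[mask].mean() + LOG_FLOOR)
    return out


class KPCAExtractor:
    """Kernel PCA over raw segments: fit on training segments only.

    The kernel matrix is centred (standard KPCA); components are
    deterministic up to sign, fixed here by making the largest-magnitude
    training score of each component positive.  The default Gaussian
    kernel bandwidth follows the median pairwise-distance heuristic.
    """

    def __init__(
        self,
        n_components: int = 8,
        kernel: str = "rbf",
        gamma: float | None = None,
    ):
        self.n_components = n_components
        self.kernel = kernel
        self.gamma = gamma
        self._kpca: KernelPCA | None = None
        self._signs: np.ndarray | None = None

    def fit(self, segments_matrix: np.ndarray) -> "KPCAExtractor":
        """Fit on an L x N matrix of raw segments (segments in columns)."""
        X = np.asarray(segments_matrix, dtype=float).T  # sklearn: samples in rows
        n = X.shape[0]
        if self.n_components > n - 1:
            raise ValueError(
                f"n_components={self.n_components} must be <= N-1 = {n - 1}"
            )
        gamma = self.gamma
        if gamma is None and self.kernel == "rbf":
            med = np.median(pdist(X))
            gamma = 1.0 / (2.0 * med**2) if med > 0 else 1.0
        self._kpca = KernelPCA(
            n_components=self.n_components, kernel=self.kernel, gamma=gamma
        )
        scores = self._kpca.fit_transform(X)
        rank = np.sum(self._kpca.eigenvalues_ > 1e-10 * self._kpca.eigenvalues_[0])
        if rank < self.n_components:
            raise ValueError(
                f"kernel matrix rank {rank} < requested {self.n_components} "
                "components"
            )
        top = np.argmax(np.abs(scores), axis=0)
        self._signs = np.sign(scores[top, np.arange(scores.shape[1])])
        self._signs[self._signs == 0] = 1.0
        return self

    def transform(self, segments_matrix: np.ndarray) -> np.ndarray:
        """Map segments (columns) to n_components x N coordinates."""
        if self._kpca is None:
            raise RuntimeError("fit must be called before transform")
        scores = self._kpca.transform(np.asarray(segments_matrix, dtype=float).T)
        return (scores * self._signs).T


def fit_kpca(
    segments_matrix: np.ndarray,
    kernel: str = "rbf",
    n_components: int = 8,
    gamma: float | None = None,
) -> KPCAExtractor:
    """Convenience wrapper: fit a :class:`KPCAExtractor` on raw segments."""
    return KPCAExtractor(
        n_components=n_components, kernel=kernel, gamma=gamma
    ).fit(segments_matrix)


# ---------------------------------------------------------------------------
# Specs and the train/test pipeline


@dataclass(frozen=True)
class WPDSpec:
    wavelet: str = "db4"
    level: int = 3

    name = "WPD"

    @property
    def dim(self) -> int:
        return 2**self.level


@dataclass(frozen=True)
class STFTSpec:
    window_length: int = 256
    hop: int = 128
    n_bands: int = 8

    name = "STFT"

    @property
    def dim(self) -> int:
        return self.n_bands


@dataclass(frozen=True)
class KPCASpec:
    n_components: int = 8
    kernel: str = "rbf"
    gamma: float | None = None

    name = "KPCA"

    @property
    def dim(self) -> int:
        return self.n_components


def default_specs(dim: int = 8) -> list:
    """The three standard views (WPD, STFT, KPCA) at a common dimension."""
    level = int(np.log2(dim))
    if 2**level != dim:
        raise ValueError("dim must be a power of two so the WPD view can match")
    return [WPDSpec(level=level), STFTSpec(n_bands=dim), KPCASpec(n_components=dim)]


def _segments_matrix(segments: list[EEGSegment]) -> np.ndarray:
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"segments differ in length: {sorted(lengths)}")
    return np.column_stack([s.samples for s in segments])


class FeaturePipeline:
    """Extract all views with train-only state (KPCA fit, standardisation).

    ``fit`` learns the KPCA map and per-feature standardisation statistics
    on the training segments; ``transform`` applies them to any segments.
    This is the object the cross-validation harness refits per fold so no
    test-fold information leaks into feature extraction.
    """

    def __init__(self, specs: list, standardize: bool = True):
        dims = {spec.dim for spec in specs}
        if len(dims) != 1:
            raise ValueError(
                f"feature specs must share one output dimension, got {sorted(dims)}"
            )
        self.specs = specs
        self.standardize = standardize
        self._kpca: dict[int, KPCAExtractor] = {}
        self._stats: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _raw_view(self, i: int, spec, segments: list[EEGSegment]) -> np.ndarray:
        if isinstance(spec, WPDSpec):
            return np.column_stack(
                [extract_wpd(s, spec.wavelet, spec.level) for s in segments]
            )
        if isinstance(spec, STFTSpec):
            return np.column_stack(
                [
                    extract_stft(s, spec.window_length, spec.hop, spec.n_bands)
                    for s in segments
                ]
            )
        if isinstance(spec, KPCASpec):
            return self._kpca[i].transform(_segments_matrix(segments))
        raise TypeError(f"unknown feature spec {spec!r}")

    def fit(self, segments: list[EEGSegment]) -> "FeaturePipeline":
        for i, spec in enumerate(self.specs):
            if isinstance(spec, KPCASpec):
                self._kpca[i] = KPCAExtractor(
                    n_components=spec.n_components,
                    kernel=spec.kernel,
                    gamma=spec.gamma,
                ).fit(_segments_matrix(segments))
        if self.standardize:
            for i, spec in enumerate(self.specs):
                X = self._raw_view(i, spec, segments)
                mean = X.mean(axis=1, keepdims=True)
                sd = X.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                self._stats[i] = (mean, sd)
        return self

    def transform(
        self, segments: list[EEGSegment], labels: np.ndarray
    ) -> MultiViewDataset:
        views = []
        for i, spec in enumerate(self.specs):
            X = self._raw_view(i, spec, segments)
            if self.standardize:
                mean, sd = self._stats[i]
                X = (X - mean) / sd
            views.append((spec.name, X))
        return MultiViewDataset(views=views, labels=np.asarray(labels))


def assemble_views(
    segments: list[EEGSegment],
    labels: np.ndarray,
    feature_specs: list,
    standardize: bool = True,
) -> MultiViewDataset:
    """One-shot extraction: fit the pipeline on all segments and transform.

    For cross-validation use :class:`FeaturePipeline` directly so the KPCA
    map and standardisation statistics come from the training fold only.
    """
    pipe = FeaturePipeline(feature_specs, standardize=standardize).fit(segments)
    return pipe.transform(segments, labels)
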