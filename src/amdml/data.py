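"""Core data containers: single-channel EEG segments and multi-view feature sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Nominal sampling rate (Hz) of the Bonn segments as commonly cited.
DEFAULT_RATE = 173.6

#: The five Bonn group labels.
GROUPS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class EEGSegment:
    """One single-channel EEG time series.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in recording order (arbitrary units).
    rate : float
        Sampling rate in Hz; must be positive.
    group : str or None
        Categorical group label, one of ``A``–``E`` when known.
    source_id : str
        Opaque identifier of the file (or generator) of origin.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    group: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class MultiViewDataset:
    """Per-view feature matrices over the same samples plus a shared label vector.

    Each view is a ``D x N`` matrix (features in rows, samples in columns).
    All views must share the same number of samples ``N`` and, in this
    package, the same feature dimensionality ``D``, because one shared
    projection is applied to every view.
    """

    views: list[tuple[str, np.ndarray]]
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("at least one view is required")
        labels = np.asarray(self.labels)
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        n = labels.size
        views: list[tuple[str, np.ndarray]] = []
        dims = set()
        for name, X in self.views:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError(f"view {name!r} is not a matrix")
            if X.shape[1] != n:
                raise ValueError(
                    f"view {name!r} has {X.shape[1]} columns but there are {n} labels"
                )
            if not np.all(np.isfinite(X)):
                raise ValueError(f"view {name!r} contains non-finite entries")
            dims.add(X.shape[0])
            views.append((str(name), X))
        if len(dims) != 1:
            raise ValueError(f"views disagree on feature dimension: {sorted(dims)}")
        self.views = views
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def dim(self) -> int:
        """Common feature dimensionality D across views."""
        return self.views[0][1].shape[0]

    @property
    def view_names(self) -> list[str]:
        return [name for name, _ in self.views]

    def matrices(self) -> list[np.ndarray]:
        return [X for _, X in self.views]

    def subset(self, idx: np.ndarray) -> "MultiViewDataset":
        """Column subset (same views, selected samples)."""
        idx = np.asarray(idx)
        return MultiViewDataset(
            views=[(name, X[:, idx]) for name, X in self.views],
            labels=self.labels[idx],
            meta=dict(self.meta),
        )
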