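"""Per-window multi-frequency multilayer brain network (MMBN) construction.

Each EEG window yields one network layer per frequency band: channels are
the nodes and the edge weight between two channels is the Spearman rank
correlation of their band-limited signals,

    w = 1 - 6 * sum(d_l^2) / (L * (L^2 - 1)),

where ``d_l`` is the rank difference at sample ``l`` (exact for tie-free
data; with ties, average ranks followed by a product-moment correlation of
the ranks, which reduces to the same formula when ranks are unique). Within
each layer only the strongest 30% of the N(N-1)/2 undirected edges are
retained at their original weights — proportional thresholding — which fixes
edge density across windows and bands so that graph measures compare
topology rather than overall correlation level.

"Strongest" defaults to largest signed weight (most positive correlation);
magnitude ranking is available via ``by_magnitude``. Because the downstream
graph measures assume nonnegative weights, any negative weight that survives
thresholding is clipped to zero there, not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import stats

from .io import WindowSample
from .wavelet import BandSet, decompose_window

__all__ = [
    "LayerNetwork",
    "MultilayerNetwork",
    "spearman_weight",
    "spearman_matrix",
    "build_layer",
    "threshold_layer",
    "build_mmbn",
    "DEFAULT_KEEP_FRACTION",
]

DEFAULT_KEEP_FRACTION = 0.30


@dataclass
class LayerNetwork:
    """One weighted network layer (channels x channels) for one band.

    ``weights`` is symmetric with zero diagonal; before thresholding the
    off-diagonal entries are Spearman correlations in [-1, 1], after
    thresholding exactly ``ceil(keep_fraction * N(N-1)/2)`` undirected edges
    are nonzero.
    """

    weights: np.ndarray
    band_index: int
    thresholded: bool = False
    retained_fraction: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of nonzero undirected edges."""
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class MultilayerNetwork:
    """The per-window MMBN: one :class:`LayerNetwork` per frequency band.

    All layers share the node set (channels, in fixed order). ``label`` is
    the window's state (0 normal, 1 seizure) when known.
    """

    layers: list
    channel_labels: list = field(default_factory=list)
    label: int | None = None
    start_time: float | None = None
    band_edges: list = field(default_factory=list)

    def __post_init__(self):
        ns = {layer.n_nodes for layer in self.layers}
        if len(ns) > 1:
            raise ValueError("layers disagree on node count")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    def as_array(self) -> np.ndarray:
        """Stack layers into (n_layers, N, N)."""
        return np.stack([layer.weights for layer in self.layers])


def spearman_weight(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two equal-length series.

    Average ranks are used for ties; for tie-free data this equals
    ``1 - 6*sum(d^2)/(L*(L^2-1))`` exactly. A constant series has no rank
    ordering, so the weight is defined as 0 (with a warning) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series: Spearman weight undefined, using 0", stacklevel=2)
        return 0.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman_matrix(series: np.ndarray) -> np.ndarray:
    """All-pairs Spearman weights of the rows of ``series`` (N x L).

    Vectorized equivalent of calling :func:`spearman_weight` on every pair;
    zero-variance rows get zero weights to every other node.
    """
    series = np.asarray(series, dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, series)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", ranks, ranks))
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn("constant channel(s): Spearman weights set to 0", stacklevel=2)
        norms = np.where(degenerate, 1.0, norms)
    w = (ranks / norms[:, None]) @ (ranks / norms[:, None]).T
    w[degenerate, :] = 0.0
    w[:, degenerate] = 0.0
    np.fill_diagonal(w, 0.0)
    return np.clip(w, -1.0, 1.0)


def build_layer(bandset: BandSet, band_index: int) -> LayerNetwork:
    """Unthresholded Spearman layer for one frequency band of a window."""
    if not 0 <= band_index < bandset.n_bands:
        raise IndexError(f"band_index {band_index} outside 0..{bandset.n_bands - 1}")
    w = spearman_matrix(bandset.bands[:, band_index, :])
    return LayerNetwork(weights=w, band_index=band_index, thresholded=False)


def n_retained_edges(n_nodes: int, keep_fraction: float) -> int:
    """Edge count kept by proportional thresholding: ceil(f * N(N-1)/2)."""
    return ceil(keep_fraction * n_nodes * (n_nodes - 1) / 2)


def threshold_layer(
    layer: LayerNetwork,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    by_magnitude: bool = False,
) -> LayerNetwork:
    """Keep the strongest ``keep_fraction`` of undirected edges.

    Edges are ranked by signed weight (default) or by ``abs`` weight;
    survivors keep their original values, everything else becomes 0. Ties at
    the retention boundary break deterministically by lexicographic node-pair
    order, so results are reproducible.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if layer.thresholded:
        raise ValueError("layer is already thresholded")
    n = layer.n_nodes
    iu, ju = np.triu_indices(n, 1)
    vals = layer.weights[iu, ju]
    key = np.abs(vals) if by_magnitude else vals
    k = n_retained_edges(n, keep_fraction)
    # stable sort on descending key; equal keys keep (i, j) lexicographic order
    order = np.argsort(-key, kind="stable")[:k]
    w = np.zeros_like(layer.weights)
    w[iu[order], ju[order]] = vals[order]
    w += w.T
    return LayerNetwork(
        weights=w, band_index=layer.band_index, thresholded=True, retained_fraction=keep_fraction
    )


def build_mmbn(
    window: WindowSample,
    fs: float = 256.0,
    wavelet: str = "db4",
    level: int = 4,
    keep_fraction: float = DEFAULT_KEEP_FRACTION,
    by_magnitude: bool = False,
    channel_labels: list | None = None,
) -> MultilayerNetwork:
    """Build the thresholded MMBN of one window: decompose, correlate, prune.

    Returns one thresholded layer per retained frequency band (eight at the
    defaults), carrying the window's label.
    """
    bandset = decompose_window(window.data, fs=fs, wavelet=wavelet, level=level)
    layers = [
        threshold_layer(build_layer(bandset, b), keep_fraction=keep_fraction, by_magnitude=by_magnitude)
        for b in range(bandset.n_bands)
    ]
    return MultilayerNetwork(
        layers=layers,
        channel_labels=channel_labels or [f"ch{i}" for i in range(window.data.shape[0])],
        label=window.label,
        start_time=window.start_time,
        band_edges=bandset.band_edges,
    )
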