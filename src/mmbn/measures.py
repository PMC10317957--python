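"""Graph statistics of MMBN layers and normal-vs-seizure comparison.

Four measures summarize each layer's weighted adjacency matrix W (symmetric,
nonnegative, zero diagonal, N nodes):

* average clustering coefficient C-bar = mean_v C(v), with the weighted
  clustering of node v defined through ordered triples,
  C(v) = sum_{k != a, both != v} W[v,k] W[v,a] W[k,a] / (k_v (k_v - 1)),
  where k_v = sum_{k != v} W[v,k] is the node strength; C(v) := 0 when the
  denominator is below 1e-12 (isolated or single-edge nodes on sparse
  thresholded layers);
* clustering-coefficient entropy E_C = -sum_v P(v) log P(v) in nats, with
  P(v) = C(v) / sum_u C(u) (0 log 0 := 0; all-zero clustering gives 0),
  maximal at log N when clustering is uniform;
* spectral radius R = max_v |lambda_v| over the eigenvalues of W;
* graph energy E = sum_v |lambda_v| (the nuclear norm; E >= R always).

Thresholded layers may retain negative correlations under signed ranking;
these are clipped to zero here (with a warning) since the triangle products
and strengths presuppose nonnegative weights.

Group comparison mirrors the usual ictal-vs-interictal analysis: a Welch
(unequal-variance) two-sample t-test per measure and band across windows,
with significance tiers at p < 0.05 (*) and p < 0.001 (**).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import LayerNetwork, MultilayerNetwork

__all__ = [
    "LayerMeasures",
    "StateComparison",
    "node_strength",
    "clustering_coefficient",
    "layer_measures",
    "measures_table",
    "compare_states",
    "MEASURE_NAMES",
]

MEASURE_NAMES = ("avg_clustering", "clustering_entropy", "spectral_radius", "graph_energy")

_EPS = 1e-12


def _checked_weights(weights: np.ndarray, clip_negative: bool = True) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    if (w < 0).any():
        if not clip_negative:
            raise ValueError("negative weights not allowed")
        warnings.warn("negative weights clipped to 0 for graph measures", stacklevel=3)
        w = np.maximum(w, 0.0)
    return w


def node_strength(weights: np.ndarray, v: int | None = None):
    """Weighted degree k_v: row sum excluding the diagonal.

    Returns all strengths when ``v`` is None.
    """
    w = _checked_weights(weights, clip_negative=False)
    k = w.sum(axis=1)
    return k if v is None else float(k[v])


def clustering_coefficient(weights: np.ndarray, v: int | None = None):
    """Weighted clustering coefficient C(v) via ordered-triple products.

    Returns the vector of all C(v) when ``v`` is None. Nodes with strength
    denominator k_v (k_v - 1) < 1e-12 get C(v) = 0.
    """
    w = _checked_weights(weights)
    k = w.sum(axis=1)
    # ordered-pair triangle sum around each node: diag(W^3)
    tri = np.einsum("vk,ka,av->v", w, w, w)
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > _EPS, tri / np.where(denom > _EPS, denom, 1.0), 0.0)
    return c if v is None else float(c[v])


@dataclass
class LayerMeasures:
    """The four statistics of one layer."""

    avg_clustering: float
    clustering_entropy: float
    spectral_radius: float
    graph_energy: float

    def as_tuple(self) -> tuple:
        return (self.avg_clustering, self.clustering_entropy, self.spectral_radius, self.graph_energy)


def layer_measures(layer: LayerNetwork | np.ndarray) -> LayerMeasures:
    """Compute all four measures of one (thresholded) layer.

    Entropy uses the natural logarithm, so E_C is in nats and bounded by
    log N.
    """
    weights = layer.weights if isinstance(layer, LayerNetwork) else layer
    w = _checked_weights(weights)
    c = clustering_coefficient(w)
    cbar = float(c.mean())
    csum = c.sum()
    if csum > _EPS:
        p = c[c > 0] / csum
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0
    lam = np.linalg.eigvalsh(w)
    return LayerMeasures(
        avg_clustering=cbar,
        clustering_entropy=entropy,
        spectral_radius=float(np.abs(lam).max()) if lam.size else 0.0,
        graph_energy=float(np.abs(lam).sum()),
    )


def measures_table(networks: list) -> pd.DataFrame:
    """Tidy per-window, per-band measure table.

    Columns: window_id, band, the four measures, label.
    """
    rows = []
    for wid, net in enumerate(networks):
        for layer in net.layers:
            m = layer_measures(layer)
            rows.append(
                {
                    "window_id": wid,
                    "band": layer.band_index,
                    "avg_clustering": m.avg_clustering,
                    "clustering_entropy": m.clustering_entropy,
                    "spectral_radius": m.spectral_radius,
                    "graph_energy": m.graph_energy,
                    "label": net.label,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StateComparison:
    """Welch t-test results per measure (optionally per band).

    ``table`` columns: band (or 'pooled'), measure, mean_normal,
    mean_seizure, t, p, significance ('' / '*' / '**').
    """

    table: pd.DataFrame

    def significant(self, tier: str = "*") -> pd.DataFrame:
        thr = {"*": 0.05, "**": 0.001}[tier]
        return self.table[self.table["p"] < thr]


def _tier(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        warnings.warn("zero variance in both groups: p set to 1", stacklevel=3)
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_states(
    measures_normal,
    measures_seizure,
    per_band: bool = True,
) -> StateComparison:
    """Compare the two state groups measure-by-measure.

    Inputs are either lists of :class:`LayerMeasures` (single-band use, one
    test per measure) or tidy tables from :func:`measures_table` (tests per
    band, plus pooled rows when ``per_band`` is False).
    """
    if isinstance(measures_normal, pd.DataFrame):
        dfn, dfs = measures_normal, measures_seizure
    else:
        if len(measures_normal) < 2 or len(measures_seizure) < 2:
            raise ValueError("need at least 2 samples per group")
        dfn = pd.DataFrame([dict(zip(MEASURE_NAMES, m.as_tuple()), band=0) for m in measures_normal])
        dfs = pd.DataFrame([dict(zip(MEASURE_NAMES, m.as_tuple()), band=0) for m in measures_seizure])
    rows = []
    bands = sorted(set(dfn["band"])) if per_band else ["pooled"]
    for band in bands:
        sel_n = dfn if band == "pooled" else dfn[dfn["band"] == band]
        sel_s = dfs if band == "pooled" else dfs[dfs["band"] == band]
        if len(sel_n) < 2 or len(sel_s) < 2:
            raise ValueError(f"need at least 2 samples per group in band {band}")
        for meas in MEASURE_NAMES:
            a = sel_n[meas].to_numpy()
            b = sel_s[meas].to_numpy()
            t, p = _welch(a, b)
            rows.append(
                {
                    "band": band,
                    "measure": meas,
                    "mean_normal": float(a.mean()),
                    "mean_seizure": float(b.mean()),
                    "t": t,
                    "p": p,
                    "significance": _tier(p),
                }
            )
    return StateComparison(table=pd.DataFrame(rows))
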