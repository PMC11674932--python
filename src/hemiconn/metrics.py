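"""Hemispheric connectivity measures.

Four measures per subject, two interhemispheric and two intrahemispheric:

* commissural ratio — fraction of streamline weight whose endpoints lie in
  opposite hemispheres, over total streamline weight;
* CC ratio — corpus callosum midsagittal area normalized by brain volume
  (area / volume^(2/3) so the quotient is dimensionless);
* mean shortest path length (SPL) — mean graph distance over node pairs
  within one hemisphere, averaged across hemispheres (lower = stronger);
* efficiency — mean inverse graph distance over node pairs, averaged across
  hemispheres (higher = stronger; robust to disconnected pairs).

Plus the four inter/intra ratios crossing {commissural, CC} with
{SPL, efficiency}.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome, DistanceGraph, hemisphere_blocks, to_distance_graph

__all__ = [
    "UndefinedMetricError",
    "HemisphericMetrics",
    "PathStats",
    "commissural_ratio",
    "cc_ratio",
    "path_stats",
    "mean_spl",
    "efficiency",
    "subject_metrics",
]

DEFAULT_CC_EXPONENT = 2.0 / 3.0


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (e.g. zero total weight)."""


class PathStats(NamedTuple):
    """Shortest-path summary of a distance graph.

    mean_spl averages over *reachable* unordered pairs; efficiency averages
    1/d over *all* unordered pairs with unreachable pairs contributing 0.
    """

    mean_spl: float
    efficiency: float
    n_pairs: int
    n_unreachable: int


@dataclass(frozen=True)
class HemisphericMetrics:
    """The four connectivity measures and four inter/intra ratios for one subject."""

    commissural_ratio: float
    cc_ratio: float
    spl_left: float
    spl_right: float
    spl_mean: float
    eff_left: float
    eff_right: float
    eff_mean: float
    ratio_commissural_spl: float
    ratio_commissural_eff: float
    ratio_ccratio_spl: float
    ratio_ccratio_eff: float
    n_unreachable_pairs: int = 0

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def commissural_ratio(inter_weight_sum: float, total_weight_sum: float) -> float:
    """Share of connection weight crossing between hemispheres."""
    if total_weight_sum <= 0:
        raise UndefinedMetricError("total weight sum must be positive")
    if not 0 <= inter_weight_sum <= total_weight_sum:
        raise UndefinedMetricError(
            f"inter weight sum {inter_weight_sum} outside [0, {total_weight_sum}]"
        )
    return inter_weight_sum / total_weight_sum


def cc_ratio(cc_area: float, brain_volume: float, *, exponent: float = DEFAULT_CC_EXPONENT) -> float:
    """Corpus callosum midsagittal area over brain volume^exponent.

    The default exponent 2/3 renders the quotient dimensionless
    (area / area); it is configurable for sensitivity analyses.
    """
    if cc_area <= 0 or brain_volume <= 0:
        raise UndefinedMetricError("cc_area and brain_volume must be positive")
    return cc_area / brain_volume**exponent


def _pairwise_distances(g: DistanceGraph) -> np.ndarray:
    n = g.n_nodes
    sparse = csr_matrix(g.edge_length)
    return dijkstra(sparse, directed=False, indices=np.arange(n))


def path_stats(g: DistanceGraph) -> PathStats:
    """Mean SPL and efficiency of a distance graph in one pass.

    Disconnected pairs: excluded from the SPL mean (and counted), and
    contribute 0 to efficiency.
    """
    n = g.n_nodes
    if n < 2:
        raise UndefinedMetricError(f"need >= 2 nodes, got {n}")
    dist = _pairwise_distances(g)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    reachable = np.isfinite(d)
    n_pairs = d.size
    n_unreachable = int(n_pairs - reachable.sum())
    spl = float(d[reachable].mean()) if reachable.any() else float("inf")
    eff = float(np.sum(1.0 / d[reachable]) / n_pairs)
    return PathStats(spl, eff, n_pairs, n_unreachable)


def mean_spl(g: DistanceGraph) -> float:
    """Mean shortest path length over reachable unordered node pairs."""
    return path_stats(g).mean_spl


def efficiency(g: DistanceGraph) -> float:
    """Mean inverse shortest path length over all unordered node pairs."""
    return path_stats(g).efficiency


def subject_metrics(
    c: Connectome,
    cc_area: float,
    brain_volume: float,
    *,
    cc_exponent: float = DEFAULT_CC_EXPONENT,
    on_midline: str = "warn",
) -> HemisphericMetrics:
    """Full per-subject metric chain on a cortical, length-normalized connectome.

    Splits the connectome into hemispheres, computes the commissural ratio
    from the hemispheric weight sums, per-hemisphere SPL and efficiency on
    the inverse-weight distance graphs, and the four inter/intra ratios
    (each interhemispheric measure divided by each averaged intrahemispheric
    measure).
    """
    left, right, inter, total = hemisphere_blocks(c, on_midline=on_midline)
    comm = commissural_ratio(inter, total)
    ccr = cc_ratio(cc_area, brain_volume, exponent=cc_exponent)
    stats_l = path_stats(to_distance_graph(left))
    stats_r = path_stats(to_distance_graph(right))
    spl_m = (stats_l.mean_spl + stats_r.mean_spl) / 2.0
    eff_m = (stats_l.efficiency + stats_r.efficiency) / 2.0
    return HemisphericMetrics(
        commissural_ratio=comm,
        cc_ratio=ccr,
        spl_left=stats_l.mean_spl,
        spl_right=stats_r.mean_spl,
        spl_mean=spl_m,
        eff_left=stats_l.efficiency,
        eff_right=stats_r.efficiency,
        eff_mean=eff_m,
        ratio_commissural_spl=comm / spl_m,
        ratio_commissural_eff=comm / eff_m,
        ratio_ccratio_spl=ccr / spl_m,
        ratio_ccratio_eff=ccr / eff_m,
        n_unreachable_pairs=stats_l.n_unreachable + stats_r.n_unreachable,
    )
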