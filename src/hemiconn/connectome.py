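"""Connectome containers and the matrix-to-graph preparation steps.

A connectome here is a pair of symmetric matrices over a labeled
parcellation: streamline-derived connection weights (SIFT2-weighted counts
or any derived strength) and mean fiber lengths in mm. Regions carry a
hemisphere tag (L, R, or M for midline) and a cortical flag. The analysis
chain is: divide weights by fiber length, restrict to cortical regions,
split into hemispheric blocks, and invert weights into graph distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Connectome",
    "DistanceGraph",
    "InvalidConnectomeError",
    "normalize_by_length",
    "cortical_subgraph",
    "to_distance_graph",
    "hemisphere_blocks",
]

_SYMMETRY_TOL = 1e-9
_VALID_HEMIS = frozenset({"L", "R", "M"})


class InvalidConnectomeError(ValueError):
    """A connectome violates its structural invariants."""


@dataclass(frozen=True)
class Connectome:
    """Labeled symmetric weight + fiber-length matrices.

    Parameters
    ----------
    labels : ordered region identifiers.
    hemisphere : per-region tag in {"L", "R", "M"}.
    cortical : per-region boolean flag.
    weights : symmetric non-negative matrix, zero diagonal.
    lengths : symmetric matrix, mm; positive wherever ``weights`` is positive.
    """

    labels: tuple[str, ...]
    hemisphere: np.ndarray
    cortical: np.ndarray
    weights: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere, dtype=object))
        object.__setattr__(self, "cortical", np.asarray(self.cortical, dtype=bool))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def validate(self) -> "Connectome":
        """Check every invariant; raise :class:`InvalidConnectomeError` on failure."""
        n = self.n_regions
        w, ln = self.weights, self.lengths
        if w.shape != (n, n) or ln.shape != (n, n):
            raise InvalidConnectomeError(
                f"matrix shapes {w.shape}/{ln.shape} do not match {n} labels"
            )
        if len(self.hemisphere) != n or len(self.cortical) != n:
            raise InvalidConnectomeError("hemisphere/cortical tags do not match label count")
        bad = set(self.hemisphere) - _VALID_HEMIS
        if bad:
            raise InvalidConnectomeError(f"invalid hemisphere tags: {sorted(bad)}")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(ln)):
            raise InvalidConnectomeError("non-finite matrix entries")
        if np.max(np.abs(w - w.T), initial=0.0) > _SYMMETRY_TOL:
            raise InvalidConnectomeError("weight matrix is not symmetric")
        if np.max(np.abs(ln - ln.T), initial=0.0) > _SYMMETRY_TOL:
            raise InvalidConnectomeError("length matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidConnectomeError("weight diagonal is not zero")
        if np.any(w < 0):
            raise InvalidConnectomeError("negative weights")
        if np.any((w > 0) & (ln <= 0)):
            raise InvalidConnectomeError("non-positive fiber length on a connected pair")
        cort_hemis = set(self.hemisphere[self.cortical])
        if not {"L", "R"} <= cort_hemis:
            raise InvalidConnectomeError(
                "need at least one cortical region per hemisphere, "
                f"found cortical tags {sorted(cort_hemis)}"
            )
        return self

    def subset(self, index: np.ndarray) -> "Connectome":
        """Restrict to the regions selected by a boolean or integer index."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Connectome(
            labels=tuple(self.labels[i] for i in index),
            hemisphere=self.hemisphere[index],
            cortical=self.cortical[index],
            weights=self.weights[np.ix_(index, index)],
            lengths=self.lengths[np.ix_(index, index)],
        )


@dataclass(frozen=True)
class DistanceGraph:
    """Weighted graph whose edge lengths are inverse connection strengths.

    ``edge_length[i, j] > 0`` means an edge; 0 means no edge (an absent
    connection is never stored as an infinite length).
    """

    labels: tuple[str, ...]
    hemisphere: np.ndarray
    edge_length: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere, dtype=object))
        object.__setattr__(self, "edge_length", np.asarray(self.edge_length, dtype=float))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def normalize_by_length(c: Connectome) -> Connectome:
    """Divide each connection weight by its mean fiber length.

    Down-weights long-range connections so that streamline counts are not
    biased toward longer fibers. Lengths are carried through unchanged.
    Not idempotent: applying twice divides by length twice.
    """
    c.validate()
    out = np.zeros_like(c.weights)
    mask = c.weights > 0
    out[mask] = c.weights[mask] / c.lengths[mask]
    return replace(c, weights=out)


def cortical_subgraph(c: Connectome) -> Connectome:
    """Restrict the connectome to cortical regions only."""
    if not np.any(c.cortical):
        raise InvalidConnectomeError("connectome has no cortical regions")
    return c.subset(c.cortical)


def to_distance_graph(c: Connectome) -> DistanceGraph:
    """Invert connection weights into graph edge lengths.

    Stronger (length-normalized) connections become shorter edges:
    ``edge_length = 1 / weight`` where weight > 0, no edge otherwise.
    The caller is responsible for length-normalizing first; the pipeline
    enforces the order normalize -> cortical subset -> invert.
    """
    edge = np.zeros_like(c.weights)
    mask = c.weights > 0
    edge[mask] = 1.0 / c.weights[mask]
    return DistanceGraph(labels=c.labels, hemisphere=c.hemisphere, edge_length=edge)


def hemisphere_blocks(
    c: Connectome, *, on_midline: str = "warn"
) -> tuple[Connectome, Connectome, float, float]:
    """Partition a connectome into hemispheric blocks.

    Returns ``(left, right, inter_weight_sum, total_weight_sum)`` where the
    sums run over unordered region pairs: ``inter_weight_sum`` over pairs
    whose endpoints lie in opposite hemispheres, ``total_weight_sum`` over
    all pairs. By conservation of weight mass,
    ``inter + within-left + within-right == total`` exactly.

    Parameters
    ----------
    on_midline : "warn" (default) drops midline (M) regions with a warning;
        "error" raises.
    """
    is_mid = c.hemisphere == "M"
    if np.any(is_mid):
        if on_midline == "error":
            raise InvalidConnectomeError(
                f"{int(is_mid.sum())} midline regions in hemispheric partition"
            )
        warnings.warn(
            f"MIDLINE_EXCLUDED n={int(is_mid.sum())}: dropping midline regions "
            "from the hemispheric partition",
            stacklevel=2,
        )
        c = c.subset(~is_mid)
    left = c.subset(c.hemisphere == "L")
    right = c.subset(c.hemisphere == "R")
    iu = np.triu_indices(c.n_regions, k=1)
    total = float(c.weights[iu].sum())
    inter_mask = (c.hemisphere[iu[0]] != c.hemisphere[iu[1]])
    inter = float(c.weights[iu][inter_mask].sum())
    return left, right, inter, total
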