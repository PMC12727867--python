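"""Frequency comparison across 2-D environmental space.

For a pair of covariates (say MAT and MAP) three weighted 2-D histograms are
built on shared bin edges: *occurrence* (a uniform background sample of domain
pixels — the realized distribution of conditions), *sampling* (one unit per
field location), and *citations* (locations weighted by their allocated
citations).  Representative sampling would make the three distributions
proportional; mass missing from the sampling/citation histograms where
occurrence has mass marks under-studied conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EnvHistogram2D", "bin2d", "shared_edges", "env_space_comparison",
           "DEFAULT_PAIRS"]

#: Default covariate pairs, one per histogram row.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("MAT", "MAP"),
    ("dMAT", "dMAP"),
    ("LAI", "SOC"),
    ("plant_rich", "animal_rich"),
)


@dataclass
class EnvHistogram2D:
    """Binned weights over a pair of environmental axes.

    ``weights[i, j]`` is the mass in x-bin ``i``, y-bin ``j`` (bins are
    right-open, the last bin right-closed).  ``n_dropped`` counts input rows
    with missing or out-of-range coordinates; their weight is
    ``dropped_weight`` so total mass is conserved.
    """

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    weights: np.ndarray
    total_weight: float
    n_dropped: int
    dropped_weight: float

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("negative histogram mass")

    def to_dict(self) -> dict:
        return {
            "x_name": self.x_name,
            "y_name": self.y_name,
            "x_edges": self.x_edges.tolist(),
            "y_edges": self.y_edges.tolist(),
            "weights": self.weights.tolist(),
            "total_weight": self.total_weight,
            "n_dropped": self.n_dropped,
            "dropped_weight": self.dropped_weight,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    def to_long_frame(self) -> pd.DataFrame:
        xi, yi = np.nonzero(self.weights)
        return pd.DataFrame(
            {"x_bin": xi, "y_bin": yi, "weight": self.weights[xi, yi]}
        )


def bin2d(
    x: Sequence[float],
    y: Sequence[float],
    x_edges: Sequence[float],
    y_edges: Sequence[float],
    w: Sequence[float] | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> EnvHistogram2D:
    """Weighted 2-D histogram with right-open bins (last bin closed).

    Rows with a non-finite coordinate or weight, or falling outside the edge
    range, are dropped and tallied in ``n_dropped`` / ``dropped_weight``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and w must have equal length")
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(y_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    finite = np.isfinite(x) & np.isfinite(y) & np.isfinite(w)
    if np.any(w[finite] < 0):
        raise ValueError("negative weights are not allowed")
    in_range = (
        finite
        & (x >= x_edges[0]) & (x <= x_edges[-1])
        & (y >= y_edges[0]) & (y <= y_edges[-1])
    )
    weights, _, _ = np.histogram2d(
        x[in_range], y[in_range], bins=[x_edges, y_edges], weights=w[in_range]
    )
    total = float(np.nansum(np.where(np.isfinite(w), w, 0.0)))
    dropped_w = total - float(weights.sum())
    return EnvHistogram2D(
        x_name=x_name,
        y_name=y_name,
        x_edges=x_edges,
        y_edges=y_edges,
        weights=weights,
        total_weight=total,
        n_dropped=int((~in_range).sum()),
        dropped_weight=dropped_w,
    )


def shared_edges(
    background: pd.DataFrame,
    locations: pd.DataFrame,
    name: str,
    n_bins: int = 50,
    expand: float = 0.001,
) -> np.ndarray:
    """Bin edges from the pooled range of background and location values.

    The pooled min/max is expanded by ``expand`` (fraction of the range) so
    extreme values land inside the closed outer bins.
    """
    pooled = np.concatenate(
        [background[name].to_numpy(dtype=float), locations[name].to_numpy(dtype=float)]
    )
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValueError(f"no finite values for covariate {name!r}")
    lo, hi = float(pooled.min()), float(pooled.max())
    pad = (hi - lo) * expand or max(abs(lo), 1.0) * expand
    return np.linspace(lo - pad, hi + pad, n_bins + 1)


def env_space_comparison(
    background: pd.DataFrame,
    locations: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    n_bins: int = 50,
    citation_col: str = "allocated_citations",
) -> dict[tuple[str, str], dict[str, EnvHistogram2D]]:
    """Occurrence / sampling / citation histograms per covariate pair.

    All three histograms of a pair share edges derived from the pooled
    background and location values, so their shapes are directly comparable.
    """
    out: dict[tuple[str, str], dict[str, EnvHistogram2D]] = {}
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in background.columns or name not in locations.columns:
                raise KeyError(f"unknown covariate {name!r}")
        xe = shared_edges(background, locations, x_name, n_bins)
        ye = shared_edges(background, locations, y_name, n_bins)
        out[(x_name, y_name)] = {
            "occurrence": bin2d(
                background[x_name], background[y_name], xe, ye,
                x_name=x_name, y_name=y_name,
            ),
            "sampling": bin2d(
                locations[x_name], locations[y_name], xe, ye,
                x_name=x_name, y_name=y_name,
            ),
            "citations": bin2d(
                locations[x_name], locations[y_name], xe, ye,
                w=locations[citation_col], x_name=x_name, y_name=y_name,
            ),
        }
    return out
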