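"""Distinct-neighbour-pair (DNP) site-aggregation statistic.

For every lattice site with a non-empty state, each of its six hexagonal
neighbour relations to another non-empty site is one neighbour-pair link (NP);
a link whose two states differ is a distinct-neighbour-pair link (DNP). With
``alpha`` the total DNP count and ``beta`` the total NP count, the DNP
concentration is ``C = alpha / beta`` and site aggregation is ``1 - C``:
high aggregation means same-state crypts are spatially clustered (domain
coarsening), empty sites are ignored throughout.

Links are counted over the multiset of ordered neighbour relations (each
unordered pair contributes twice); the ratio C is unaffected by the ordering
convention. For half-lattice values each link is attributed to the half
containing the focal site, so links crossing the half boundary enter both
halves' denominators once each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .lattice import NEIGHBOUR_OFFSETS, LatticeState

__all__ = ["AggregationValue", "site_aggregation"]

_REGIONS = ("whole", "left", "right")


@dataclass(frozen=True)
class AggregationValue:
    """Link counts and derived aggregation for one lattice region."""

    alpha: int
    beta: int

    @property
    def defined(self) -> bool:
        """False when the region has no non-empty neighbour pairs (beta = 0)."""
        return self.beta > 0

    @property
    def concentration(self) -> float:
        """C = alpha / beta; NaN when undefined."""
        return self.alpha / self.beta if self.defined else math.nan

    @property
    def aggregation(self) -> float:
        """Site aggregation 1 - C; NaN when undefined (never reported as 0)."""
        return 1.0 - self.concentration if self.defined else math.nan


def site_aggregation(
    state: Union[LatticeState, np.ndarray], region: str = "whole"
) -> AggregationValue:
    """Compute alpha/beta link counts on a lattice state.

    Parameters
    ----------
    state
        A :class:`~cryptclones.lattice.LatticeState` or a raw square grid with
        entries in {-1, 0, +1}.
    region
        ``"whole"``, ``"left"`` (focal columns 0..M/2-1) or ``"right"``
        (focal columns M/2..M-1).
    """
    grid = state.grid if isinstance(state, LatticeState) else np.asarray(state)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError("grid must be square")
    if region not in _REGIONS:
        raise ValueError(f"region must be one of {_REGIONS}, got {region!r}")

    M = grid.shape[0]
    if region == "whole":
        focal = np.ones((M, M), dtype=bool)
    else:
        focal = np.zeros((M, M), dtype=bool)
        if region == "left":
            focal[:, : M // 2] = True
        else:
            focal[:, M // 2 :] = True

    occ = grid != 0
    alpha = 0
    beta = 0
    for di, dj in NEIGHBOUR_OFFSETS:
        nbr = np.roll(grid, shift=(-di, -dj), axis=(0, 1))
        both = focal & occ & (nbr != 0)
        beta += int(both.sum())
        alpha += int((both & (nbr != grid)).sum())
    return AggregationValue(alpha=alpha, beta=beta)
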