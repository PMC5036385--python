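"""Community summary statistics: Shannon–Wiener diversity and shared OTUs.

The Shannon–Wiener index H' = −Σ p_i ln p_i (natural log, i.e. nats) over the
relative abundances p_i of the R taxa in a profile measures alpha diversity:
0 for a single-taxon community, ln R for a perfectly even one. The shared-OTU
operation decomposes k group OTU sets into all 2^k − 1 exclusive Venn regions
(a partition of the union), the basis for cross-group comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ProfileError
from .profiling import TaxonProfile


@dataclass(frozen=True)
class AbundanceVector:
    """Relative abundances with richness R and Shannon–Wiener index H'."""

    p: np.ndarray
    richness: int
    h_prime: float


def shannon_wiener(profile: TaxonProfile, base: float | None = None) -> AbundanceVector:
    """Shannon–Wiener diversity of a taxon profile.

    Raw counts are normalised to fractions internally; taxa with zero count
    do not contribute (the 0·ln 0 = 0 convention) and are excluded from the
    richness R. ``base`` switches the logarithm (default natural log, nats).
    """
    values = np.array([c for c in profile.counts.values() if c > 0], dtype=float)
    if values.size == 0:
        raise ProfileError("diversity of an empty or all-zero profile is undefined")
    p = values / values.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return AbundanceVector(p=p, richness=int(values.size), h_prime=h)


def shared_otus(groups: dict[str, set]) -> dict[str, set]:
    """All 2^k − 1 exclusive Venn regions of k ≥ 2 group OTU sets.

    Region labels join the member group names with ``&`` (in the groups'
    given order); each region holds the taxa present in exactly those groups,
    so the regions partition the union of all sets. Empty regions are
    included so every region is always addressable.
    """
    if len(groups) < 2:
        raise ProfileError("shared-OTU analysis requires at least 2 groups")
    labels = list(groups)
    universe = set().union(*groups.values())
    regions: dict[str, set] = {}
    for r in range(1, len(labels) + 1):
        for members in itertools.combinations(labels, r):
            region = set(universe)
            for lab in labels:
                if lab in members:
                    region &= groups[lab]
                else:
                    region -= groups[lab]
            regions["&".join(members)] = region
    return regions


def group_summary(indices: dict[str, list[float]]) -> pd.DataFrame:
    """Mean/min/max of per-sample diversity indices for each group.

    Mirrors box-plot style aggregation of H' values across a group's member
    samples; no inferential statistics are computed.
    """
    rows = [
        {
            "group": g,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }
        for g, vals in indices.items()
        if vals
    ]
    return pd.DataFrame(rows, columns=["group", "n", "mean", "min", "max"])
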