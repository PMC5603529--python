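"""Centroid nearest-neighbour colocalization between two punctate channels.

Each punctum in the query channel is matched to its nearest punctum (by
centre-of-mass Euclidean distance) in the reference channel; the pair counts
as colocalized when the distance is strictly less than a threshold, by
default the average endosome equivalent-disk diameter of the query channel.
Matching is directional (query -> reference) and many-to-one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .segmentation import LabeledRegions

__all__ = [
    "ColocResult",
    "coloc_threshold",
    "colocalization_fraction",
    "pulse_chase_coloc_compare",
]


@dataclass
class ColocResult:
    n_query: int
    n_matched: int
    percent: float
    threshold_px: float
    distances_px: np.ndarray
    direction: str = "ch1->ch2"

    def __post_init__(self):
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError("percent out of [0, 100]")
        if self.n_matched > self.n_query:
            raise ValueError("n_matched cannot exceed n_query")

    def to_dict(self) -> dict:
        return {
            "n_query": self.n_query,
            "n_matched": self.n_matched,
            "percent": self.percent,
            "threshold_px": self.threshold_px,
            "direction": self.direction,
        }


def coloc_threshold(regions_ch1: LabeledRegions) -> float:
    """Matching threshold: mean equivalent-disk diameter (px) of the query
    channel's regions, ``mean(2 * sqrt(area / pi))``."""
    if len(regions_ch1) == 0:
        raise ValueError("no regions: threshold undefined")
    return float(regions_ch1.table["eq_diameter_px"].mean())


def colocalization_fraction(
    regions_ch1: LabeledRegions,
    regions_ch2: LabeledRegions,
    threshold: float | None = None,
) -> ColocResult:
    """Fraction of channel-1 puncta with a channel-2 punctum centre strictly
    closer than ``threshold`` (defaults to :func:`coloc_threshold` on
    channel 1).  Many-to-one matches are allowed."""
    if threshold is None:
        threshold = coloc_threshold(regions_ch1)
    q = regions_ch1.centroids()
    n_query = len(q)
    if n_query == 0:
        raise ValueError("no query regions")
    r = regions_ch2.centroids()
    if len(r) == 0:
        warnings.warn("empty reference channel: 0% colocalization", stacklevel=2)
        dists = np.full(n_query, np.inf)
    else:
        tree = cKDTree(r)
        dists, _ = tree.query(q)
    matched = dists < threshold
    return ColocResult(
        n_query=n_query,
        n_matched=int(matched.sum()),
        percent=100.0 * matched.mean(),
        threshold_px=float(threshold),
        distances_px=np.asarray(dists, dtype=float),
    )


def pulse_chase_coloc_compare(results_pulse, results_chase) -> dict:
    """Compare per-cell colocalization percentages between two conditions.

    Accepts lists of :class:`ColocResult` or plain percentages (>= 2 per
    condition).  Returns per-condition mean/SD/SEM and a pooled-variance
    two-tailed Student's t-test p-value.
    """

    def _percents(results):
        return np.array(
            [r.percent if isinstance(r, ColocResult) else float(r) for r in results]
        )

    a = _percents(results_pulse)
    b = _percents(results_chase)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 results per condition")
    if np.isclose(a.mean(), b.mean()) and a.std() == 0 and b.std() == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "mean_pulse": float(a.mean()),
        "sd_pulse": float(a.std(ddof=1)),
        "sem_pulse": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_chase": float(b.mean()),
        "sd_chase": float(b.std(ddof=1)),
        "sem_chase": float(b.std(ddof=1) / np.sqrt(len(b))),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "n_pulse": len(a),
        "n_chase": len(b),
    }
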