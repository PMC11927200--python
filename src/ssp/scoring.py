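"""Trajectory quality scores, ranking, and cross-tree aggregation.

Three diagnostics qualify a fitted trend:

* **sequentiality** — out of 100: the fraction of group transitions whose
  descriptor change follows the fitted trend direction;
* **fluctuation** — distinct residues divided by number of groups, high when
  the trajectory explores many states rather than oscillating between few;
* **break trend** — raised when the most recent transition moves against the
  fitted trend, i.e. the lineage may have already turned around.

Predictions rank best with no break, high sequentiality, high fluctuation.
Identical (site, mutation, scale) predictions from different trees are merged
by arithmetic averaging.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

from .aaindex import AAIndexScale
from .trajectory import Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrajectoryScore:
    sequentiality: float  # 0..100
    fluctuation: float  # in (0, 1]
    break_trend: float  # 0/1 per tree; mean fraction after aggregation


@dataclass(frozen=True)
class SitePrediction:
    """One per-tree prediction: a mutation proposed by one scale at one site
    (1-based ungapped target coordinates), with its trajectory scores."""

    tree_id: str
    site: int
    wild_type: str
    predicted_residue: str
    accession: str
    category: str
    slope: float
    score: TrajectoryScore

    @property
    def mutation(self) -> str:
        return f"{self.wild_type}{self.site}{self.predicted_residue}"


@dataclass(frozen=True)
class RankedPrediction:
    """A prediction merged across trees; scores are arithmetic means."""

    site: int
    wild_type: str
    predicted_residue: str
    accession: str
    category: str
    score: TrajectoryScore
    n_trees_supporting: int

    @property
    def mutation(self) -> str:
        return f"{self.wild_type}{self.site}{self.predicted_residue}"


def _scale_values(traj: Trajectory, scale: AAIndexScale) -> list[float]:
    return [scale[r] for r in traj.group_residues if r in scale]


def _consistent(dy: float, slope: float) -> bool:
    # a tie (no descriptor change across the substitution) never counts
    # against the trend
    return dy == 0 or math.copysign(1, dy) == math.copysign(1, slope) and slope != 0


def sequentiality(traj: Trajectory, scale: AAIndexScale, slope: float) -> float:
    """Score out of 100: share of transitions following the trend direction.

    A perfectly monotone trajectory under a same-signed slope scores 100; a
    trajectory whose every change opposes the slope scores 0.
    """
    values = _scale_values(traj, scale)
    if len(values) < 2:
        raise ValueError("sequentiality undefined without transitions")
    deltas = [b - a for a, b in zip(values, values[1:])]
    return 100.0 * sum(_consistent(d, slope) for d in deltas) / len(deltas)


def fluctuation(traj: Trajectory) -> float:
    """Distinct residues divided by number of groups (in (0, 1])."""
    if not traj.groups:
        raise ValueError("fluctuation undefined for an empty trajectory")
    return len(set(traj.group_residues)) / len(traj.groups)


def break_trend(
    traj: Trajectory,
    scale: AAIndexScale,
    slope: float,
    *,
    mode: str = "last",
) -> bool:
    """Whether the trajectory's most recent move opposes the fitted trend.

    ``mode="last"`` inspects the transition into the final group (default);
    ``mode="penultimate"`` the one before it. With fewer than two transitions
    the flag is undefined and reported as no-break with a warning. Ties
    (zero descriptor change) are consistent.
    """
    values = _scale_values(traj, scale)
    if len(values) < 3:
        logger.warning(
            "site %d: <2 transitions, break-trend undefined, treating as no break",
            traj.site,
        )
        return False
    if mode == "last":
        dy = values[-1] - values[-2]
    elif mode == "penultimate":
        dy = values[-2] - values[-3]
    else:
        raise ValueError(f"unknown break-trend mode {mode!r}")
    return dy != 0 and not _consistent(dy, slope)


def _rank_key(pred) -> tuple:
    s = pred.score
    return (
        float(s.break_trend),  # no break first
        -s.sequentiality,
        -s.fluctuation,
        pred.site,
        pred.accession,
        pred.predicted_residue,
    )


def rank(predictions: list) -> list:
    """Total order over predictions: no break first, then sequentiality and
    fluctuation descending, ties broken by site then accession."""
    return sorted(predictions, key=_rank_key)


def aggregate_across_trees(
    per_tree: list[SitePrediction],
) -> list[RankedPrediction]:
    """Merge identical (site, mutation, scale) predictions across trees.

    Scores are averaged arithmetically; the break flag becomes the fraction
    of supporting trees that flagged a break. Sites must agree on the wild
    type across trees — a mismatch signals inconsistent coordinates upstream.
    """
    wild_by_site: dict[int, str] = {}
    for p in per_tree:
        prev = wild_by_site.setdefault(p.site, p.wild_type)
        if prev != p.wild_type:
            raise ValueError(
                f"site {p.site}: wild type differs across trees "
                f"({prev!r} vs {p.wild_type!r}); alignment coordinates inconsistent"
            )

    buckets: dict[tuple, list[SitePrediction]] = defaultdict(list)
    for p in per_tree:
        buckets[(p.site, p.wild_type, p.predicted_residue, p.accession)].append(p)

    out = []
    for (site, wt, pred_res, acc), group in sorted(buckets.items()):
        n = len(group)
        score = TrajectoryScore(
            sequentiality=sum(p.score.sequentiality for p in group) / n,
            fluctuation=sum(p.score.fluctuation for p in group) / n,
            break_trend=sum(float(p.score.break_trend) for p in group) / n,
        )
        out.append(
            RankedPrediction(
                site=site,
                wild_type=wt,
                predicted_residue=pred_res,
                accession=acc,
                category=group[0].category,
                score=score,
                n_trees_supporting=len({p.tree_id for p in group}),
            )
        )
    return rank(out)
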