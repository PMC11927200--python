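"""Per-site trajectories and trend extrapolation.

A *trajectory* is one alignment column read along the main path, root first.
Consecutive identical residues are collapsed into *groups* — an amino acid
conserved across successive ancestors is one evolutionary state, so only
boundaries between groups count as substitutions (*transitions*). Each
eligible trajectory is featurised through a descriptor scale (one point per
group, positioned at the group's first-node distance from the root), a
distance-weighted linear regression is fitted, and the line is extrapolated
one mean inter-node step beyond the target to propose the successor residue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression

from .aaindex import AAIndexScale, AAIndexTable, nearest_residue
from .phylo import MainPath, mean_step

logger = logging.getLogger(__name__)

#: residues with fewer than this many group transitions carry too little
#: signal for a trend and are excluded (boundary inclusive: exactly 3 passes)
MIN_TRANSITIONS = 3

GAP = "-"


@dataclass(frozen=True)
class Trajectory:
    """Residues of one alignment column along the main path.

    ``residues``/``positions`` are parallel, gap entries already removed
    (gaps carry no descriptor value); ``target_residue`` is the raw column
    character of the target sequence, which may be a gap.
    """

    site: int
    residues: tuple[str, ...]
    positions: tuple[float, ...]
    groups: tuple[tuple[str, int, int], ...]  # (residue, first_index, last_index)
    target_residue: str

    @property
    def n_transitions(self) -> int:
        return max(len(self.groups) - 1, 0)

    @property
    def group_residues(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.groups)


@dataclass(frozen=True)
class FeatureSeries:
    """Descriptor-space representation of a trajectory for one scale.

    One (x, y, w) point per residue group: x is the cumulative distance of the
    group's first node (optionally divided by the transition count so slope
    magnitudes are comparable across sites), y the residue's scale value, w a
    recency weight.
    """

    accession: str
    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    x_divisor: float  # divisor already applied to x (1.0 when unnormalised)

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.weights)):
            raise ValueError("x, y, weights must be parallel")


@dataclass(frozen=True)
class TrendModel:
    """Fitted linear trend for one (site, scale) pair.

    ``predicted_value = slope * (x[-1] + step) + intercept`` in the series'
    (possibly normalised) x coordinates; ``predicted_residue`` is the scale
    inversion of that value.
    """

    site: int
    accession: str
    slope: float
    intercept: float
    step: float
    predicted_value: float
    predicted_residue: str
    current_residue: str

    @property
    def is_self_prediction(self) -> bool:
        return self.predicted_residue == self.current_residue


def build_trajectory(path: MainPath, site: int) -> Trajectory:
    """Read one alignment column root-first and collapse it into groups."""
    if not 0 <= site < path.alignment_length:
        raise IndexError(f"site {site} outside alignment of length {path.alignment_length}")
    column = path.column(site)
    distances = path.cumulative_distance
    residues, positions = zip(
        *[(r, d) for r, d in zip(column, distances) if r != GAP]
    ) if any(r != GAP for r in column) else ((), ())

    groups: list[tuple[str, int, int]] = []
    for i, r in enumerate(residues):
        if groups and groups[-1][0] == r:
            groups[-1] = (r, groups[-1][1], i)
        else:
            groups.append((r, i, i))
    return Trajectory(
        site=site,
        residues=tuple(residues),
        positions=tuple(positions),
        groups=tuple(groups),
        target_residue=column[-1],
    )


def is_eligible(traj: Trajectory, min_transitions: int = MIN_TRANSITIONS) -> bool:
    """A site qualifies for prediction when it substituted at least
    ``min_transitions`` times along the lineage and the target holds a
    residue (not a gap) there."""
    return traj.n_transitions >= min_transitions and traj.target_residue != GAP


def featurize(
    traj: Trajectory,
    scale: AAIndexScale,
    *,
    normalize: bool = True,
    weighting: str = "linear-recency",
) -> FeatureSeries:
    """Map a trajectory into descriptor space for one scale.

    Groups whose residue has no value on the scale (e.g. ``X``) are skipped
    with a warning. With ``normalize`` the x axis is divided by the transition
    count; ``weighting`` is ``"linear-recency"`` (weights rise linearly from 1
    at the root to 2 at the most recent group) or ``"uniform"``.
    """
    xs: list[float] = []
    ys: list[float] = []
    for res, first, _last in traj.groups:
        if res not in scale:
            logger.warning(
                "site %d: residue %r has no value on %s; group skipped",
                traj.site, res, scale.accession,
            )
            continue
        xs.append(traj.positions[first])
        ys.append(scale[res])

    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if weighting == "linear-recency":
        d_max = x.max() if len(x) and x.max() > 0 else 1.0
        w = 1.0 + x / d_max
    elif weighting == "uniform":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    divisor = float(traj.n_transitions) if normalize and traj.n_transitions else 1.0
    return FeatureSeries(
        accession=scale.accession,
        x=x / divisor,
        y=y,
        weights=w,
        x_divisor=divisor,
    )


class DegenerateFitError(ValueError):
    """All x positions identical; no line can be fitted."""


def fit_trend(
    series: FeatureSeries,
    step: float,
    scale: AAIndexScale,
    *,
    site: int,
    current_residue: str,
) -> TrendModel:
    """Weighted least-squares line through the feature series, extrapolated
    one step beyond the most recent group and inverted back to a residue.

    ``step`` is given in raw branch-length units and is rescaled by the same
    divisor applied to the series' x axis.
    """
    if len(series.x) < 2:
        raise DegenerateFitError("need at least two groups with scale values")
    if np.ptp(series.x) == 0:
        raise DegenerateFitError("all group positions identical")
    reg = LinearRegression()
    reg.fit(series.x.reshape(-1, 1), series.y, sample_weight=series.weights)
    slope = float(reg.coef_[0])
    intercept = float(reg.intercept_)
    scaled_step = step / series.x_divisor
    predicted_value = slope * (series.x[-1] + scaled_step) + intercept
    return TrendModel(
        site=site,
        accession=series.accession,
        slope=slope,
        intercept=intercept,
        step=scaled_step,
        predicted_value=float(predicted_value),
        predicted_residue=nearest_residue(predicted_value, scale),
        current_residue=current_residue,
    )


def predict_site(
    path: MainPath,
    site: int,
    table: AAIndexTable,
    *,
    min_transitions: int = MIN_TRANSITIONS,
    normalize: bool = True,
    weighting: str = "linear-recency",
) -> list[TrendModel]:
    """Fit one trend per descriptor scale at a site.

    Ineligible sites yield an empty list; degenerate (site, scale) pairs are
    skipped. Self-predictions (successor equals the target residue) are
    retained here, flagged, and filtered from mutation output downstream.
    """
    traj = build_trajectory(path, site)
    if not is_eligible(traj, min_transitions):
        return []
    step = mean_step(path)
    models: list[TrendModel] = []
    for scale in table:
        series = featurize(traj, scale, normalize=normalize, weighting=weighting)
        try:
            models.append(
                fit_trend(
                    series, step, scale,
                    site=site, current_residue=traj.target_residue,
                )
            )
        except DegenerateFitError:
            logger.debug("site %d / %s: degenerate fit skipped", site, scale.accession)
    return models


def target_position(path: MainPath, site: int) -> int | None:
    """1-based position of an alignment column on the ungapped target
    sequence, or None when the target has a gap there."""
    target = path.aligned_sequences[-1]
    if target[site] == GAP:
        return None
    return sum(1 for c in target[: site + 1] if c != GAP)
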