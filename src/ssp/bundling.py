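"""Three-tier consolidation of per-scale predictions.

Different descriptor scales often propose substitutions at the same site.
Predictions are bundled into tiers by agreement level:

* **MAP** (mutation-agreeing): two or more scales propose the *same*
  substitution — consolidated into one prediction, the strongest tier;
* **SAP** (site-agreeing): several scales target the same site but disagree
  on the residue — each residue reported, tagged with the shared site;
* **Prediction**: a single scale, a single substitution.

A substitution supported by multiple scales at a contested site is still a
MAP: mutation-level agreement outranks the site-level conflict, and the
other residues at that site remain SAPs.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum

from .scoring import RankedPrediction, TrajectoryScore


class Tier(str, Enum):
    MAP = "MAP"
    SAP = "SAP"
    PREDICTION = "Prediction"


@dataclass(frozen=True)
class BundledPrediction:
    """One substitution with its agreement tier and supporting scales."""

    tier: Tier
    site: int
    wild_type: str
    predicted_residue: str
    supporting_accessions: tuple[str, ...]
    supporting_categories: tuple[str, ...]
    score: TrajectoryScore  # means over the supporting predictions
    n_trees_supporting: int
    site_group: int  # shared id linking SAP members of one site

    @property
    def mutation(self) -> str:
        return f"{self.wild_type}{self.site}{self.predicted_residue}"


def support_count(bundled: BundledPrediction) -> int:
    """Number of distinct scales behind the substitution (MAP requires >= 2)."""
    return len(set(bundled.supporting_accessions))


def bundle(ranked: list[RankedPrediction]) -> list[BundledPrediction]:
    """Collapse tree-aggregated predictions into the three agreement tiers.

    Input predictions sharing (site, wild type, residue) merge into one
    bundle whose supports are the union of scales and whose scores are
    averaged. Every input contributes to exactly one output bundle.
    """
    by_mutation: dict[tuple, list[RankedPrediction]] = defaultdict(list)
    for p in ranked:
        by_mutation[(p.site, p.wild_type, p.predicted_residue)].append(p)

    residues_per_site: dict[int, set[str]] = defaultdict(set)
    for site, _wt, res in by_mutation:
        residues_per_site[site].add(res)

    out: list[BundledPrediction] = []
    for (site, wt, res), group in sorted(by_mutation.items()):
        accessions = tuple(sorted({p.accession for p in group}))
        categories = tuple(sorted({p.category for p in group}))
        n = len(group)
        score = TrajectoryScore(
            sequentiality=sum(p.score.sequentiality for p in group) / n,
            fluctuation=sum(p.score.fluctuation for p in group) / n,
            break_trend=sum(p.score.break_trend for p in group) / n,
        )
        if len(accessions) >= 2:
            tier = Tier.MAP
        elif len(residues_per_site[site]) >= 2:
            tier = Tier.SAP
        else:
            tier = Tier.PREDICTION
        out.append(
            BundledPrediction(
                tier=tier,
                site=site,
                wild_type=wt,
                predicted_residue=res,
                supporting_accessions=accessions,
                supporting_categories=categories,
                score=score,
                n_trees_supporting=max(p.n_trees_supporting for p in group),
                site_group=site,
            )
        )

    tier_order = {Tier.MAP: 0, Tier.SAP: 1, Tier.PREDICTION: 2}
    out.sort(
        key=lambda b: (
            tier_order[b.tier],
            -support_count(b),
            -b.score.sequentiality,
            b.site,
            b.predicted_residue,
        )
    )
    return out


_MUTATION_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


def to_mutation_notation(bundled: BundledPrediction, target_sequence: str | None = None) -> str:
    """Render a bundle as standard mutation notation, e.g. ``E3K``.

    When the ungapped target sequence is given, the wild type is checked
    against it (1-based) as a guard against coordinate bugs.
    """
    if target_sequence is not None:
        if not 1 <= bundled.site <= len(target_sequence):
            raise ValueError(f"site {bundled.site} outside target of length {len(target_sequence)}")
        actual = target_sequence[bundled.site - 1]
        if actual != bundled.wild_type:
            raise ValueError(
                f"wild type mismatch at site {bundled.site}: "
                f"prediction says {bundled.wild_type!r}, target has {actual!r}"
            )
    return bundled.mutation


def parse_mutation(notation: str) -> tuple[str, int, str]:
    """Parse ``"E3K"`` into ``("E", 3, "K")``."""
    m = _MUTATION_RE.match(notation.strip())
    if not m:
        raise ValueError(f"malformed mutation notation {notation!r}")
    return m.group(1), int(m.group(2)), m.group(3)
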