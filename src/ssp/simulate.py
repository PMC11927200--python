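"""Synthetic evolutionary histories with planted physicochemical trends.

Generates fully self-contained toy inputs for the predictor: a rooted tree
whose root-to-target backbone carries ancestor sequences in which chosen
alignment columns follow a planted monotone trend on a chosen descriptor
scale (optionally blurred with Gaussian noise in scale units), plus matching
truth tables and mutational-enrichment tables for end-to-end validation.

The generator emulates the *shape* of real ancestral-reconstruction output —
a labelled chain of ancestors with branch lengths and residue substitutions —
not its substitution process: there is no rate matrix, no site heterogeneity,
and background columns are conserved or i.i.d. noise. Recovery of planted
trends therefore demonstrates correctness of the trend machinery, not
performance on real proteins.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .aaindex import AAIndexTable, load_default_indices
from .phylo import SequenceRecord


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted trajectory.

    ``direction`` +1 plants ascending descriptor values root->target, -1
    descending; ``noise_sd`` is Gaussian noise in the scale's native units
    applied to the ideal trend values before residue selection.
    """

    site: int
    accession: str
    direction: int = +1
    n_transitions: int = 3
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.n_transitions < 1:
            raise ValueError("need at least one transition")


def _plant_residues(
    spec: PlantSpec, table: AAIndexTable, rng: random.Random
) -> list[str]:
    """Choose ``n_transitions + 1`` residues whose scale values follow the
    planted direction (strictly, when noiseless)."""
    scale = table[spec.accession]
    ordered = sorted(scale.values, key=lambda a: (scale.values[a], a))
    if spec.direction < 0:
        ordered = ordered[::-1]
    lo, hi = scale.values[ordered[0]], scale.values[ordered[-1]]
    n_groups = spec.n_transitions + 1

    chosen: list[str] = []
    for k in range(n_groups):
        ideal = lo + (hi - lo) * (k + 0.5) / n_groups
        if spec.noise_sd:
            ideal += rng.gauss(0.0, spec.noise_sd)
        if spec.noise_sd:
            candidates = [a for a in ordered if not chosen or a != chosen[-1]]
        else:
            # noiseless: force strict monotonicity in the planted direction
            candidates = [
                a
                for a in ordered
                if not chosen
                or spec.direction * (scale.values[a] - scale.values[chosen[-1]]) > 0
            ]
        if not candidates:
            raise ValueError(
                f"site {spec.site}: no residue chain realises "
                f"{spec.n_transitions} transitions on {spec.accession}"
            )
        chosen.append(min(candidates, key=lambda a: (abs(scale.values[a] - ideal), a)))
    return chosen


def _group_sizes(n_nodes: int, n_groups: int, rng: random.Random) -> list[int]:
    if n_nodes < n_groups:
        raise ValueError(f"path of {n_nodes} nodes cannot host {n_groups} groups")
    sizes = [1] * n_groups
    for _ in range(n_nodes - n_groups):
        sizes[rng.randrange(n_groups)] += 1
    return sizes


def make_history(
    specs: list[PlantSpec],
    n_sites: int,
    seed: int,
    *,
    path_length: int = 10,
    background: str = "constant",
    table: AAIndexTable | None = None,
    target_id: str = "target",
) -> tuple[str, list[SequenceRecord], list[dict]]:
    """Generate one root->target history with planted trends.

    Returns a Newick string (a backbone chain of labelled ancestors, each
    with a decoy side leaf so the tree is properly bifurcating), the FASTA
    records for every node, and a truth table listing, per planted site, the
    residue chain and expected trend direction.

    ``path_length`` counts the nodes on the root->target chain; branch
    lengths are drawn uniformly from 0.05–0.15 substitutions/site, the range
    typical of the inter-ancestor distances the predictor consumes.
    """
    if len({s.site for s in specs}) != len(specs):
        raise ValueError("planted sites must be distinct")
    for s in specs:
        if not 0 <= s.site < n_sites:
            raise ValueError(f"planted site {s.site} outside 0..{n_sites - 1}")
    if table is None:
        table = load_default_indices()
    rng = random.Random(seed)

    columns: dict[int, list[str]] = {}
    truth: list[dict] = []
    for spec in sorted(specs, key=lambda s: s.site):
        residues = _plant_residues(spec, table, rng)
        sizes = _group_sizes(path_length, len(residues), rng)
        col = [r for r, size in zip(residues, sizes) for _ in range(size)]
        columns[spec.site] = col
        truth.append(
            {
                "site": spec.site,
                "accession": spec.accession,
                "direction": spec.direction,
                "n_transitions": spec.n_transitions,
                "residues": residues,
            }
        )

    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for site in range(n_sites):
        if site in columns:
            continue
        if background == "constant":
            columns[site] = [rng.choice(alphabet)] * path_length
        elif background == "random":
            columns[site] = [rng.choice(alphabet) for _ in range(path_length)]
        else:
            raise ValueError(f"unknown background mode {background!r}")

    node_ids = [f"N{i}" for i in range(path_length - 1)] + [target_id]
    records = [
        SequenceRecord(
            node_ids[k], "".join(columns[s][k] for s in range(n_sites))
        )
        for k in range(path_length)
    ]
    edges = [round(rng.uniform(0.05, 0.15), 6) for _ in range(path_length - 1)]

    # decoy side leaves make every internal node bifurcating
    decoys = []
    for i in range(path_length - 1):
        decoy_id = f"D{i}"
        decoys.append(
            SequenceRecord(
                decoy_id, "".join(rng.choice(alphabet) for _ in range(n_sites))
            )
        )
    newick = f"{target_id}:{edges[-1]}"
    for i in range(path_length - 2, -1, -1):
        decoy_len = round(rng.uniform(0.05, 0.15), 6)
        inner = f"({newick},D{i}:{decoy_len})N{i}"
        newick = f"{inner}:{edges[i - 1]}" if i > 0 else f"{inner};"
    return newick, records + decoys, truth


DEFAULT_CONDITIONS = tuple(
    f"{ab}_{conc}"
    for ab in ("kanamycin", "neomycin", "paromomycin", "ribostamycin", "butirosin", "gentamicinB")
    for conc in ("1x", "2x", "4x", "8x")
)


def make_enrichment_table(
    predicted_mutations: list[str],
    background_mutations: list[str],
    seed: int,
    *,
    baseline: float = 0.8,
    boost: float = 0.6,
    noise_sd: float = 0.0,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
) -> list[tuple[str, str, float]]:
    """Synthetic deep-mutational-scanning enrichment rows.

    Emulates a site-saturation selection experiment read out across several
    antibiotic/concentration conditions: background mutations centre on
    ``baseline`` (< 1, mildly deleterious on average), designated predicted
    mutations on ``baseline + boost``. ``noise_sd`` is the sigma of
    multiplicative lognormal noise; zero gives exact means.
    """
    if baseline <= 0 or boost <= 0:
        raise ValueError("baseline and boost must be positive")
    rng = random.Random(seed)
    rows: list[tuple[str, str, float]] = []
    for muts, mean in ((background_mutations, baseline), (predicted_mutations, baseline + boost)):
        for mut in muts:
            for cond in conditions:
                value = mean
                if noise_sd:
                    value *= math.exp(rng.gauss(0.0, noise_sd))
                rows.append((mut, cond, value))
    return rows
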