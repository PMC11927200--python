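"""End-to-end orchestration: trees in, bundled mutation report out.

For every (tree, node-sequence FASTA) pair the main path is extracted, every
eligible alignment column is fitted per descriptor scale, predictions are
scored and expressed in 1-based ungapped target coordinates, merged across
trees, and bundled into agreement tiers. All randomness is seeded and the
configuration is echoed (with a hash) into every output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aaindex import AAIndexTable, load_default_indices
from .bundling import BundledPrediction, bundle, support_count
from .phylo import extract_main_path, read_fasta, read_newick
from .scoring import (
    RankedPrediction,
    SitePrediction,
    TrajectoryScore,
    aggregate_across_trees,
    break_trend,
    fluctuation,
    sequentiality,
)
from .trajectory import (
    MIN_TRANSITIONS,
    build_trajectory,
    predict_site,
    target_position,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one prediction run; defaults are the reference settings."""

    tree_paths: tuple[str, ...] = ()
    alignment_paths: tuple[str, ...] = ()
    target_id: str = "target"
    min_transitions: int = MIN_TRANSITIONS
    weighting: str = "linear-recency"  # or "uniform"
    normalize: bool = True
    break_mode: str = "last"  # or "penultimate"
    drop_self_predictions: bool = True
    seed: int = 0
    output_dir: str = "ssp_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def predict_tree(
    tree_id: str,
    path,
    table: AAIndexTable,
    config: RunConfig = RunConfig(),
) -> list[SitePrediction]:
    """All scored per-scale predictions for one tree's main path."""
    predictions: list[SitePrediction] = []
    for site in range(path.alignment_length):
        models = predict_site(
            path,
            site,
            table,
            min_transitions=config.min_transitions,
            normalize=config.normalize,
            weighting=config.weighting,
        )
        if not models:
            continue
        pos = target_position(path, site)
        if pos is None:
            continue
        traj = build_trajectory(path, site)
        for model in models:
            if config.drop_self_predictions and model.is_self_prediction:
                logger.debug(
                    "%s site %d/%s: self-prediction %s dropped",
                    tree_id, pos, model.accession, model.predicted_residue,
                )
                continue
            scale = table[model.accession]
            score = TrajectoryScore(
                sequentiality=sequentiality(traj, scale, model.slope),
                fluctuation=fluctuation(traj),
                break_trend=float(
                    break_trend(traj, scale, model.slope, mode=config.break_mode)
                ),
            )
            predictions.append(
                SitePrediction(
                    tree_id=tree_id,
                    site=pos,
                    wild_type=model.current_residue,
                    predicted_residue=model.predicted_residue,
                    accession=model.accession,
                    category=scale.category,
                    slope=model.slope,
                    score=score,
                )
            )
    return predictions


def run_predict(config: RunConfig) -> tuple[list[RankedPrediction], list[BundledPrediction]]:
    """Run the full pipeline over every configured tree and write reports.

    Returns the cross-tree aggregated predictions and their bundles; writes
    ``predictions.tsv``, ``bundled.tsv`` and ``report.json`` (full score
    provenance plus the echoed configuration) under ``config.output_dir``.
    """
    if not config.tree_paths:
        raise ValueError("no trees configured")
    if len(config.tree_paths) != len(config.alignment_paths):
        raise ValueError("need one alignment FASTA per tree")
    table = load_default_indices()

    per_tree: list[SitePrediction] = []
    for tree_path, fasta_path in zip(config.tree_paths, config.alignment_paths):
        tree = read_newick(tree_path)
        records = {r.id: r for r in read_fasta(fasta_path)}
        path = extract_main_path(tree, records, config.target_id)
        per_tree.extend(predict_tree(Path(tree_path).stem, path, table, config))

    ranked = aggregate_across_trees(per_tree)
    bundled = bundle(ranked)
    write_reports(ranked, bundled, config)
    return ranked, bundled


def write_reports(
    ranked: list[RankedPrediction],
    bundled: list[BundledPrediction],
    config: RunConfig,
) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    pd.DataFrame(
        [
            {
                "site": p.site,
                "wild_type": p.wild_type,
                "predicted": p.predicted_residue,
                "accession": p.accession,
                "category": p.category,
                "sequentiality": p.score.sequentiality,
                "fluctuation": p.score.fluctuation,
                "break_trend": p.score.break_trend,
                "n_trees": p.n_trees_supporting,
            }
            for p in ranked
        ]
    ).to_csv(out / "predictions.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {
                "mutation": b.mutation,
                "tier": b.tier.value,
                "supports": ";".join(b.supporting_categories),
                "accessions": ";".join(b.supporting_accessions),
                "n_supporting_indices": support_count(b),
                "sequentiality": b.score.sequentiality,
                "fluctuation": b.score.fluctuation,
                "break_fraction": b.score.break_trend,
                "n_trees": b.n_trees_supporting,
            }
            for b in bundled
        ]
    ).to_csv(out / "bundled.tsv", sep="\t", index=False)

    report = {
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "n_ranked": len(ranked),
        "n_bundled": len(bundled),
        "bundles": [
            {
                "mutation": b.mutation,
                "tier": b.tier.value,
                "site_group": b.site_group,
                "accessions": list(b.supporting_accessions),
                "categories": list(b.supporting_categories),
                "score": dataclasses.asdict(b.score),
                "n_trees": b.n_trees_supporting,
            }
            for b in bundled
        ],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
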