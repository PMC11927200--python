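"""Homolog filtering and sequence-file construction.

Dataset curation keeps homologs in the informative similarity band — close
enough to align reliably, distant enough to carry evolutionary signal
(30–90% identity to the target, 80–120% of its length) — and then splits the
clustered dataset into diverse 150-sequence files, one phylogenetic tree per
file. Search (BLAST), clustering (USEARCH/SigClust), alignment and tree
building run externally; this module consumes their tabular outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .phylo import SequenceRecord


@dataclass(frozen=True)
class HomologFilterConfig:
    min_identity: float = 0.30
    max_identity: float = 0.90
    min_length_frac: float = 0.80
    max_length_frac: float = 1.20
    cluster_identity: float = 0.90
    seqs_per_file: int = 150
    n_clusters: int = 150
    seed: int = 0
    identity_denominator: str = "alignment"  # or "shorter"

    def __post_init__(self) -> None:
        if not 0 < self.min_identity < self.max_identity <= 1:
            raise ValueError("identity bounds must satisfy 0 < min < max <= 1")
        if not 0 < self.min_length_frac < self.max_length_frac:
            raise ValueError("length fractions must be positive with min < max")


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    alignment: tuple[str, str] | None = None,
    denominator: str = "alignment",
) -> float:
    """Fraction of identical positions between two sequences.

    A global (Needleman–Wunsch, BLOSUM62) alignment is computed unless a
    pre-aligned pair of equal-length gapped strings is supplied. The
    denominator is the full alignment length (gap columns included) or, with
    ``denominator="shorter"``, the shorter ungapped sequence length.
    """
    ua, ub = a.ungapped, b.ungapped
    if not ua or not ub:
        raise ValueError("empty sequence")
    if alignment is None:
        aln = _global_aligner().align(ua, ub)[0]
        row_a, row_b = str(aln[0]), str(aln[1])
    else:
        row_a, row_b = alignment
        if len(row_a) != len(row_b):
            raise ValueError("pre-aligned sequences differ in length")
    matches = sum(x == y and x != "-" for x, y in zip(row_a, row_b))
    if denominator == "alignment":
        denom = len(row_a)
    elif denominator == "shorter":
        denom = min(len(ua), len(ub))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return matches / denom


@dataclass(frozen=True)
class FilterDecision:
    record: SequenceRecord
    retained: bool
    identity: float
    length_frac: float
    reason: str = ""


def filter_homologs(
    target: SequenceRecord,
    candidates: list[SequenceRecord],
    cfg: HomologFilterConfig = HomologFilterConfig(),
) -> tuple[list[SequenceRecord], list[FilterDecision]]:
    """Apply the identity and length windows (boundaries inclusive).

    Returns the retained records plus a per-candidate decision trail with
    the computed identity, length fraction and rejection reason.
    """
    retained: list[SequenceRecord] = []
    decisions: list[FilterDecision] = []
    t_len = len(target.ungapped)
    for cand in candidates:
        ident = pairwise_identity(target, cand, denominator=cfg.identity_denominator)
        frac = len(cand.ungapped) / t_len
        reasons = []
        if ident < cfg.min_identity:
            reasons.append(f"identity {ident:.3f} below {cfg.min_identity}")
        if ident > cfg.max_identity:
            reasons.append(f"identity {ident:.3f} above {cfg.max_identity}")
        if frac < cfg.min_length_frac:
            reasons.append(f"length fraction {frac:.3f} below {cfg.min_length_frac}")
        if frac > cfg.max_length_frac:
            reasons.append(f"length fraction {frac:.3f} above {cfg.max_length_frac}")
        ok = not reasons
        decisions.append(
            FilterDecision(cand, ok, ident, frac, "; ".join(reasons))
        )
        if ok:
            retained.append(cand)
    return retained, decisions


@dataclass(frozen=True)
class ClusterAssignment:
    """Map of sequence id -> cluster id (each id in exactly one cluster)."""

    assignments: dict[str, str]

    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for seq_id in sorted(self.assignments):
            out.setdefault(self.assignments[seq_id], []).append(seq_id)
        return out


def build_sequence_files(
    clusters: ClusterAssignment,
    target_id: str,
    cfg: HomologFilterConfig = HomologFilterConfig(),
    n_files: int | None = None,
) -> list[list[str]]:
    """Partition clustered sequences into diverse per-tree files.

    Each file draws one sequence from every cluster; within a cluster,
    sequences are used without replacement across files until the cluster is
    exhausted, then its pool resets — so small clusters recycle while large
    ones spread their members over the files. The target sequence is present
    in every file (added alongside its cluster's pick when not itself
    picked). By default enough files are built to exhaust the largest
    cluster, so every sequence appears at least once. Deterministic under
    ``cfg.seed``.
    """
    if target_id not in clusters.assignments:
        raise ValueError(f"target {target_id!r} has no cluster assignment")
    by_cluster = clusters.clusters()
    if not by_cluster:
        raise ValueError("no clusters given")
    if n_files is None:
        n_files = max(len(members) for members in by_cluster.values())

    rng = random.Random(cfg.seed)
    pools: dict[str, list[str]] = {cid: [] for cid in by_cluster}
    files: list[list[str]] = []
    for _ in range(n_files):
        picks: list[str] = []
        for cid in sorted(by_cluster):
            if not pools[cid]:
                pools[cid] = list(by_cluster[cid])
                rng.shuffle(pools[cid])
            picks.append(pools[cid].pop())
        if target_id not in picks:
            picks.append(target_id)
        files.append(picks)
    return files
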