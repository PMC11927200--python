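"""Sequence and tree IO plus main-path extraction.

The predictor consumes rooted Newick trees whose internal nodes are labelled
(as ancestral-reconstruction tools emit them) and a FASTA of aligned sequences
covering every node on the root-to-target path. This module reads those
formats, sanitizes headers for downstream tools, and extracts the ordered
root-to-target "main path" with cumulative evolutionary distances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

SEQUENCE_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass(frozen=True)
class SequenceRecord:
    """A named, possibly gapped amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty sequence id")
        bad = set(self.sequence.upper()) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid sequence characters {sorted(bad)}")

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass(frozen=True)
class MainPath:
    """Ordered chain of nodes from the root to the target leaf.

    ``cumulative_distance[i]`` is the patristic distance from the root to
    ``nodes[i]``; ``aligned_sequences`` are equal-length gapped sequences
    parallel to ``nodes``, the last being the target.
    """

    nodes: tuple[str, ...]
    edge_lengths: tuple[float, ...]
    aligned_sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.edge_lengths) != len(self.nodes) - 1:
            raise ValueError("edge_lengths must have one entry per edge")
        if len(self.aligned_sequences) != len(self.nodes):
            raise ValueError("one aligned sequence required per node")
        lengths = {len(s) for s in self.aligned_sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        if any(e < 0 for e in self.edge_lengths):
            raise ValueError("negative branch length on main path")

    @property
    def cumulative_distance(self) -> tuple[float, ...]:
        out = [0.0]
        for e in self.edge_lengths:
            out.append(out[-1] + e)
        return tuple(out)

    @property
    def alignment_length(self) -> int:
        return len(self.aligned_sequences[0])

    @property
    def target_id(self) -> str:
        return self.nodes[-1]

    def column(self, site: int) -> tuple[str, ...]:
        """Residues (root-first) at a 0-based alignment column."""
        return tuple(s[site] for s in self.aligned_sequences)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


_SAFE = re.compile(r"[^A-Za-z0-9_.-]")


def sanitize_headers(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Clean ids so external tree/MSA tools cannot choke on them.

    Every character outside ``[A-Za-z0-9_.-]`` becomes ``_``; ids starting
    with a digit get an ``s_`` prefix; collisions after cleaning are resolved
    with numeric suffixes. Returns the renamed records and the bijective
    old-id -> new-id map.
    """
    rename: dict[str, str] = {}
    used: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in records:
        clean = _SAFE.sub("_", rec.id)
        if clean[0].isdigit():
            clean = "s_" + clean
        candidate, k = clean, 0
        while candidate in used:
            k += 1
            candidate = f"{clean}_{k}"
        used.add(candidate)
        rename[rec.id] = candidate
        out.append(SequenceRecord(candidate, rec.sequence))
    return out, rename


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with labelled internal nodes.

    Raises ``ValueError`` when an internal node lacks a label or a non-root
    edge lacks a branch length, since the main path needs both.
    """
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if _node_label(node) is None:
            raise ValueError(
                "unlabelled internal node: relabel ancestors before running "
                "(ancestral-reconstruction tools emit node labels)"
            )
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError(f"missing branch length above node {_node_label(node)}")
    return tree


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or None


def extract_main_path(
    tree: dendropy.Tree,
    node_sequences: dict[str, SequenceRecord],
    target_id: str,
) -> MainPath:
    """Extract the root-to-target chain with aligned node sequences.

    Every node on the path must have an entry in ``node_sequences`` and all
    those sequences must share one gapped length (a pre-aligned input is part
    of the contract; no aligner is invoked here).
    """
    target = None
    for leaf in tree.leaf_node_iter():
        if _node_label(leaf) == target_id:
            target = leaf
            break
    if target is None:
        raise ValueError(f"target {target_id!r} is not a leaf of the tree")

    chain: list[dendropy.Node] = []
    node = target
    while node is not None:
        chain.append(node)
        node = node.parent_node
    chain.reverse()

    labels = [_node_label(n) for n in chain]
    missing = [lab for lab in labels if lab not in node_sequences]
    if missing:
        raise ValueError(f"no sequence for main-path node(s): {missing}")
    return MainPath(
        nodes=tuple(labels),
        edge_lengths=tuple(float(n.edge.length) for n in chain[1:]),
        aligned_sequences=tuple(node_sequences[lab].sequence for lab in labels),
    )


def mean_step(path: MainPath) -> float:
    """Average branch length between consecutive nodes on the main path.

    This is the extrapolation step: the predicted successor sits one mean
    inter-node distance beyond the target.
    """
    if len(path.nodes) < 2:
        raise ValueError("main path has a single node; no edges to average")
    return sum(path.edge_lengths) / len(path.edge_lengths)
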