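"""Validation statistics for prediction sets.

The central statistic is the AAC — the arithmetic mean of mutational
enrichment values across every assay condition (antibiotics and their
concentrations, in the reference use case). Enrichment is ~1 for the wild
type, above 1 for fitness-enhancing variants; the AAC of the complete
site-saturation table is the random-mutagenesis proxy, and the AAC restricted
to a prediction set measures how much better than random that set selects
enriched variants.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .bundling import parse_mutation


def read_enrichment(
    path: str | Path,
    *,
    mutation_col: str = "mutation",
    condition_col: str = "condition",
    value_col: str = "enrichment",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read an enrichment table (mutation x condition -> value) from TSV.

    Column names are declarative so externally supplied tables with other
    layouts map onto the canonical three columns.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (mutation_col, condition_col, value_col):
        if col not in df.columns:
            raise ValueError(f"enrichment table lacks column {col!r}; has {list(df.columns)}")
    out = df[[mutation_col, condition_col, value_col]].copy()
    out.columns = ["mutation", "condition", "enrichment"]
    if not out["enrichment"].map(lambda v: pd.notna(v) and abs(v) != float("inf")).all():
        raise ValueError("non-finite enrichment value in table")
    return out


def compute_aac(table: pd.DataFrame, subset: set[str] | None = None) -> float:
    """Average enrichment across all rows, optionally restricted to a
    mutation subset. Raises on an empty selection."""
    if subset is not None:
        missing = subset - set(table["mutation"])
        if missing:
            raise ValueError(f"subset mutations absent from table: {sorted(missing)[:5]}")
        table = table[table["mutation"].isin(subset)]
    if len(table) == 0:
        raise ValueError("empty enrichment selection")
    return float(table["enrichment"].mean())


def overlap_report(
    predictions: set[str] | list[str],
    experimental_mutations: set[str] | list[str],
    total_space_size: int | None = None,
) -> dict[str, int]:
    """Set-arithmetic summary of predicted vs experimentally covered
    mutations, for Venn-style reporting. Malformed notations are dropped
    with a warning rather than aborting the report."""
    import logging

    log = logging.getLogger(__name__)

    def clean(muts) -> set[str]:
        out = set()
        for m in muts:
            try:
                parse_mutation(m)
                out.add(m)
            except ValueError:
                log.warning("skipping malformed mutation notation %r", m)
        return out

    pred, exp = clean(predictions), clean(experimental_mutations)
    report = {
        "predicted": len(pred),
        "experimental": len(exp),
        "overlap": len(pred & exp),
    }
    if total_space_size is not None:
        report["total"] = total_space_size
    return report
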