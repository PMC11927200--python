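"""Curated AAindex physicochemical scales.

Nine amino-acid descriptor scales are embedded with the package, chosen to
cover complementary physicochemical axes (size, melting point, hydrophobicity,
flexibility, transfer energy, electrical effect, polarity, isoelectric point)
while keeping mutual redundancy low. Each scale maps the 20 standard residues
to a real value in the scale's native units; values are stored raw, exactly as
published in the AAindex database, because every regression downstream operates
within a single scale and units never mix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: accession -> (property name, category) for the embedded descriptor set.
#: The two size-like scales (molecular weight, residue volume) share the
#: Size category; every other scale carries its own.
SCALE_METADATA: dict[str, tuple[str, str]] = {
    "FASG760101": ("Molecular weight", "Size"),
    "FASG760102": ("Melting point", "MeltingPoint"),
    "GOLD730102": ("Residue volume", "Size"),
    "WOLR790101": ("Hydrophobicity index", "Hydrophobicity"),
    "BHAR880101": ("Average flexibility indices", "Flexibility"),
    "BULH740101": ("Transfer free energy to surface", "TransferEnergy"),
    "FAUJ880108": ("Localized electrical effect", "ElectricEffect"),
    "ZIMJ680103": ("Polarity", "Polarity"),
    "ZIMJ680104": ("Isoelectric point", "IsoelectricPoint"),
}

DEFAULT_ACCESSIONS = tuple(SCALE_METADATA)


class AAIndexError(ValueError):
    """Raised when embedded scale data fail validation."""


@dataclass(frozen=True)
class AAIndexScale:
    """One amino-acid descriptor scale.

    Parameters
    ----------
    accession
        AAindex database accession, e.g. ``"FASG760101"``.
    property_name
        Human-readable property description.
    category
        Coarse physicochemical category used when bundling predictions.
    values
        Mapping of the 20 standard one-letter residue codes to scale values
        in the scale's native units.
    """

    accession: str
    property_name: str
    category: str
    values: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise AAIndexError(
                f"{self.accession}: scale must cover exactly the 20 standard "
                f"residues (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        if any(v is None or not np.isfinite(v) for v in self.values.values()):
            raise AAIndexError(f"{self.accession}: non-finite scale value")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.values

    def vector(self, order: str = AMINO_ACIDS) -> np.ndarray:
        """Scale values as an array in the given residue order."""
        return np.array([self.values[a] for a in order], dtype=float)


@dataclass(frozen=True)
class AAIndexTable:
    """Ordered collection of descriptor scales keyed by accession."""

    scales: tuple[AAIndexScale, ...]

    def __post_init__(self) -> None:
        accs = [s.accession for s in self.scales]
        if len(set(accs)) != len(accs):
            raise AAIndexError("duplicate accession in table")

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    def __getitem__(self, accession: str) -> AAIndexScale:
        for s in self.scales:
            if s.accession == accession:
                return s
        raise KeyError(accession)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(s.accession for s in self.scales)


def load_default_indices() -> AAIndexTable:
    """Load the nine embedded descriptor scales.

    Returns a validated :class:`AAIndexTable`; raises :class:`AAIndexError`
    if the embedded data are corrupt (wrong accessions, missing residues).
    """
    raw: dict[str, dict[str, float]] = {}
    with resources.files("ssp.data").joinpath("aaindex9.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw.setdefault(row["accession"], {})[row["residue"]] = float(row["value"])
    if set(raw) != set(DEFAULT_ACCESSIONS):
        raise AAIndexError(
            f"embedded data carry accessions {sorted(raw)}, "
            f"expected {sorted(DEFAULT_ACCESSIONS)}"
        )
    scales = tuple(
        AAIndexScale(acc, *SCALE_METADATA[acc], values=raw[acc])
        for acc in DEFAULT_ACCESSIONS
    )
    return AAIndexTable(scales)


def descriptor_correlation(table: AAIndexTable) -> np.ndarray:
    """Pairwise Pearson correlation of scales over their 20 residue values.

    Returns a symmetric ``len(table) x len(table)`` matrix with unit diagonal,
    ordered as ``table.accessions``. Used as a redundancy diagnostic for the
    descriptor set.
    """
    mat = np.vstack([s.vector() for s in table])
    corr = np.corrcoef(mat)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_residue(
    value: float, scale: AAIndexScale, exclude: frozenset[str] | set[str] = frozenset()
) -> str:
    """Invert a scale: the residue whose value is closest to ``value``.

    Ties are broken alphabetically on the one-letter code so the inversion is
    deterministic. ``exclude`` removes residues from consideration (e.g. to
    forbid predicting the wild type back).
    """
    candidates = [a for a in sorted(scale.values) if a not in exclude]
    if not candidates:
        raise ValueError("exclude set covers all residues")
    return min(candidates, key=lambda a: (abs(scale.values[a] - value), a))
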