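"""Alignment-level summary statistics for barcode datasets.

Covers the descriptive statistics a barcoding study reports before any
identification is attempted: base composition, variable and
parsimony-informative sites, per-species haplotype counts and polymorphic
(segregating) sites. The outgroup is excluded from all of these by
default, since the statistics describe the focal taxa only.

Gap/ambiguity policy: haplotype collapsing and polymorphic-site counting
first drop every column that contains a gap or an ambiguity code anywhere
in the analyzed record set, then compare complete columns only. Variable-
site classification instead ignores non-ACGT states column-wise (an
ambiguity code neither creates nor suppresses variability).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .seqio import ACGT, BarcodeAlignment, SequenceRecord


@dataclass(frozen=True)
class SiteClassification:
    n_variable: int
    n_parsimony_informative: int
    variable_positions: tuple[int, ...]
    has_indels: bool

    def __post_init__(self) -> None:
        assert 0 <= self.n_parsimony_informative <= self.n_variable


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotype and polymorphism summary for a single species."""

    species: str
    n_sequences: int
    n_haplotypes: int
    n_polymorphic_sites: int | None  # None: not applicable (singleton species)
    assignment: dict[str, int]  # record_id -> haplotype index (0-based)

    @property
    def is_singleton(self) -> bool:
        return self.n_sequences == 1


def _included_records(
    alignment: BarcodeAlignment, exclude_species: str | None
) -> list[SequenceRecord]:
    exclude = exclude_species if exclude_species is not None else alignment.outgroup_species
    records = [r for r in alignment.records if r.species != exclude]
    if not records:
        raise ValueError("no records left after excluding outgroup")
    return records


def base_composition(
    alignment: BarcodeAlignment, exclude_species: str | None = None
) -> dict[str, float]:
    """Pooled base composition over unambiguous A/C/G/T characters.

    Returns fractions per base plus ``AT_content`` and ``GC_content`` as
    percentages. Gaps and ambiguity codes are not counted.
    """
    records = _included_records(alignment, exclude_species)
    counts = Counter()
    for r in records:
        counts.update(c for c in r.residues if c in ACGT)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous A/C/G/T characters in alignment")
    frac = {b: counts[b] / total for b in "ACGT"}
    frac["AT_content"] = 100.0 * (frac["A"] + frac["T"])
    frac["GC_content"] = 100.0 * (frac["G"] + frac["C"])
    return frac


def classify_sites(
    alignment: BarcodeAlignment, exclude_species: str | None = None
) -> SiteClassification:
    """Count variable and parsimony-informative columns.

    A column is variable iff at least two distinct unambiguous states
    occur among the included records, and parsimony-informative iff at
    least two distinct states each occur in at least two records.
    """
    records = _included_records(alignment, exclude_species)
    if len(records) < 2:
        raise ValueError("site classification needs at least 2 records")
    variable: list[int] = []
    n_informative = 0
    has_indels = False
    for col in range(alignment.length):
        states = Counter()
        for r in records:
            c = r.residues[col]
            if c == "-":
                has_indels = True
            if c in ACGT:
                states[c] += 1
        if len(states) >= 2:
            variable.append(col)
            if sum(1 for n in states.values() if n >= 2) >= 2:
                n_informative += 1
    return SiteClassification(
        n_variable=len(variable),
        n_parsimony_informative=n_informative,
        variable_positions=tuple(variable),
        has_indels=has_indels,
    )


def _complete_columns(records: list[SequenceRecord]) -> list[int]:
    """Columns where every record has an unambiguous A/C/G/T state."""
    length = len(records[0])
    return [
        col
        for col in range(length)
        if all(r.residues[col] in ACGT for r in records)
    ]


def collapse_haplotypes(records: list[SequenceRecord]) -> HaplotypeTable:
    """Collapse one species' records into haplotypes.

    Two sequences share a haplotype iff they are identical at every column
    retained after dropping gap/ambiguity-containing columns; polymorphic
    sites are retained columns with >=2 states within the species.
    """
    if not records:
        raise ValueError("collapse_haplotypes needs at least one record")
    species = records[0].species
    if any(r.species != species for r in records):
        raise ValueError("collapse_haplotypes: mixed species labels")
    if len({len(r) for r in records}) != 1:
        raise ValueError("collapse_haplotypes: unequal sequence lengths")

    columns = _complete_columns(records)
    keys: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for r in sorted(records, key=lambda r: r.record_id):
        key = "".join(r.residues[c] for c in columns)
        if key not in keys:
            keys[key] = len(keys)
        assignment[r.record_id] = keys[key]

    n_poly = sum(
        1 for c in columns if len({r.residues[c] for r in records}) >= 2
    )
    return HaplotypeTable(
        species=species,
        n_sequences=len(records),
        n_haplotypes=len(keys),
        n_polymorphic_sites=None if len(records) == 1 else n_poly,
        assignment=assignment,
    )


def species_summary_table(
    alignment: BarcodeAlignment, exclude_species: str | None = None
) -> list[HaplotypeTable]:
    """One :class:`HaplotypeTable` per species, ordered by species label.

    Singleton species keep their (trivial) haplotype count but have
    polymorphic sites marked not applicable.
    """
    records = _included_records(alignment, exclude_species)
    by_species: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    return [collapse_haplotypes(by_species[sp]) for sp in sorted(by_species)]


def species_summary_frame(
    alignment: BarcodeAlignment, exclude_species: str | None = None
) -> pd.DataFrame:
    """Tabular report of the per-species summary (one row per species)."""
    rows = []
    for t in species_summary_table(alignment, exclude_species):
        rows.append(
            {
                "species": t.species,
                "n_sequences": t.n_sequences,
                "n_polymorphic_sites": "N/A" if t.is_singleton else t.n_polymorphic_sites,
                "n_haplotypes": t.n_haplotypes,
            }
        )
    return pd.DataFrame(rows)
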