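"""Annotated FASTA input/output for barcode alignments.

Specimen metadata travels in the FASTA header as delimited fields
(``id|species|site|accession`` by default), mirroring the labelling
convention of published barcode reference trees (voucher code, species
name, collection site, accession number).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide codes plus the alignment gap character.
ALLOWED_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous nucleotide states.
ACGT = frozenset("ACGT")


class SeqIOError(ValueError):
    """Raised for malformed alignments, headers, or FASTA files."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned nucleotide sequence plus its specimen metadata.

    The ``species`` label is the identification ground truth used by the
    distance- and tree-based identification stages.
    """

    record_id: str
    species: str
    residues: str
    site: str = ""
    gene: str = "other"
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise SeqIOError("record_id must be non-empty")
        if not self.species:
            raise SeqIOError(f"record {self.record_id!r}: species label required")
        residues = self.residues.upper()
        if not residues:
            raise SeqIOError(f"record {self.record_id!r}: empty sequence")
        for pos, char in enumerate(residues):
            if char not in ALLOWED_CHARS:
                raise SeqIOError(
                    f"record {self.record_id!r}: illegal character {char!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "residues", residues)

    @property
    def has_gaps(self) -> bool:
        return "-" in self.residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class BarcodeAlignment:
    """An equal-length collection of records for one gene, with a species
    partition and an optional outgroup label."""

    records: list[SequenceRecord]
    outgroup_species: str | None = None
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment must contain at least one record")
        self.length = len(self.records[0])
        bad = [r.record_id for r in self.records if len(r) != self.length]
        if bad:
            raise SeqIOError(
                f"unequal sequence lengths: records {bad} differ from "
                f"{self.records[0].record_id!r} (length {self.length})"
            )
        seen: set[str] = set()
        for r in self.records:
            if r.record_id in seen:
                raise SeqIOError(f"duplicate record id {r.record_id!r}")
            seen.add(r.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def species_map(self) -> dict[str, str]:
        """record_id -> species label."""
        return {r.record_id: r.species for r in self.records}

    def species_partition(self, include_outgroup: bool = False) -> dict[str, list[str]]:
        """species -> list of record ids, in record order."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            if not include_outgroup and r.species == self.outgroup_species:
                continue
            out.setdefault(r.species, []).append(r.record_id)
        return out

    def ingroup(self) -> "BarcodeAlignment":
        """Alignment restricted to non-outgroup records."""
        if self.outgroup_species is None:
            return self
        kept = [r for r in self.records if r.species != self.outgroup_species]
        if not kept:
            raise SeqIOError("no ingroup records left after excluding outgroup")
        return BarcodeAlignment(kept, outgroup_species=None)

    def subset(self, ids: list[str]) -> "BarcodeAlignment":
        wanted = set(ids)
        kept = [r for r in self.records if r.record_id in wanted]
        missing = wanted - {r.record_id for r in kept}
        if missing:
            raise SeqIOError(f"unknown record ids: {sorted(missing)}")
        return BarcodeAlignment(kept, outgroup_species=self.outgroup_species)

    @property
    def has_gaps(self) -> bool:
        return any(r.has_gaps for r in self.records)


def parse_specimen_header(
    header: str, delimiter: str = "|", gene: str = "other"
) -> SequenceRecord | tuple[str, str, str, str]:
    """Split a FASTA header into (record_id, species, site, accession).

    Field order is ``id<delim>species<delim>site<delim>accession``; trailing
    fields may be omitted and default to empty. The species field is
    mandatory because downstream identification has no ground truth
    without it.
    """
    if not header:
        raise SeqIOError("empty FASTA header")
    parts = [p.strip() for p in header.split(delimiter)]
    if len(parts) < 2 or not parts[1]:
        raise SeqIOError(
            f"header {header!r}: no species field "
            f"(expected id{delimiter}species[{delimiter}site[{delimiter}accession]])"
        )
    parts += [""] * (4 - len(parts))
    record_id, species, site, accession = parts[:4]
    return record_id, species, site, accession


def format_specimen_header(record: SequenceRecord, delimiter: str = "|") -> str:
    fields = [record.record_id, record.species, record.site, record.accession]
    while len(fields) > 2 and not fields[-1]:
        fields.pop()
    return delimiter.join(fields)


def read_alignment_fasta(
    path: str | os.PathLike,
    delimiter: str = "|",
    gene: str = "other",
    outgroup_species: str | None = None,
) -> BarcodeAlignment:
    """Read an aligned multi-FASTA file into a :class:`BarcodeAlignment`.

    Residues are uppercased; gaps (``-``) are accepted but the caller's
    analysis stage decides its own gap policy. Unequal lengths, duplicate
    ids, or characters outside the IUPAC alphabet raise :class:`SeqIOError`
    naming the offending record.
    """
    entries = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not entries:
        raise SeqIOError(f"no FASTA records found in {path}")
    records = []
    for entry in entries:
        rid, species, site, accession = parse_specimen_header(
            entry.description, delimiter=delimiter
        )
        records.append(
            SequenceRecord(
                record_id=rid,
                species=species,
                site=site,
                gene=gene,
                accession=accession,
                residues=str(entry.seq),
            )
        )
    return BarcodeAlignment(records, outgroup_species=outgroup_species)


def write_alignment_fasta(
    alignment: BarcodeAlignment,
    path: str | os.PathLike,
    delimiter: str = "|",
    line_width: int = 70,
) -> None:
    """Write the alignment back to FASTA, rebuilding delimited headers.

    Record order is preserved, so write followed by read is the identity.
    """
    bio_records = [
        _BioSeqRecord(
            Seq(r.residues),
            id=format_specimen_header(r, delimiter=delimiter),
            description="",
        )
        for r in alignment.records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(bio_records)


def duplicate_record(record: SequenceRecord, suffix: str = "_dup") -> SequenceRecord:
    """Exact copy of a record under a new id (singleton-duplication rule)."""
    return replace(record, record_id=record.record_id + suffix)
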