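"""Screen barcode amplicons for nuclear mitochondrial pseudogenes (NUMTs).

A NUMT is a nuclear copy of a mitochondrial gene. Freed from coding
constraints, it accumulates frame-disrupting indels and premature stop
codons, which betray it once the amplicon is translated with the
invertebrate mitochondrial genetic code (NCBI translation table 5:
ATA=Met, TGA=Trp, AGA/AGG=Ser; stops TAA and TAG only). A functional
mitochondrial protein gene cannot carry internal stops, so their
presence — or a deletion whose length is not a multiple of three —
flags the record as a putative pseudogene.

The reading frame of the amplicon is inferred once per alignment (all
records share primers, hence a frame) as the frame minimizing the total
internal-stop count.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .seqio import ACGT, BarcodeAlignment, SequenceRecord

#: NCBI invertebrate mitochondrial code.
INVERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[5]

STOP_MARK = "*"
UNKNOWN_MARK = "X"


def translate_mito(residues: str, frame: int = 0) -> str:
    """Translate under the invertebrate mitochondrial code.

    Stops appear as ``*``; codons containing gaps or ambiguity codes
    translate to ``X``; a trailing partial codon is dropped.
    """
    if not residues:
        raise ValueError("cannot translate an empty sequence")
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = residues.upper()
    if len(seq) < frame + 3:
        raise ValueError(f"sequence too short to translate in frame {frame}")
    out = []
    for start in range(frame, len(seq) - 2, 3):
        codon = seq[start : start + 3]
        if any(c not in ACGT for c in codon):
            out.append(UNKNOWN_MARK)
        elif codon in INVERTEBRATE_MITO.stop_codons:
            out.append(STOP_MARK)
        else:
            out.append(INVERTEBRATE_MITO.forward_table[codon])
    return "".join(out)


def _internal_stop_positions(protein: str) -> list[int]:
    """Codon indices of stops that are followed by at least one real
    (non-unknown) codon; a stop in the terminal position is not internal."""
    stops = []
    for i, aa in enumerate(protein):
        if aa == STOP_MARK and any(c != UNKNOWN_MARK for c in protein[i + 1 :]):
            stops.append(i)
    return stops


def infer_reading_frame(alignment: BarcodeAlignment) -> int:
    """Frame (0/1/2) minimizing total internal stops across all records,
    ties broken toward the lowest frame."""
    totals = []
    for frame in (0, 1, 2):
        total = 0
        for r in alignment.records:
            degapped = r.residues.replace("-", "")
            if len(degapped) < frame + 3:
                continue
            total += len(_internal_stop_positions(translate_mito(degapped, frame)))
        totals.append(total)
    return min(range(3), key=lambda f: (totals[f], f))


@dataclass(frozen=True)
class NumtReport:
    record_id: str
    frame_used: int
    n_internal_stops: int
    stop_positions: tuple[int, ...]
    gap_lengths: tuple[int, ...]

    @property
    def frame_disrupting_gap(self) -> bool:
        return any(g % 3 != 0 for g in self.gap_lengths)

    @property
    def is_flagged(self) -> bool:
        return self.n_internal_stops > 0 or self.frame_disrupting_gap


def _gap_runs(residues: str) -> tuple[int, ...]:
    runs, current = [], 0
    for c in residues:
        if c == "-":
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return tuple(runs)


def screen_record(record: SequenceRecord, frame: int) -> NumtReport:
    degapped = record.residues.replace("-", "")
    if len(degapped) >= frame + 3:
        stops = _internal_stop_positions(translate_mito(degapped, frame))
    else:
        stops = []
    return NumtReport(
        record_id=record.record_id,
        frame_used=frame,
        n_internal_stops=len(stops),
        stop_positions=tuple(stops),
        gap_lengths=_gap_runs(record.residues),
    )


def screen_numt(
    alignment: BarcodeAlignment, frame: int | None = None
) -> list[NumtReport]:
    """Per-record NUMT reports for a whole alignment.

    Gap runs are measured against the alignment (a deletion shows up as a
    run of ``-``); the degapped sequence is then translated in the shared
    reading frame (inferred when not given). Flagged records are
    reported, never silently removed.
    """
    if frame is None:
        frame = infer_reading_frame(alignment)
    return [screen_record(r, frame) for r in alignment.records]


def flagged_ids(reports: list[NumtReport]) -> list[str]:
    return [r.record_id for r in reports if r.is_flagged]


def drop_flagged(
    alignment: BarcodeAlignment, frame: int | None = None
) -> tuple[BarcodeAlignment, list[NumtReport]]:
    """Screen and return (clean alignment, full report list).

    Reproduces the usual handling of NUMT-contaminated datasets: the
    flagged records are excluded from downstream distance and tree
    analyses.
    """
    reports = screen_numt(alignment, frame)
    bad = set(flagged_ids(reports))
    kept = [r for r in alignment.records if r.record_id not in bad]
    if not kept:
        raise ValueError("all records were flagged as putative NUMTs")
    return BarcodeAlignment(kept, outgroup_species=alignment.outgroup_species), reports
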