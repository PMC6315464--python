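"""Kimura two-parameter (K2P/K80) pairwise distances and divergence summaries.

The K2P distance corrects the observed proportions of transitional
(A<->G, C<->T) and transversional differences for multiple hits:

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

with P and Q the transition and transversion proportions over the sites
compared. Sites are compared under pairwise deletion: a column is used
for a pair iff both sequences carry an unambiguous A/C/G/T state there.
When the log argument is non-positive the estimator is undefined
(saturation); such pairs are flagged, not fabricated.

Distances are stored as proportions and reported as percentages (x100,
one decimal) in the tabular summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .seqio import BarcodeAlignment

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class SaturationError(ValueError):
    """The K2P estimator is undefined for this pair (log argument <= 0)."""


class NoComparableSitesError(ValueError):
    """No columns left for a pair after pairwise deletion."""


def encode_alignment(alignment: BarcodeAlignment) -> np.ndarray:
    """(n_records, length) int8 matrix; A/C/G/T -> 0..3, anything else -> -1."""
    buf = np.frombuffer(
        "".join(r.residues for r in alignment.records).encode("ascii"), dtype=np.uint8
    )
    return _CODE[buf].reshape(len(alignment.records), alignment.length)


def count_transitions_transversions(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n_transitions, n_transversions, n_compared) for two coded sequences."""
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    diff = valid & (a != b)
    # A=0, G=2 are even; C=1, T=3 are odd: a substitution within a parity
    # class is a transition, across classes a transversion.
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, n


def k2p_from_proportions(p: float, q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={p:.4g}, Q={q:.4g} (log argument <= 0)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalizes -0.0


def k2p_distance(seq1: str, seq2: str) -> float:
    """K2P distance between two equal-length residue strings.

    Raises :class:`SaturationError` when the estimator is undefined and
    :class:`NoComparableSitesError` when pairwise deletion leaves nothing.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    a = _CODE[np.frombuffer(seq1.upper().encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(seq2.upper().encode("ascii"), dtype=np.uint8)]
    ts, tv, n = count_transitions_transversions(a, b)
    if n == 0:
        raise NoComparableSitesError("no comparable sites after pairwise deletion")
    return k2p_from_proportions(ts / n, tv / n)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix keyed by record id.

    Saturated pairs hold NaN in ``values`` and are listed in
    ``saturated_pairs``; summary operations exclude them with a warning.
    """

    ids: list[str]
    values: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        assert self.values.shape == (n, n)
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def get(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def is_saturated(self, id1: str, id2: str) -> bool:
        return math.isnan(self.get(id1, id2))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    def write_phylip(self, path) -> None:
        """Square PHYLIP distance format (relaxed names, tab-separated)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.values):
                cells = "\t".join(f"{v:.8f}" for v in row)
                fh.write(f"{rid}\t{cells}\n")


def build_distance_matrix(alignment: BarcodeAlignment) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion.

    Saturated pairs are tolerated (NaN + flag); a pair with zero
    comparable sites is an error, since no estimate can be defined at all.
    """
    if len(alignment) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    codes = encode_alignment(alignment)
    return distance_matrix_from_codes(codes, alignment.ids)


def distance_matrix_from_codes(codes: np.ndarray, ids: list[str]) -> DistanceMatrix:
    n = codes.shape[0]
    values = np.zeros((n, n), dtype=float)
    saturated: list[tuple[str, str]] = []
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise NoComparableSitesError(
                    f"pair ({ids[i]!r}, {ids[j]!r}): no comparable sites"
                )
            a = codes[i][both]
            b = codes[j][both]
            diff = a != b
            ts = int((diff & ((a & 1) == (b & 1))).sum())
            tv = int(diff.sum()) - ts
            try:
                d = k2p_from_proportions(ts / m, tv / m)
            except SaturationError:
                d = math.nan
                saturated.append((ids[i], ids[j]))
            values[i, j] = values[j, i] = d
    if saturated:
        logger.warning("K2P saturation for %d pair(s): %s", len(saturated), saturated)
    return DistanceMatrix(ids=list(ids), values=values, saturated_pairs=saturated)


def _pair_distances(
    matrix: DistanceMatrix, partition: dict[str, list[str]]
) -> tuple[list[float], list[float]]:
    """(intraspecific, interspecific) distance multisets, NaN excluded."""
    species_of = {
        rid: sp for sp, ids in partition.items() for rid in ids
    }
    covered = [rid for rid in matrix.ids if rid in species_of]
    intra, inter = [], []
    n_dropped = 0
    for id1, id2 in combinations(covered, 2):
        d = matrix.get(id1, id2)
        if math.isnan(d):
            n_dropped += 1
            continue
        (intra if species_of[id1] == species_of[id2] else inter).append(d)
    if n_dropped:
        logger.warning("excluded %d saturated pair(s) from summaries", n_dropped)
    return intra, inter


@dataclass(frozen=True)
class DivergenceSummary:
    """Per-species intraspecific and per-species-pair interspecific K2P
    divergence (proportions; use :meth:`intraspecific_frame` /
    :meth:`interspecific_frame` for percentage tables)."""

    intraspecific: dict[str, tuple[float, float, float, int] | None]
    # species -> (mean, min, max, n_pairs); None for singleton species
    interspecific: dict[tuple[str, str], tuple[float, int]]
    # (species_a, species_b) sorted -> (mean, n_pairs)

    def intraspecific_frame(self) -> pd.DataFrame:
        rows = []
        for sp in sorted(self.intraspecific):
            v = self.intraspecific[sp]
            if v is None:
                rows.append({"species": sp, "mean_pct": "N/A", "min_pct": "N/A",
                             "max_pct": "N/A", "n_pairs": 0})
            else:
                mean, lo, hi, n = v
                rows.append({"species": sp, "mean_pct": round(100 * mean, 1),
                             "min_pct": round(100 * lo, 1),
                             "max_pct": round(100 * hi, 1), "n_pairs": n})
        return pd.DataFrame(rows)

    def interspecific_frame(self) -> pd.DataFrame:
        rows = [
            {"species_a": a, "species_b": b,
             "mean_pct": round(100 * self.interspecific[(a, b)][0], 1),
             "n_pairs": self.interspecific[(a, b)][1]}
            for (a, b) in sorted(self.interspecific)
        ]
        return pd.DataFrame(rows)


def divergence_summary(
    matrix: DistanceMatrix, partition: dict[str, list[str]]
) -> DivergenceSummary:
    """Per-species (mean, min, max) intraspecific distance and mean
    interspecific distance per species pair, over all defined pairs."""
    intra: dict[str, tuple[float, float, float, int] | None] = {}
    for sp, ids in partition.items():
        ds = [
            matrix.get(a, b)
            for a, b in combinations(ids, 2)
            if not math.isnan(matrix.get(a, b))
        ]
        intra[sp] = (
            (float(np.mean(ds)), min(ds), max(ds), len(ds)) if ds else None
        )
    inter: dict[tuple[str, str], tuple[float, int]] = {}
    for sp_a, sp_b in combinations(sorted(partition), 2):
        ds = [
            matrix.get(a, b)
            for a in partition[sp_a]
            for b in partition[sp_b]
            if not math.isnan(matrix.get(a, b))
        ]
        if ds:
            inter[(sp_a, sp_b)] = (float(np.mean(ds)), len(ds))
    return DivergenceSummary(intraspecific=intra, interspecific=inter)


@dataclass(frozen=True)
class OverlapReport:
    """Barcoding-gap summary: interval endpoints of the intra- and
    interspecific distance distributions plus binned histograms."""

    max_intraspecific: float
    min_interspecific: float
    bin_width: float
    intra_histogram: tuple[tuple[float, int], ...]  # (bin left edge, count)
    inter_histogram: tuple[tuple[float, int], ...]

    @property
    def overlap_width(self) -> float:
        """max_intra - min_inter; positive iff the two ranges overlap."""
        return self.max_intraspecific - self.min_interspecific


def overlap_report(
    matrix: DistanceMatrix,
    partition: dict[str, list[str]],
    bin_width: float = 0.005,
) -> OverlapReport:
    """Compare the intra- and interspecific distance distributions.

    ``bin_width`` is in distance units (default 0.005 = half a percentage
    point, the granularity barcoding-gap histograms are usually drawn at).
    """
    intra, inter = _pair_distances(matrix, partition)
    if not intra:
        raise ValueError("no intraspecific pairs: overlap is undefined")
    if not inter:
        raise ValueError("no interspecific pairs: overlap is undefined")

    def hist(values: list[float]) -> tuple[tuple[float, int], ...]:
        top = max(max(values), bin_width)
        n_bins = int(math.ceil(top / bin_width)) or 1
        counts, edges = np.histogram(values, bins=n_bins, range=(0.0, n_bins * bin_width))
        return tuple((float(e), int(c)) for e, c in zip(edges[:-1], counts))

    return OverlapReport(
        max_intraspecific=max(intra),
        min_interspecific=min(inter),
        bin_width=bin_width,
        intra_histogram=hist(intra),
        inter_histogram=hist(inter),
    )
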