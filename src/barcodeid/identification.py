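"""Leave-one-out distance-based species identification.

Implements the three identification-success criteria of Meier et al. as
used in barcoding-gap studies:

* **Best Match (BM)** — the query takes the species of its nearest
  neighbour(s); all conspecific -> correct, all allospecific ->
  incorrect, a mixed tie -> ambiguous.
* **Best Close Match (BCM)** — as BM, but a query whose nearest
  neighbour lies above a distance threshold gets *no match*.
* **All Species Barcodes (ASB)** — as BCM, but a correct identification
  is downgraded to ambiguous when the query has only a single
  conspecific reference, i.e. its species' barcode set is exhausted by
  one sequence.

The threshold is the nearest-rank 95th percentile of all intraspecific
pairwise distances. Because a species represented by a single sequence
can never be matched correctly, each singleton is duplicated before
analysis; the duplicate is a legal (zero-distance) match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import pandas as pd

from .distance import DistanceMatrix, build_distance_matrix
from .seqio import BarcodeAlignment, duplicate_record

#: Absolute tolerance for "equal best distance" ties. Distances are
#: analytic functions of integer mismatch counts, so true ties are exact;
#: the tolerance only guards against floating-point jitter.
TIE_TOLERANCE = 1e-9

SINGLETON_SUFFIX = "_dup"


class Criterion(str, Enum):
    BM = "BM"
    BCM = "BCM"
    ASB = "ASB"


class Category(str, Enum):
    CORRECT = "correct"
    AMBIGUOUS = "ambiguous"
    INCORRECT = "incorrect"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    criterion: Criterion
    category: Category
    best_distance: float
    best_match_ids: tuple[str, ...]
    threshold_used: float | None


def augment_singletons(
    alignment: BarcodeAlignment, suffix: str = SINGLETON_SUFFIX
) -> BarcodeAlignment:
    """Duplicate every singleton species' record once (outgroup excluded).

    The duplicate carries a marked id suffix and identical residues, so
    the species contributes one zero-distance intraspecific pair.
    """
    partition = alignment.species_partition()
    records = list(alignment.records)
    for sp, ids in partition.items():
        if len(ids) == 1:
            (rid,) = ids
            original = next(r for r in alignment.records if r.record_id == rid)
            records.append(duplicate_record(original, suffix))
    return BarcodeAlignment(records, outgroup_species=alignment.outgroup_species)


def intraspecific_distances(
    matrix: DistanceMatrix, partition: dict[str, list[str]]
) -> list[float]:
    ds = []
    for ids in partition.values():
        for a, b in combinations(ids, 2):
            d = matrix.get(a, b)
            if not math.isnan(d):
                ds.append(d)
    return ds


def compute_threshold(
    matrix: DistanceMatrix,
    partition: dict[str, list[str]],
    percentile: float = 95.0,
) -> float:
    """Nearest-rank percentile of all intraspecific pairwise distances.

    With m intraspecific pairs, returns the k-th smallest distance where
    k = ceil(percentile/100 * m) — always an actually observed value.
    """
    ds = sorted(intraspecific_distances(matrix, partition))
    if not ds:
        raise ValueError("no intraspecific pairs: threshold is undefined")
    k = max(1, math.ceil(percentile / 100.0 * len(ds)))
    return ds[min(k, len(ds)) - 1]


def classify_query(
    query_id: str,
    matrix: DistanceMatrix,
    partition: dict[str, list[str]],
    criterion: Criterion | str,
    threshold: float | None = None,
) -> IdentificationResult:
    """Classify one query against all other records (leave-one-out)."""
    criterion = Criterion(criterion)
    species_of = {rid: sp for sp, ids in partition.items() for rid in ids}
    if query_id not in species_of:
        raise KeyError(f"unknown query id {query_id!r}")
    if criterion in (Criterion.BCM, Criterion.ASB) and threshold is None:
        raise ValueError(f"{criterion.value} requires a threshold")

    references = [rid for rid in matrix.ids if rid != query_id and rid in species_of]
    if not references:
        raise ValueError("no reference sequences besides the query")
    dists = {rid: matrix.get(query_id, rid) for rid in references}
    defined = {rid: d for rid, d in dists.items() if not math.isnan(d)}
    if not defined:
        raise ValueError(f"all distances from {query_id!r} are saturated")

    best = min(defined.values())
    matches = tuple(
        rid for rid, d in defined.items() if d <= best + TIE_TOLERANCE
    )
    query_species = species_of[query_id]

    if criterion in (Criterion.BCM, Criterion.ASB) and best > threshold:
        return IdentificationResult(
            query_id, criterion, Category.NO_MATCH, best, (), threshold
        )

    conspecific = [species_of[m] == query_species for m in matches]
    if all(conspecific):
        category = Category.CORRECT
    elif not any(conspecific):
        category = Category.INCORRECT
    else:
        category = Category.AMBIGUOUS

    if criterion is Criterion.ASB and category is Category.CORRECT:
        n_conspecific_refs = sum(
            1 for rid in references if species_of[rid] == query_species
        )
        if n_conspecific_refs == 1:
            category = Category.AMBIGUOUS

    return IdentificationResult(
        query_id,
        criterion,
        category,
        best,
        matches,
        threshold if criterion is not Criterion.BM else None,
    )


@dataclass(frozen=True)
class IdentificationSummary:
    """Identification-success roll-up over a whole dataset."""

    n_sequences: int
    n_species: int
    threshold: float
    percentile: float
    counts: dict[Criterion, dict[Category, int]]
    results: dict[Criterion, tuple[IdentificationResult, ...]]
    n_zero_distance_closest: int
    n_allospecific_zero_matches: int

    def percentages(self) -> dict[Criterion, dict[Category, float]]:
        return {
            crit: {
                cat: round(100.0 * n / self.n_sequences, 2)
                for cat, n in cats.items()
            }
            for crit, cats in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = []
        for crit in Criterion:
            for cat in Category:
                rows.append(
                    {
                        "criterion": crit.value,
                        "category": cat.value,
                        "count": self.counts[crit][cat],
                        "percent": pct[crit][cat],
                    }
                )
        return pd.DataFrame(rows)


def summarize_identifications(
    alignment: BarcodeAlignment,
    matrix: DistanceMatrix | None = None,
    percentile: float = 95.0,
) -> IdentificationSummary:
    """Run all three criteria over every record of an (already
    singleton-augmented) alignment and tabulate the outcome.

    The outgroup, if labelled, is excluded from both queries and
    references. Also reports how many queries sit at zero distance from
    their closest match, and how many of those zero-distance match sets
    contain an allospecific sequence (shared barcodes across species).
    """
    partition = alignment.species_partition()
    if matrix is None:
        matrix = build_distance_matrix(alignment.ingroup() if alignment.outgroup_species else alignment)
    threshold = compute_threshold(matrix, partition, percentile)

    query_ids = [rid for ids in partition.values() for rid in ids]
    query_ids = [rid for rid in matrix.ids if rid in set(query_ids)]

    counts = {c: {cat: 0 for cat in Category} for c in Criterion}
    results = {c: [] for c in Criterion}
    n_zero = 0
    n_allo_zero = 0
    species_of = {rid: sp for sp, ids in partition.items() for rid in ids}
    for qid in query_ids:
        for crit in Criterion:
            res = classify_query(qid, matrix, partition, crit, threshold)
            counts[crit][res.category] += 1
            results[crit].append(res)
            if crit is Criterion.BM:
                if res.best_distance <= TIE_TOLERANCE:
                    n_zero += 1
                    if any(species_of[m] != species_of[qid] for m in res.best_match_ids):
                        n_allo_zero += 1

    return IdentificationSummary(
        n_sequences=len(query_ids),
        n_species=len(partition),
        threshold=threshold,
        percentile=percentile,
        counts=counts,
        results={c: tuple(v) for c, v in results.items()},
        n_zero_distance_closest=n_zero,
        n_allospecific_zero_matches=n_allo_zero,
    )


def results_frame(summary: IdentificationSummary, species_of: dict[str, str]) -> pd.DataFrame:
    """Per-query long-format report across all criteria."""
    rows = []
    for crit, results in summary.results.items():
        for r in results:
            rows.append(
                {
                    "query_id": r.query_id,
                    "species": species_of.get(r.query_id, ""),
                    "criterion": crit.value,
                    "category": r.category.value,
                    "best_distance": r.best_distance,
                    "best_match_ids": ",".join(r.best_match_ids),
                }
            )
    return pd.DataFrame(rows)
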