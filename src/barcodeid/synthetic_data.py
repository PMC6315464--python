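"""Synthetic barcode datasets with the structure of a real barcoding study.

Generates multi-species alignments under the K80 (Kimura two-parameter)
substitution process: a species tree (balanced by default) scaled so the
mean pairwise distance between species matches a target interspecific
divergence, per-species clusters of near-identical haplotypes at a
target intraspecific divergence, singleton species, a distant outgroup,
and optional NUMT-like pseudogene injection (deletions + internal stop
codons). The default configuration mirrors a typical blow-fly COI
study: 16 species with uneven sampling (including one singleton),
1247-bp amplicons, A/T-rich composition (~69.5% A+T), intraspecific
divergence well below 1% and interspecific divergence of several
percent.

All randomness flows through one ``numpy`` generator seeded from the
config, so regeneration from the same config is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import BarcodeAlignment, SequenceRecord

_BASES = "ACGT"
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T

#: Per-species sequence counts of a 16-species blow-fly COI survey
#: (uneven sampling with one singleton species), totalling 113.
STUDY_LIKE_COUNTS = (1, 15, 8, 7, 2, 4, 14, 14, 8, 9, 6, 5, 10, 4, 3, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic reference dataset.

    Divergences are expected pairwise K2P distances (proportions);
    ``kappa`` is the transition/transversion *rate* ratio.
    ``base_frequencies`` is (A, C, G, T) for the ancestral draw — the
    default is the A/T-rich composition typical of insect mtDNA.
    ``avoid_stop_codons`` repairs frame-0 stop codons so the data look
    like a functional protein-coding gene; disable it to simulate the
    pure K80 process.
    """

    n_species: int = 16
    seqs_per_species: int | tuple[int, ...] = STUDY_LIKE_COUNTS
    seq_length: int = 1247
    interspecific_divergence: float = 0.08
    intraspecific_divergence: float = 0.005
    kappa: float = 4.0
    base_frequencies: tuple[float, float, float, float] = (0.307, 0.149, 0.156, 0.388)
    outgroup_divergence: float = 0.13
    outgroup_species: str = "Outgroup"
    tree_shape: str = "balanced"  # "balanced" | "random"
    avoid_stop_codons: bool = True
    seed: int = 0

    def per_species_counts(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_species, int):
            return (self.seqs_per_species,) * self.n_species
        return tuple(self.seqs_per_species)

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        counts = self.per_species_counts()
        if len(counts) != self.n_species or any(c < 1 for c in counts):
            raise ValueError("seqs_per_species must give >=1 per species")
        if self.seq_length < 60:
            raise ValueError("seq_length must be >= 60")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ValueError("base_frequencies must sum to 1")
        if min(self.base_frequencies) < 0:
            raise ValueError("base_frequencies must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for name in ("interspecific_divergence", "intraspecific_divergence",
                     "outgroup_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tree_shape not in ("balanced", "random"):
            raise ValueError("tree_shape must be 'balanced' or 'random'")


@dataclass
class SyntheticDataset:
    alignment: BarcodeAlignment
    true_tree_newick: str
    config: SimulationConfig


def k80_transition_matrix(d: float, kappa: float) -> np.ndarray:
    """4x4 substitution probability matrix for branch length ``d``
    (expected substitutions/site) under K80 with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = math.exp(-4.0 * beta * d)
    e_ts = math.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv  # each of the two transversion targets
    T = np.full((4, 4), p_tv)
    for s in range(4):
        T[s, _TS_PARTNER[s]] = p_ts
        T[s, s] = 1.0 - p_ts - 2.0 * p_tv
    return T


def evolve_sequence(codes: np.ndarray, d: float, kappa: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Evolve a coded (0..3) sequence along a branch of length ``d``."""
    if d == 0.0:
        return codes.copy()
    T = k80_transition_matrix(d, kappa)
    cum = np.cumsum(T, axis=1)
    u = rng.random(codes.shape[0])
    return (u[:, None] > cum[codes]).sum(axis=1).astype(np.int8)


# --- species tree -----------------------------------------------------------


class _SpNode:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, children=None, length=0.0):
        self.name = name
        self.children = children or []
        self.length = length

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _build_shape(names: list[str], shape: str, rng: np.random.Generator) -> _SpNode:
    if len(names) == 1:
        return _SpNode(name=names[0], length=1.0)
    if shape == "balanced":
        half = len(names) // 2
        left, right = names[:half], names[half:]
    else:
        k = int(rng.integers(1, len(names)))
        perm = list(rng.permutation(names))
        left, right = sorted(perm[:k]), sorted(perm[k:])
    node = _SpNode(length=1.0)
    node.children = [_build_shape(left, shape, rng), _build_shape(right, shape, rng)]
    return node


def _leaf_depths(node: _SpNode, depth: float = 0.0) -> dict[str, float]:
    depth += node.length
    if not node.children:
        return {node.name: depth}
    out = {}
    for c in node.children:
        out.update(_leaf_depths(c, depth))
    return out


def _mean_pairwise_path(node: _SpNode) -> float:
    """Mean leaf-to-leaf path length, computed bottom-up."""
    # returns (list of (leaf depth from this node), running sums)
    total, n_pairs = 0.0, 0

    def walk(nd: _SpNode) -> list[float]:
        nonlocal total, n_pairs
        if not nd.children:
            return [nd.length]
        groups = [walk(c) for c in nd.children]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                for a in groups[i]:
                    for b in groups[j]:
                        total += a + b
                        n_pairs += 1
        return [d + nd.length for g in groups for d in g]

    walk(node)
    if n_pairs == 0:
        return 0.0
    return total / n_pairs


def _scale_tree(node: _SpNode, factor: float) -> None:
    node.length *= factor
    for c in node.children:
        _scale_tree(c, factor)


# --- stop-codon repair ------------------------------------------------------

_STOP_CODONS = {(3, 0, 0), (3, 0, 2)}  # TAA, TAG under code table 5


def repair_stop_codons(codes: np.ndarray) -> np.ndarray:
    """Rewrite frame-0 stop codons (TAA/TAG) to TAT (Tyr), emulating
    purifying selection against nonsense mutations in a coding gene."""
    out = codes.copy()
    for start in range(0, len(out) - 2, 3):
        if (out[start], out[start + 1], out[start + 2]) in _STOP_CODONS:
            out[start + 2] = 3  # third position -> T
    return out


# --- main simulation --------------------------------------------------------


def simulate_reference_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a species-labelled alignment under the configured
    conditions. Deterministic given the config (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = [f"Species_{i + 1:02d}" for i in range(config.n_species)]
    counts = config.per_species_counts()

    # species tree scaled to the target mean between-species divergence
    root = _build_shape(names, config.tree_shape, rng)
    root.length = 0.0
    if config.n_species > 1:
        mean_path = _mean_pairwise_path(root)
        _scale_tree(root, config.interspecific_divergence / mean_path)
        root.length = 0.0

    freqs = np.asarray(config.base_frequencies)
    ancestral = rng.choice(4, size=config.seq_length, p=freqs).astype(np.int8)
    if config.avoid_stop_codons:
        ancestral = repair_stop_codons(ancestral)

    # evolve centroids down the species tree
    centroids: dict[str, np.ndarray] = {}

    def descend(node: _SpNode, seq: np.ndarray) -> None:
        evolved = evolve_sequence(seq, node.length, config.kappa, rng)
        if not node.children:
            centroids[node.name] = evolved
        for c in node.children:
            descend(c, evolved)

    descend(root, ancestral)

    records: list[SequenceRecord] = []
    for sp, count in zip(names, counts):
        for i in range(count):
            member = evolve_sequence(
                centroids[sp], config.intraspecific_divergence / 2.0,
                config.kappa, rng,
            )
            if config.avoid_stop_codons:
                member = repair_stop_codons(member)
            records.append(
                SequenceRecord(
                    record_id=f"{sp}_{i + 1:02d}",
                    species=sp,
                    site="sim",
                    residues="".join(_BASES[c] for c in member),
                )
            )

    # outgroup branch: total outgroup-to-ingroup distance ~ outgroup_divergence
    depths = _leaf_depths(root)
    mean_depth = float(np.mean(list(depths.values())))
    out_branch = max(config.outgroup_divergence - mean_depth, 1e-6)
    out_seq = evolve_sequence(ancestral, out_branch, config.kappa, rng)
    if config.avoid_stop_codons:
        out_seq = repair_stop_codons(out_seq)
    records.append(
        SequenceRecord(
            record_id=f"{config.outgroup_species}_01",
            species=config.outgroup_species,
            site="sim",
            residues="".join(_BASES[c] for c in out_seq),
        )
    )

    newick = f"({root.newick()},{config.outgroup_species}:{out_branch:.6f});" \
        if config.n_species > 1 else \
        f"({names[0]}:{mean_depth:.6f},{config.outgroup_species}:{out_branch:.6f});"
    alignment = BarcodeAlignment(records, outgroup_species=config.outgroup_species)
    return SyntheticDataset(alignment=alignment, true_tree_newick=newick, config=config)


def inject_numt(
    record: SequenceRecord,
    deletion_length: int = 30,
    n_stop_mutations: int = 2,
    seed: int = 0,
) -> SequenceRecord:
    """Turn a clean record into a NUMT-like pseudogene copy.

    Deletes a contiguous block (written as gaps against the alignment)
    and/or converts frame-0 codons downstream of the deletion into stop
    codons (TAA/TAG). The output is detectable by the NUMT screen by
    construction; parameter combinations that cannot produce a
    detectable pseudogene raise ``ValueError``.
    """
    if deletion_length < 0 or deletion_length >= len(record.residues):
        raise ValueError("deletion_length must be in [0, record length)")
    if n_stop_mutations < 1 and deletion_length % 3 == 0:
        raise ValueError(
            "undetectable NUMT: need >=1 stop mutation or a deletion "
            "length not divisible by 3"
        )
    rng = np.random.default_rng(seed)
    residues = list(record.residues)
    length = len(residues)

    # place the deletion at a codon boundary in the first half so enough
    # downstream codons remain for stop injection
    del_start = 0
    if deletion_length > 0:
        max_start = max(0, length // 2 - deletion_length)
        del_start = 3 * int(rng.integers(0, max(1, max_start // 3)))
        for k in range(del_start, del_start + deletion_length):
            residues[k] = "-"
    del_end = del_start + deletion_length

    if n_stop_mutations > 0:
        nongap_cols = [i for i, c in enumerate(residues) if c != "-"]
        n_codons = len(nongap_cols) // 3
        candidates = [
            j for j in range(n_codons - 1)  # last codon cannot be internal
            if nongap_cols[3 * j] >= del_end
        ]
        if len(candidates) < n_stop_mutations:
            raise ValueError(
                "not enough downstream codons to place the requested stops"
            )
        chosen = rng.choice(len(candidates), size=n_stop_mutations, replace=False)
        for idx in sorted(int(c) for c in chosen):
            j = candidates[idx]
            stop = "TAA" if rng.random() < 0.5 else "TAG"
            for offset in range(3):
                residues[nongap_cols[3 * j + offset]] = stop[offset]

    return replace(record, residues="".join(residues))
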