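# Methods

## Scope and model

`barcodeid` implements the standard distance- and tree-based analysis of a
DNA-barcoding reference library: a set of aligned, equal-length
mitochondrial protein-coding sequences, each labelled with a species (the
ground truth), plus an outgroup. All genetic distances are Kimura
two-parameter (K2P) distances,

    d = -(1/2) · ln((1 − 2P − Q) · sqrt(1 − 2Q)),

with `P` and `Q` the proportions of transitional (A↔G, C↔T) and
transversional differences over the sites compared. K2P assumes equal base
frequencies and a single transition/transversion rate ratio; it remains
the de facto convention of the barcoding literature, which is why it is
the only model offered. The estimator is undefined when `1 − 2P − Q ≤ 0`
or `1 − 2Q ≤ 0` (saturation); such pairs are flagged and carried as
missing rather than silently truncated, and summary statistics exclude
them with a warning.

**Gap/ambiguity policy.** Distances use pairwise deletion: a column
contributes to a pair iff both sequences have an unambiguous A/C/G/T
state there. Haplotype collapsing and polymorphic-site counts instead
drop, for the analysed record set, every column containing a gap or
ambiguity code anywhere, then compare complete columns — the behaviour
of the classical polymorphism tools. Variable-site classification
ignores non-ACGT states column-wise (an ambiguity code neither creates
nor suppresses variability). On indel-free, unambiguous data all three
policies coincide; they are fixed here so general inputs behave
predictably.

## Distance-based identification

Identification is leave-one-out: each record in turn is the query, all
others the references; the outgroup never participates. The three
criteria of Meier et al. are:

- **BM** — the query takes the species of its nearest neighbour(s). The
  match set is every reference within `1e-9` of the minimal distance
  (distances are analytic functions of integer mismatch counts, so true
  ties are exact; the tolerance only absorbs floating-point jitter).
  All-conspecific → correct, all-allospecific → incorrect, mixed →
  ambiguous.
- **BCM** — as BM, but if the best distance exceeds the threshold the
  query gets *no match*.
- **ASB** — as BCM, with a correct result downgraded to *ambiguous* when
  the query has exactly one conspecific reference. This reading — rather
  than stricter all-conspecific-barcode formulations — is the one
  consistent with how surveys report the criterion: the ambiguous calls
  are exactly the duplicated singletons and two-member species.

**Threshold.** The BCM/ASB threshold is the nearest-rank 95th percentile
of the multiset of all intraspecific pairwise distances
(`k = ceil(0.95·m)`-th smallest of `m`), an actually observed distance.
It is computed on the singleton-augmented dataset (below), so duplicated
singletons contribute zero-distance pairs. By construction roughly 5% of
intraspecific distances exceed it, so occasional BCM/ASB *no match*
results on real-shaped data are expected behaviour, not an error.

**Singleton duplication.** A species represented by one sequence can
never be matched correctly under leave-one-out, so each singleton is
duplicated once (id suffix `_dup`) before analysis; the duplicate is a
legal zero-distance match. This mirrors standard practice and is why an
n-record dataset with one singleton is analysed as n+1 sequences.

## Tree-based identification

Neighbor joining follows Saitou & Nei: repeatedly join the pair
minimizing `Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, with branch lengths from
the standard rate-corrected formulas, ending in a central trifurcation.
Ties in `Q` (within `1e-12` relative) are broken toward the
lexicographically smallest pair of node labels, where an internal node
is labelled by its smallest descendant leaf id — this makes topologies
bit-reproducible across platforms. Negative branch lengths, a known NJ
artefact, are retained by default (`clamp_negative=True` floors them),
preserving the additivity of path lengths.

Bootstrap supports resample alignment columns with replacement to the
original length, rebuild the K2P matrix and NJ tree, and record for each
internal bipartition of the *original* tree the percentage of replicates
containing it (supports are attached to the original tree, not a
consensus). Replicates whose resampled matrix contains a saturated pair
are redrawn and counted. A species is monophyletic iff its leaf set is
exactly one side of some edge — equivalently, a single clade once the
tree is rooted on the outgroup; singletons are trivially monophyletic.
Trees are carried as dendropy objects; Newick output stores supports as
integer internal-node labels and round-trips.

## NUMT screening

Nuclear mitochondrial pseudogenes are detected by translating each
record (degapped) with the invertebrate mitochondrial code, NCBI
table 5, taken from Biopython's codon tables (stops TAA/TAG only;
TGA=Trp, ATA=Met, AGA/AGG=Ser). A record is flagged iff it has at least
one internal stop codon (a stop followed by a real codon; a terminal
stop is not internal because amplicons need not end on a gene boundary)
or a gap run whose length is not a multiple of three. The reading frame
is inferred once per alignment — all amplicons share primers, hence a
frame — as the frame minimizing the total internal-stop count, ties
toward frame 0. Flagged records are reported, never silently removed;
`drop_flagged` reproduces the usual exclusion step.

## Synthetic data

The simulator emulates the structure of a real barcoding survey rather
than any particular dataset: a balanced species tree (random shapes
optional) with edges scaled so the *mean* pairwise between-species path
length equals the target interspecific divergence; an ancestral sequence
drawn from the configured base frequencies; evolution by the exact K80
transition-probability matrix per branch (`kappa` = transition/
transversion rate ratio); species members evolved independently from
their species sequence along branches of half the target intraspecific
divergence (so expected member-pair distance hits the target); and an
outgroup attached so its mean distance to the ingroup matches the
outgroup target. All randomness flows through a single seeded generator,
so datasets regenerate bit-identically.

Default conditions mirror a 16-species blow-fly COI survey: per-species
counts `(1, 15, 8, 7, 2, 4, 14, 14, 8, 9, 6, 5, 10, 4, 3, 3)` (113
sequences, one singleton), 1247 bp, base frequencies
(A, C, G, T) = (0.307, 0.149, 0.156, 0.388) (~69.5% A+T), intraspecific
divergence 0.005, interspecific 0.08, outgroup 0.13, `kappa = 4`
(typical of insect mitochondrial protein genes).

Because the real markers are protein-coding, the generator by default
repairs frame-0 stop codons (TAA/TAG → TAT) in the ancestral and final
sequences, emulating purifying selection against nonsense mutations;
this is what makes "clean simulated sequences are never NUMT-flagged" a
meaningful specificity check. The repair is a small departure from the
pure K80 process, so parameter-recovery tests of the K2P estimator
disable it (`avoid_stop_codons=False`). Two further idealizations: the
K80 process drifts composition slightly toward uniform along deep
branches, so realized A+T content sits a little below the ancestral
target; and there is no indel or rate-heterogeneity model — gaps enter
only via explicit NUMT injection. Passing tests on this generator
therefore demonstrate correctness of the estimators and decision rules
under the assumed substitution model, not robustness to alignment error,
heterotachy, or introgression in field data.

`inject_numt` produces the diagnostic pseudogene pattern — a contiguous
deletion (written as gaps) placed on a codon boundary in the first half
of the sequence, plus a chosen number of downstream frame-0 stop codons
— and rejects parameter combinations that could not be detected
(deletion divisible by three with no stops).

## Numerical and size choices

- Distances are kept at full precision internally; tabular reports
  multiply by 100 and round to 1 decimal (2 decimals for identification
  percentages and thresholds), the conventional presentation.
- Histogram bin width for the gap plot defaults to 0.005 (half a
  percentage point).
- The acceptance script runs the full default-size dataset (114 analysis
  sequences) but uses 100 bootstrap replicates, 20 replicate simulations
  of 100-kb pairs for parameter recovery, and 20 random tree-metric
  matrices for NJ verification — sizes chosen so the whole script
  completes in well under a minute while keeping Monte-Carlo error far
  below the tolerances asserted anywhere.

## Known limitations

- Only the K2P model; no variance estimates on distances; no
  model selection.
- BCM/ASB edge-case behaviour of historical implementations
  (percentile interpolation, tie handling) is not documented anywhere
  authoritative; the rules here are fixed, deterministic, and stated
  above, but may differ from legacy tools on adversarial inputs.
- NUMTs lacking both stops and frame-disrupting indels are undetectable
  by translation screening, by the nature of the test.
- The simulator's species tree scaling targets the *mean* interspecific
  divergence; individual species pairs vary around it, as in real data.
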