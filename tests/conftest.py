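import numpy as np
import pytest

from barcodeid import BarcodeAlignment, SequenceRecord


def make_record(record_id, species, residues, **kwargs):
    return SequenceRecord(record_id=record_id, species=species,
                          residues=residues, **kwargs)


def make_alignment(entries, outgroup_species=None):
    """entries: list of (record_id, species, residues)."""
    return BarcodeAlignment(
        [make_record(rid, sp, seq) for rid, sp, seq in entries],
        outgroup_species=outgroup_species,
    )


@pytest.fixture
def two_species_alignment():
    """Two well-separated species, two identical records each, plus an
    outgroup — a dataset with a clean barcoding gap."""
    a = "AAAAACCCCCGGGGGTTTTTAAAAACCCCCGGGGGTTTTTAAAAACCCCCGGGGGTTTTT"
    b = "AAAAACCCCCGGGGGTTTTTAAAAACCCCCTTTTTAAAAAAAAAACCCCCGGGGGTTTTT"
    # moderately divergent outgroup (~25% K2P, well below saturation)
    out = "GGGGGCCCCCGGGGGTTTTTCCCCCCCCCCGGGGGTTTTTTTTTTCCCCCGGGGGTTTTT"
    return make_alignment(
        [
            ("A1", "SpA", a),
            ("A2", "SpA", a),
            ("B1", "SpB", b),
            ("B2", "SpB", b),
            ("OUT1", "Musca_domestica", out),
        ],
        outgroup_species="Musca_domestica",
    )


def random_clean_alignment(rng, n_records=4, length=60, species="SpX"):
    """Random gap-free ACGT alignment (records may repeat)."""
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=length)
    entries = []
    for i in range(n_records):
        s = anc.copy()
        n_mut = int(rng.integers(0, max(1, length // 5)))
        pos = rng.choice(length, size=n_mut, replace=False)
        s[pos] = (s[pos] + rng.integers(1, 4, size=n_mut)) % 4
        entries.append((f"r{i}", species, "".join(bases[s])))
    return make_alignment(entries)
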