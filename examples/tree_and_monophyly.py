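"""Tree-based identification: NJ + bootstrap + per-species monophyly.

Builds a neighbor-joining tree from K2P distances, attaches
nonparametric bootstrap supports (column resampling), and checks that
each species forms a single clade when the tree is rooted on the
outgroup — the tree-based identification criterion.
"""

from barcodeid import (
    SimulationConfig,
    bootstrap_support,
    check_monophyly,
    simulate_reference_dataset,
    write_newick,
)

config = SimulationConfig(n_species=8, seqs_per_species=4, seq_length=800,
                          seed=7)
dataset = simulate_reference_dataset(config)
alignment = dataset.alignment

tree = bootstrap_support(alignment, n_replicates=200, seed=11)
write_newick(tree, "simulated_tree.nwk")
print("wrote simulated_tree.nwk (supports as internal node labels)")

flags = check_monophyly(
    tree, alignment.species_partition(include_outgroup=True),
    outgroup_species=config.outgroup_species)
partition = alignment.species_partition()
for sp in sorted(flags):
    split = frozenset(partition[sp])
    support = tree.supports.get(split)
    support_txt = f"{support:.0f}%" if support is not None else "n/a"
    print(f"{sp}: monophyletic={flags[sp]}  bootstrap={support_txt}")

n_mono = sum(flags.values())
print(f"\n{n_mono}/{len(flags)} species are monophyletic — every specimen "
      "clusters with its own species, so tree-based identification succeeds")
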