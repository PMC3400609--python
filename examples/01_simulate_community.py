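"""Simulate a synthetic bacterial community and a fragmented site sample.

Builds the default blueprint (four TonB-dependent transporter families,
decoy ABC/PTS/TRAP families, six single-copy markers per genome), draws
five genomes and one 1,000-ORF metagenome sample, and prints the ground
truth the rest of the pipeline is asked to recover.
"""

import numpy as np

from tbdtscan import default_family_specs, generate_reference_set, generate_site_sample

specs = default_family_specs()
print("family blueprint:")
for s in specs:
    print(f"  {s.family_id:<12} {s.category:<5} group={s.group_label:<22} "
          f"copies/genome in {s.copies_per_genome_range}, divergence {s.divergence}")

genomes = generate_reference_set(specs, n_genomes=5, seed=7)
g = genomes[0]
print(f"\ngenome {g.genome_id}: {len(g.proteome)} proteins, "
      f"{g.size_mb * 1000:.1f} kb coding, copies {g.family_copies}")

weights = np.random.default_rng(7).dirichlet(np.ones(len(genomes)))
sample, truth = generate_site_sample(genomes, weights, n_orfs=1000, seed=7)
lengths = [len(o.residues) for o in sample.orfs]
print(f"\nsite {sample.site_id}: {len(sample.orfs)} ORF fragments, "
      f"median length {int(np.median(lengths))} aa")
print("true copies per genome equivalent (what profiling should recover):")
for fam, freq in truth.site_frequencies.items():
    print(f"  {fam:<12} {freq:.3f}")
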