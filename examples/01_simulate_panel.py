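"""Simulate a nest-structured haplodiploid SNP panel with ground truth.

Generates the bundled small-fixture design — three populations, haplodiploid
nests, planted autozygous tracts — and prints what the truth tables contain.
"""

import vespagen as vg

cfg = vg.SimConfig(seed=1, autozygosity_targets=(0.05, 0.2, 0.5))
gm, meta, truth = vg.simulate_panel(cfg)

print(f"panel: {gm.n_samples} samples x {gm.n_sites} SNPs "
      f"on {cfg.n_chrom} chromosomes of {cfg.chrom_length / 1e6:.0f} Mb")
print(meta.groupby(["population", "sex"]).size().unstack(fill_value=0))
print("\nplanted autozygous fractions (fraction of SNP-covered genome that is")
print("identical-by-descent by construction; the fROH statistic should recover these):")
for s, f in truth.planted_fraction.items():
    if f > 0:
        print(f"  {s}: {f:.3f} in {len(truth.tracts[s])} tracts")
d = next(iter(truth.pedigree))
print(f"\npedigree example: {d} <- mother {truth.pedigree[d][0]}, "
      f"father {truth.pedigree[d][1]} (all sisters share the father's single haplotype)")
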