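"""Simulate the two-platform re-sequencing study inputs.

Writes a reference genome with AT-rich repeats, a truth genotype set
(60% heterozygous), two platform call sets (Poisson depths 20x / 35x,
AT-biased vs uniform dropout, depth-dependent het-to-hom miscalls, 15%
platform-specific calls at 70% repeat enrichment), per-base depth/MQ
tracks, pileups, and chip genotypes with a 10% het-to-hom error.
"""

from common import SIM

from crossvar.synthetic_data import SimConfig, simulate_bundle


def main() -> None:
    config = SimConfig(seed=2013)
    paths = simulate_bundle(config, SIM)
    print(f"simulated {config.n_variant_sites} variant sites over "
          f"{config.genome_length:,} bp ({config.n_contigs} contigs)")
    for name, path in sorted(paths.items()):
        print(f"  {name:12s} {path.relative_to(SIM.parent.parent)}")


if __name__ == "__main__":
    main()
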