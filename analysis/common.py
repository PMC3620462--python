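"""Shared paths and bundle loading for the numbered analysis scripts."""

from pathlib import Path

from crossvar import io_formats as io

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SIM = SCRATCH / "sim"  # large generated inputs stay out of results/


def load_bundle(sim_dir: Path = SIM):
    """Load the simulated input bundle written by 01_simulate.py."""
    reference = io.read_fasta(sim_dir / "reference.fa")
    lengths = {c: len(s) for c, s in reference.items()}
    return {
        "reference": reference,
        "lengths": lengths,
        "repeats": io.read_bed(sim_dir / "repeats.bed"),
        "p1": io.read_snvs(sim_dir / "p1.vcf"),
        "p2": io.read_snvs(sim_dir / "p2.vcf"),
        "chip": io.read_chip(sim_dir / "chip.tsv"),
        "p1_depth": io.read_track(sim_dir / "p1.depth.bedgraph", lengths),
        "p1_mq": io.read_track(sim_dir / "p1.mq.bedgraph", lengths),
        "p2_depth": io.read_track(sim_dir / "p2.depth.bedgraph", lengths),
        "p2_mq": io.read_track(sim_dir / "p2.mq.bedgraph", lengths),
        "p1_pileups": io.read_pileups(sim_dir / "p1.pileup.tsv"),
        "p2_pileups": io.read_pileups(sim_dir / "p2.pileup.tsv"),
    }
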