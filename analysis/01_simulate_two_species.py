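"""Simulate the two toy congeners (1.0 vs 1.9 Mb) and their reads.

Two genomes share eight repeat families at roughly doubled copy number
in the larger genome, except an Athila-like lineage (higher GP in the
small genome) and a HeloSAT-like satellite (GP ~10% vs ~1%). Writes
genomes, truth tables, and organelle-spiked paired-end FASTQ at 0.15x
coverage to the run directory.
"""

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline
from skimrepeats.seqio import read_tsv


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["simulate"])
    for code in ("HKOR", "HUMB"):
        truth = read_tsv(f"{cfg.outdir}/truth_{code}.tsv")
        repeats = 100 * truth["gp"].sum()
        print(f"{code}: {len(truth)} families, repeats cover {repeats:.1f}% of the genome")
        sat = truth[truth["family"] == "HeloSAT"].iloc[0]
        print(f"  HeloSAT satellite GP {100 * sat['gp']:.2f}% ({sat['copies']} arrays)")


if __name__ == "__main__":
    main()
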