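"""Solo-LTR quantification via junction tags (the Rsf statistic).

For the two most abundant LTR lineages, 30-nt tags at the LTR-3'/5'-UTR
junction classify reads into LTR-end hits (Lx) and junction-spanning
hits (LU); Rsf = (Lx - LU)/LU rises with the solo:full ratio, i.e. with
the footprint of unequal recombination. The small genome was simulated
with a higher solo fraction, so its Rsf should come out larger.
"""

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline
from skimrepeats.seqio import read_tsv


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["rsf"])
    table = read_tsv(f"{cfg.outdir}/rsf.tsv")
    for _, row in table.iterrows():
        print(
            f"{row['species']} {row['family']}: Lx={row['Lx']} LU={row['LU']} "
            f"Rsf={row['Rsf']:.2f}"
        )


if __name__ == "__main__":
    main()
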