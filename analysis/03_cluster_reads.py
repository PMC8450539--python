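"""Graph-based clustering: per-species runs plus the pooled comparative run.

Reads are vertices, similarity hits (90% identity over 55% of the read)
are edges, connected components are clusters, and mate-linked clusters
form superclusters. Writes cluster tables, memberships and consensus
sequences.
"""

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline
from skimrepeats.seqio import read_tsv


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["cluster"])
    for label in ("individual_HKOR", "individual_HUMB", "comparative"):
        table = read_tsv(f"{cfg.outdir}/clusters_{label}.tsv")
        print(f"{label}: {len(table)} clusters, largest {table['size'].max()} reads")


if __name__ == "__main__":
    main()
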