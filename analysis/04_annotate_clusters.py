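"""Annotate clusters against the packaged mini reference.

Each cluster read is searched against lineage-labeled exemplars; the
winning lineage needs >= 10% read support, and tandem-periodicity
detection on the consensus overrides mobile-element labels with
"satellite".
"""

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline
from skimrepeats.seqio import read_tsv


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["annotate"])
    anno = read_tsv(f"{cfg.outdir}/annotation_comparative.tsv")
    labeled = anno[anno["label"] != "unclassified"]
    print(f"comparative run: {len(labeled)}/{len(anno)} clusters classified")
    sats = anno.dropna(subset=["monomer_length"])
    for _, row in sats.iterrows():
        print(f"  {row['cluster']}: satellite, monomer {int(row['monomer_length'])} bp")


if __name__ == "__main__":
    main()
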