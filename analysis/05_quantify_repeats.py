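"""Abundance tables, the comparative read scatter, and regressions.

Produces per-species genome-proportion / Mb-per-1C tables, the shared-
cluster log2 GP ratios, the read-scatter slope (expected: the 1.9x
genome-size ratio) and lineage-wise OLS regressions with the
with/without-satellite contrast.
"""

import json

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline
from skimrepeats.seqio import read_tsv


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["quantify"])
    summary = json.load(open(f"{cfg.outdir}/comparative_summary.json"))
    print(
        f"read scatter slope {summary['scatter_slope']:.2f} "
        f"(expected {summary['expected_slope']:.2f} from the 1C ratio)"
    )
    for code in ("HKOR", "HUMB"):
        table = read_tsv(f"{cfg.outdir}/abundance_{code}.tsv")
        rep = table[table["lineage"] != "low/single copy"]
        print(
            f"{code}: repeats {rep['gp_percent'].sum():.1f}% of the genome "
            f"({rep['abundance_mb'].sum():.2f} Mb/1C)"
        )


if __name__ == "__main__":
    main()
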