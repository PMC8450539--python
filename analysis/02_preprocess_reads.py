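"""Filter reads (full-length Q20, organelle removal) and down-sample.

Reproduces the read-preparation chain: pairs with any base below Q20
are dropped, reads matching the plastid/mitochondrial references are
removed, and the nuclear survivors are down-sampled to 1.5% (individual
clustering) and 1.3% (comparative clustering) of each genome.
"""

import json

from _common import load_config, parse_args
from skimrepeats.pipeline import run_pipeline


def main():
    args = parse_args(__doc__)
    cfg = load_config(args)
    run_pipeline(cfg, stages=["preprocess"])
    log = json.load(open(f"{cfg.outdir}/preprocess_log.json"))
    for code, stats in log.items():
        print(
            f"{code}: {stats['raw_pairs']} raw pairs -> "
            f"{stats['quality_pass_pairs']} after Q20 -> "
            f"{stats['nuclear_pairs']} nuclear; sampled "
            f"{stats['individual_reads']} (individual) / "
            f"{stats['comparative_reads']} (comparative) reads"
        )


if __name__ == "__main__":
    main()
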