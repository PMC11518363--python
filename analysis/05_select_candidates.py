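#!/usr/bin/env python
"""Select candidate miRNAs by joining enrichment with prediction consensus.

Applies the significance (p <= 0.05) and |ES| >= 0.25 report filters, maps
every miRNA in a retained set against the two-tool WWOX target-prediction
consensus (base-name matching links hairpin set members to mature-arm
evidence), and writes the ordered candidate table.
"""

import argparse

import pandas as pd

import mirsea as ms
from mirsea.pipeline import stage_select


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="results/pipeline")
    args = parser.parse_args()

    cfg = ms.PipelineConfig(out_dir=args.out_dir)
    paths = stage_select(cfg)
    candidates = pd.read_csv(paths["candidates"], sep="\t")
    predicted = candidates[candidates["predicted_regulator"]]
    print(f"{len(candidates)} miRNAs occur in retained enriched sets; "
          f"{len(predicted)} are consensus-predicted WWOX regulators:")
    print(predicted.to_string(index=False))
    print(f"wrote candidates -> {paths['candidates']}")


if __name__ == "__main__":
    main()
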