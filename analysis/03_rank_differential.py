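#!/usr/bin/env python
"""Rank miRNAs by differential expression between the two conditions.

Scores every miRNA by the log2 fold change of condition means on the
relative-expression scale (WWOX-sufficient over WWOX-deficient) and writes
the descending ranked list that feeds the enrichment statistic.
"""

import argparse

import mirsea as ms
from mirsea.pipeline import stage_rank
from mirsea.ranking import RankedList


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="results/pipeline")
    args = parser.parse_args()

    cfg = ms.PipelineConfig(out_dir=args.out_dir)
    paths = stage_rank(cfg)
    ranked = RankedList.read(paths["ranked"])
    print(f"ranked {ranked.N} miRNAs; top of the list (up in WWOX-sufficient):")
    for name, score in zip(ranked.names[:5], ranked.scores[:5]):
        print(f"  {name}: {score:+.3f}")
    print("bottom of the list (up in WWOX-deficient):")
    for name, score in zip(ranked.names[-5:], ranked.scores[-5:]):
        print(f"  {name}: {score:+.3f}")
    print(f"wrote ranked -> {paths['ranked']}")


if __name__ == "__main__":
    main()
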