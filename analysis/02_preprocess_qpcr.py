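#!/usr/bin/env python
"""Call Cq values, calibrate plates, QC spike-ins and normalize to 2^-dCq.

Reads the raw curves from results/pipeline/, fits the four-parameter
logistic SDM caller to every well, removes the per-plate offsets using the
interplate calibrators, screens the spike-in controls, and writes the
reference-gene-normalized relative-expression matrix.
"""

import argparse

import pandas as pd

import mirsea as ms
from mirsea.pipeline import stage_preprocess


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", default="results/pipeline")
    args = parser.parse_args()

    cfg = ms.PipelineConfig(out_dir=args.out_dir)
    paths = stage_preprocess(cfg)

    cq = pd.read_csv(paths["cq_records"], sep="\t")
    qc = pd.read_csv(paths["spike_qc"], sep="\t")
    expr = pd.read_csv(paths["expression"], sep="\t", index_col="mirna")
    n_undet = int(cq["cq"].isna().sum())
    n_blank_undet = int((cq["cq"].isna() & (cq["well_class"] == "blank")).sum())
    print(f"called Cq for {len(cq)} wells; {n_undet} undetermined "
          f"({n_blank_undet} of them blank wells)")
    print(f"spike-in QC: {int(qc['passed'].sum())}/{len(qc)} samples pass")
    print(f"expression matrix: {expr.shape[0]} miRNAs x {expr.shape[1]} samples")
    for key, path in paths.items():
        print(f"wrote {key} -> {path}")


if __name__ == "__main__":
    main()
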