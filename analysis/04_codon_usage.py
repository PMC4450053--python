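#!/usr/bin/env python
"""Evaluate optimal-codon recovery and the Fop/Fnop contrasts.

The simulator plants a known optimal-codon profile in ribosomal-protein
families; this script compares the set recovered by the RP chi-squared
method (02_run_pipeline.py output) against that ground truth and summarises
the codon-class contrasts. Writes results/codon_recovery.tsv.
"""

from pathlib import Path

import pandas as pd
import yaml

ROOT = Path(__file__).resolve().parents[1]


def evaluate(name: str) -> pd.DataFrame:
    inferred = pd.read_csv(ROOT / "results" / "pipeline" / name / "optimal_codons.tsv", sep="\t")
    with open(ROOT / "scratch" / "datasets" / name / "config.yml") as fh:
        planted = yaml.safe_load(fh)["optimal_codons"]
    inferred["condition"] = name
    inferred["planted_optimal"] = inferred.codon.map(
        lambda c: c in set(planted.values())
    )
    return inferred


def main() -> None:
    rows = []
    for name in ("biased", "unbiased"):
        df = evaluate(name)
        tested = df[df.label != "excluded"]
        called = tested[tested.label == "optimal"]
        tp = int(called.planted_optimal.sum())
        fp = len(called) - tp
        planted_testable = int(tested.planted_optimal.sum())
        print(
            f"{name}: {len(called)} codons called optimal "
            f"({tp} of {planted_testable} planted recovered, {fp} false calls)"
        )
        rows.append(df)
    out = ROOT / "results" / "codon_recovery.tsv"
    pd.concat(rows, ignore_index=True).to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
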