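#!/usr/bin/env python
"""Differential expression and the fold-change/p signature.

Median-of-ratios normalization, Welch t on log2 counts for tumor vs
reference, then the signature filter (>2.0-fold, p < 0.05). Reports how
much of the planted differential signal the filter recovers.
"""

import argparse
import json
from pathlib import Path

from diffnet.expression import de_test, filter_signature, normalize_counts
from diffnet.io import read_expression

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()
    inputs = args.study / "inputs"

    m = read_expression(inputs / "expression.tsv", inputs / "conditions.tsv")
    norm = normalize_counts(m)
    ref, case = m.conditions[0], m.conditions[1]
    res = de_test(norm, ref, case)
    res.to_csv(args.study / "de_table.tsv", sep="\t")
    signature = filter_signature(res)
    (args.study / "signature.txt").write_text("\n".join(signature) + "\n")

    truth = json.loads((inputs / "ground_truth.json").read_text())
    planted = set(truth["de_gene_ids"])
    recovered = len(set(signature) & planted)
    print(f"{len(signature)} signature genes "
          f"(|log2FC| > 1 and p < 0.05, {case} vs {ref})")
    print(f"planted DE recovery: {recovered}/{len(planted)} "
          f"({100 * recovered / len(planted):.1f}%)")
    fp = len(set(signature) - planted)
    print(f"false positives in signature: {fp}")


if __name__ == "__main__":
    main()
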