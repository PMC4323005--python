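#!/usr/bin/env python
"""Tumor-initiating-cell frequency from limiting-dilution experiments.

Single-hit maximum-likelihood estimates with profile-likelihood intervals
for the case and reference experiments, the frequency fold change, and a
likelihood-ratio test of the equal-frequency null.
"""

import argparse
import json
from pathlib import Path

from diffnet.io import read_lda
from diffnet.lda import compare_frequencies, estimate_frequency

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = ap.parse_args()
    inputs = args.study / "inputs"
    truth = json.loads((inputs / "ground_truth.json").read_text())

    case = read_lda(inputs / "lda_case.tsv")
    ref = read_lda(inputs / "lda_reference.tsv")
    est_case, est_ref = estimate_frequency(case), estimate_frequency(ref)
    comp = compare_frequencies(case, ref)

    f_true_case, f_true_ref = truth["lda_frequencies"]
    print(f"case:      f = {est_case.frequency:.3e} "
          f"[{est_case.ci_low:.3e}, {est_case.ci_high:.3e}] "
          f"(true {f_true_case:g}, flag {est_case.boundary_flag})")
    print(f"reference: f = {est_ref.frequency:.3e} "
          f"[{est_ref.ci_low:.3e}, {est_ref.ci_high:.3e}] "
          f"(true {f_true_ref:g}, flag {est_ref.boundary_flag})")
    bound = " (lower bound)" if comp.fold_is_lower_bound else ""
    print(f"fold increase: {comp.fold:.1f}{bound} "
          f"(true {f_true_case / f_true_ref:.0f}), "
          f"LR test p = {comp.p_value:.2e}")

    with open(args.study / "tic_frequency.json", "w") as fh:
        json.dump({
            "case": est_case.__dict__, "reference": est_ref.__dict__,
            "fold": comp.fold, "p_equal": comp.p_value,
            "fold_is_lower_bound": comp.fold_is_lower_bound,
        }, fh, indent=2)


if __name__ == "__main__":
    main()
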