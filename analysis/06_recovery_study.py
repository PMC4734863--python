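#!/usr/bin/env python
"""Replicated simulation study: REML recovery and BIC order selection.

Twenty synthetic herd-books (500 cows, 25 half-sib families, ~3,000
records) are generated under a known order-2 truth and refitted; the
replicate-mean estimates are compared to the truth on the Monte-Carlo
standard-error scale, and BIC(2,2) is compared with BIC(1,1).

Writes results/recovery_summary.tsv.  Takes a couple of minutes.
"""
from pathlib import Path
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from rrtdm.study import recovery_study  # noqa: E402

res = recovery_study()    # 20 replicates at the default study seed
summary = res.summary_frame()
summary.to_csv(ROOT / "results" / "recovery_summary.tsv", sep="\t",
               index=False, float_format="%.4f")
print(summary.to_string(index=False))
print(f"\nmax |z| over {summary.shape[0]} free parameters: "
      f"{summary['z'].abs().max():.2f}")
print(f"BIC prefers the generating order (2,2) over (1,1) in "
      f"{int((res.bic_true_order < res.bic_low_order).sum())}/20 replicates")
print(f"all likelihood paths monotone: {res.paths_monotone()}")
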