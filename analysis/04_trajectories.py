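#!/usr/bin/env python
"""Variance, heritability and correlation trajectories per group.

Evaluates the fitted covariance functions at the residual-class midpoints
(variances, h², repeatability) and on the standard reporting DIM grid
(genetic below / phenotypic above diagonal correlations).

Writes results/trajectories/<group>/{trajectories.tsv,correlations.tsv}
and a combined whole-lactation summary.
"""
from pathlib import Path
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from rrtdm.basis import BasisSpec                              # noqa: E402
from rrtdm.reml import FitResult                               # noqa: E402
from rrtdm.trajectories import (                               # noqa: E402
    correlation_surface, lactation_summary, trajectory_table,
)

res = ROOT / "results"
rows = []
for fit_file in sorted((res / "selection").glob("*/best_fit.json")):
    group = fit_file.parent.name
    vc = FitResult.variance_components_from_json(fit_file.read_text())
    ba = BasisSpec(vc.ka)
    bpe = BasisSpec(vc.kpe) if vc.kpe else None
    out = res / "trajectories" / group
    out.mkdir(parents=True, exist_ok=True)
    tab = trajectory_table(vc, ba, bpe)
    tab.to_csv(out / "trajectories.tsv", sep="\t", index=False, float_format="%.3f")
    surf = correlation_surface(vc, ba, bpe)
    surf.to_frame().to_csv(out / "correlations.tsv", sep="\t", float_format="%.3f")
    summ = lactation_summary(vc, ba, bpe)
    rows.append(dict(group=group, **summ))
    mid = tab.iloc[4]
    print(f"{group}: mid-lactation h2={mid['h2']:.2f}, "
          f"daily-mean h2={summ['h2']:.2f}, repeatability={summ['repeatability']:.2f}")

pd.DataFrame(rows).to_csv(res / "lactation_summary.tsv", sep="\t",
                          index=False, float_format="%.3f")
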