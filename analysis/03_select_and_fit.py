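#!/usr/bin/env python
"""Select Q-function terms and fit the optimal regime.

Stage-2 terms first, then stage-1 terms given them, by forward stepwise
search on the BIC averaged over the imputed datasets; then backward-
induction Q-learning on each imputed dataset.  The decision rule is the
argmin of the imputation-averaged Q-functions.  Writes the term sets,
per-imputation and averaged coefficients, and prints a text rendering of
the fitted rules.
"""

from pathlib import Path

import numpy as np
import yaml

from radq.datamodel import Cohort
from radq.model_selection import select_models
from radq.qlearning import fit_regime

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohorts = [Cohort.from_csv(p)
               for p in sorted((RESULTS / "imputed").glob("imp_*.csv"))]
    print(f"loaded m={len(cohorts)} imputed datasets")

    s2, s1, trace = select_models(cohorts)
    print("selected stage-2 terms:", dict(h20=list(s2.h20),
                                          h21=list(s2.h21)))
    print("selected stage-1 terms:", dict(h10=list(s1.h10),
                                          h11=list(s1.h11),
                                          h12=list(s1.h12)))

    regime = fit_regime(cohorts, s2, s1)
    avg2 = {k: float(np.mean([m.coefficients[k]
                              for m in regime.stage2_models]))
            for k in regime.stage2_models[0].coefficients}
    avg1 = {k: float(np.mean([m.coefficients[k]
                              for m in regime.stage1_models]))
            for k in regime.stage1_models[0].coefficients}

    (RESULTS / "qfit.yaml").write_text(yaml.safe_dump({
        "stage2_terms": {"h20": list(s2.h20), "h21": list(s2.h21)},
        "stage1_terms": {"h10": list(s1.h10), "h11": list(s1.h11),
                         "h12": list(s1.h12)},
        "averaged_coefficients": {"stage2": avg2, "stage1": avg1},
        "per_imputation": {
            "stage2": [m.coefficients for m in regime.stage2_models],
            "stage1": [m.coefficients for m in regime.stage1_models]},
        "selection_trace": trace,
    }, sort_keys=False))

    print("\naveraged stage-2 coefficients:")
    for k, v in avg2.items():
        print(f"  {k:>14}: {v:7.3f}")
    contrast = " + ".join(f"{avg2[k]:+.3f}*{k.split(':', 1)[1]}"
                          if ":" in k else f"{avg2[k]:+.3f}"
                          for k in avg2 if k.startswith("A2"))
    print("\nstage-2 rule: high-dose Bupropion iff", contrast, "< 0")
    print("stage-1 rule: argmin over {placebo, Bupropion, Paroxetine} of "
          "the averaged Q1")
    print(f"\nwrote {RESULTS/'qfit.yaml'}")


if __name__ == "__main__":
    main()
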