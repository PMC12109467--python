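#!/usr/bin/env python
"""KNN sensitivity: how the headline models depend on k and scaling.

Sweeps the neighbor count k (with both vote-tie rules) and the feature
scaling choice for the two headline variable sets under LTOCV, plain and
PCA routes, and writes results/knn_sensitivity.csv.

Finding: the printed plain-variable accuracies are reproduced only by
k=2 with min-max scaled features and the strict-majority (tie -> NO)
decision rule, while the PCA route and LOOCV behave like k=1 — consistent
with a source analysis that auto-tuned the neighbor count per training
configuration. Accuracy degrades steeply for k >= 3 because every
training set contains at most three thrombosis recordings.
"""

from pathlib import Path

import pandas as pd

from hvad_acoustics.cohort import load_embedded_cohort
from hvad_acoustics.ml import (STUDY_PCA, ClassifierSpec, CVScheme, run_cv)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    _, profiles = load_embedded_cohort()
    scheme = CVScheme("ltocv", len(profiles))
    rows = []
    for variables in (("P_FF", "P_2H"), ("P_FF", "P_2H", "P_3H")):
        for k in (1, 2, 3, 5):
            for tie in ("nearest", "negative"):
                if k % 2 and tie == "negative":
                    continue  # odd k cannot tie
                for scaling in (None, "minmax", "standardize"):
                    for route, pca in (("plain", None), ("pca", STUDY_PCA)):
                        spec = ClassifierSpec(
                            "knn", {"k": k, "tie_break": tie},
                            scaling=None if route == "pca" else scaling)
                        if route == "pca" and scaling is not None:
                            continue
                        run = run_cv(profiles, variables, spec, scheme, pca=pca)
                        rows.append({
                            "variables": "+".join(variables), "route": route,
                            "k": k, "tie_break": tie, "scaling": scaling,
                            "accuracy_percent": run.accuracy_percent,
                            "fn": run.confusion.fn, "fp": run.confusion.fp})
    frame = pd.DataFrame(rows).drop_duplicates()
    OUT.mkdir(exist_ok=True)
    path = OUT / "knn_sensitivity.csv"
    frame.to_csv(path, index=False)
    print(f"wrote {path} ({len(frame)} configurations)")
    best = frame.sort_values("accuracy_percent", ascending=False).head(8)
    print(best.to_string(index=False))


if __name__ == "__main__":
    main()
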