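#!/usr/bin/env python
"""End-to-end validation of the spectral chain on synthetic recordings.

Synthesizes a pump-like acceleration signal carrying the HW-A harmonic
signature (fundamental 42.67 Hz, 12 harmonics, -40 dB white noise floor,
60 s at 6 kHz), runs it through the PSD -> harmonic power -> 0 dB
normalization chain, and reports the per-harmonic recovery error; then
exercises the CV engine on a cohort generator that reproduces the
clinical cohort's geometry (3-recording thrombosis cluster, two
non-thrombotic "confuser" rows beside it).

Finding: the signature is recovered within a few hundredths of a dB for
the strong harmonics and a few tenths for the deepest ones, and the
synthetic confuser pair reproduces the [HW-B, HW-G] failure mechanism:
held out together they are the only LTOCV errors, while LOOCV is perfect.

Writes results/synthetic_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hvad_acoustics.cohort import HARMONIC_COLUMNS, load_embedded_cohort
from hvad_acoustics.ml import ClassifierSpec, CVScheme, run_cv
from hvad_acoustics.spectral import extract_profile, normalize_profile
from hvad_acoustics.synthetic import (SyntheticSignalSpec, generate_recording,
                                      studylike_cohort)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    _, profiles = load_embedded_cohort()
    hw_a = next(p for p in profiles if p.patient_id == "HW-A")
    spec = SyntheticSignalSpec(ff=42.67, harmonic_db=hw_a.power_db,
                               noise_db=-40.0, duration=60.0,
                               patient_id="synthetic-HW-A")
    rec = generate_recording(spec)
    got = np.asarray(extract_profile(rec, ff=42.67).power_db)
    target = normalize_profile(hw_a.power_db)
    table = pd.DataFrame({"variable": HARMONIC_COLUMNS, "target_db": target,
                          "recovered_db": got, "error_db": got - target})
    OUT.mkdir(exist_ok=True)
    path = OUT / "synthetic_recovery.csv"
    table.to_csv(path, index=False, float_format="%.4f")
    print(f"wrote {path}")
    print(table.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))
    print(f"max |error| = {np.abs(table['error_db']).max():.3f} dB")

    rows = studylike_cohort(seed=0)
    knn1 = ClassifierSpec("knn", {"k": 1})
    l2 = run_cv(rows, ("P_FF", "P_2H", "P_3H"), knn1, CVScheme("ltocv", 11))
    l1 = run_cv(rows, ("P_FF", "P_2H", "P_3H"), knn1, CVScheme("loocv", 11))
    print(f"\nsynthetic cohort: LTOCV {l2.accuracy_percent}% "
          f"(errors: {sorted({e.validation_ids for e in l2.errors})}), "
          f"LOOCV {l1.accuracy_percent}%")


if __name__ == "__main__":
    main()
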