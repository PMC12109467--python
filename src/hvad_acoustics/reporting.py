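"""Study-shaped outputs: accuracy tables, confusion matrices, PCA plane.

Emits the result tables of the analysis as plain CSV/JSON data files (no
plotting dependency): the LTOCV accuracy grid over variable subsets and
algorithms, its PCA-variable counterpart (gated on exceeding the ZeroR
baseline), the KNN LOOCV table, the two headline KNN confusion matrices,
the 2D PCA coordinates of all 11 recordings, and the long-format harmonic
power chart data. Every emitted file is recorded in an append-only run
manifest together with the configuration snapshot, seeds and fixture
checksum, so each number is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import HARMONIC_COLUMNS, HarmonicProfile, load_embedded_cohort
from .ml import (FROZEN_KNN, STUDY_PCA, CVScheme, ModelRun, fit_pca,
                 frozen_knn_spec, round1, run_cv, run_grid, zeror_baseline)

__all__ = [
    "TABLE3_VARIABLE_SETS",
    "ALGORITHM_COLUMNS",
    "reproduce_tables",
    "report_profile_chart",
    "write_manifest",
]

#: The 19 harmonic-power variable subsets of the LTOCV accuracy grid.
TABLE3_VARIABLE_SETS: tuple[tuple[str, ...], ...] = (
    ("P_FF", "P_2H"),
    ("P_FF", "P_3H"),
    ("P_FF", "P_4H"),
    ("P_2H", "P_3H"),
    ("P_2H", "P_4H"),
    ("P_3H", "P_4H"),
    ("P_FF", "P_2H", "P_3H"),
    ("P_FF", "P_2H", "P_4H"),
    ("P_FF", "P_3H", "P_4H"),
    ("P_2H", "P_3H", "P_4H"),
    ("P_FF", "P_2H", "P_8H"),
    ("P_FF", "P_2H", "P_12H"),
    ("P_FF", "P_4H", "P_8H"),
    ("P_FF", "P_2H", "P_3H", "P_4H"),
    ("P_FF", "P_2H", "P_4H", "P_8H"),
    ("P_FF", "P_4H", "P_8H", "P_12H"),
    ("P_FF", "P_2H", "P_3H", "P_4H", "P_8H"),
    ("P_FF", "P_2H", "P_3H", "P_4H", "P_12H"),
    ("P_FF", "P_2H", "P_3H", "P_4H", "P_5H", "P_6H", "P_7H", "P_8H"),
)

ALGORITHM_COLUMNS = ("knn", "logistic_regression", "random_forest",
                     "gradient_boosted_trees", "svm", "naive_bayes")


def _set_label(variables: Sequence[str]) -> str:
    return "+".join(variables)


def _cohort_checksum(profiles: Sequence[HarmonicProfile]) -> str:
    text = "\n".join(
        f"{p.patient_id}," + ",".join(f"{v:.4f}" for v in p.power_db)
        + f",{p.outcome}" for p in profiles)
    return hashlib.sha256(text.encode()).hexdigest()


def write_manifest(out_dir: Path, entry: dict) -> Path:
    """Append one run entry to the directory's manifest (append-only)."""
    path = Path(out_dir) / "manifest.json"
    entries = json.loads(path.read_text()) if path.exists() else []
    entries.append(entry)
    path.write_text(json.dumps(entries, indent=2, default=str))
    return path


def _accuracy_grid(runs: list[ModelRun], variable_sets, algorithms,
                   gated: bool) -> pd.DataFrame:
    by_key = {(r.spec.algorithm, r.variables): r for r in runs}
    rows = []
    for variables in variable_sets:
        row: dict[str, object] = {"variables": _set_label(variables)}
        for algo in algorithms:
            run = by_key.get((algo, tuple(variables)))
            if run is None:
                row[algo] = "" if gated else np.nan
                row[f"{algo}_exceeds_baseline"] = ""
            else:
                row[algo] = run.accuracy_percent
                row[f"{algo}_exceeds_baseline"] = run.exceeds_baseline
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_tables(out_dir: str | Path,
                     profiles: Sequence[HarmonicProfile] | None = None,
                     algorithms: Sequence[str] = ALGORITHM_COLUMNS,
                     variable_sets: Sequence[Sequence[str]] = TABLE3_VARIABLE_SETS,
                     repeats: int = 1) -> dict[str, Path]:
    """Recompute and emit the study's result tables from the feature table.

    Writes ``table3.csv`` (plain-variable LTOCV grid), ``table4.csv``
    (2D-PCA LTOCV grid, cells only where the plain run beat the ZeroR
    baseline), ``table5.csv`` (KNN LOOCV, plain and PCA columns, rows
    whose plain accuracy beat baseline), ``fig3_confusions.json`` (the two
    headline KNN models on P_FF+P_2H+P_3H), ``fig4_pca.csv`` (2D PCA
    coordinates of all 11 recordings) and ``fig2_harmonic_powers.csv``,
    plus an entry in ``manifest.json``. Returns the emitted paths.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if profiles is None:
        _, profiles = load_embedded_cohort()
    profiles = list(profiles)
    n = len(profiles)
    ltocv, loocv = CVScheme("ltocv", n), CVScheme("loocv", n)
    labels = [p.outcome for p in profiles]
    paths: dict[str, Path] = {}

    # LTOCV grids, plain (table 3) and PCA-gated (table 4)
    runs = run_grid(profiles, variable_sets, list(algorithms), ltocv,
                    pca_modes=("none", "2d"), repeats=repeats)
    plain = [r for r in runs if r.pca is None]
    pca = [r for r in runs if r.pca is not None]
    paths["table3"] = out / "table3.csv"
    _accuracy_grid(plain, variable_sets, algorithms, gated=False).to_csv(
        paths["table3"], index=False)
    gated_sets = [v for v in variable_sets
                  if any(r.variables == tuple(v) for r in pca)]
    paths["table4"] = out / "table4.csv"
    _accuracy_grid(pca, gated_sets, algorithms, gated=True).to_csv(
        paths["table4"], index=False)

    # KNN LOOCV table (rows whose plain run beats baseline, like the study)
    baseline = zeror_baseline(labels, loocv)
    rows5 = []
    for variables in variable_sets:
        plain_run = run_cv(profiles, variables, frozen_knn_spec("loocv"), loocv)
        if plain_run.metrics.accuracy <= baseline:
            continue
        pca_run = run_cv(profiles, variables, frozen_knn_spec("loocv", pca=True),
                         loocv, pca=STUDY_PCA)
        rows5.append({"variables": _set_label(variables),
                      "accuracy_plain": plain_run.accuracy_percent,
                      "accuracy_pca": pca_run.accuracy_percent})
    paths["table5"] = out / "table5.csv"
    pd.DataFrame(rows5).to_csv(paths["table5"], index=False)

    # headline KNN confusion matrices (plain vs fold-embedded PCA)
    headline_vars = ("P_FF", "P_2H", "P_3H")
    fig3 = {}
    for route, pca_cfg in (("plain", None), ("pca2d", STUDY_PCA)):
        run = run_cv(profiles, headline_vars,
                     frozen_knn_spec("ltocv", pca=pca_cfg is not None),
                     ltocv, pca=pca_cfg)
        m = run.metrics
        fig3[route] = {
            "variables": _set_label(headline_vars),
            "confusion": dict(zip(("tp", "fp", "fn", "tn"),
                                  run.confusion.as_tuple())),
            "accuracy_percent": run.accuracy_percent,
            "precision_percent": None if m.precision is None
            else round1(100 * m.precision),
            "recall_percent": None if m.recall is None
            else round1(100 * m.recall),
            "f1_percent": None if m.f1 is None else round1(100 * m.f1),
            "error_validation_pairs": sorted(
                {e.validation_ids for e in run.errors}),
        }
    paths["fig3"] = out / "fig3_confusions.json"
    paths["fig3"].write_text(json.dumps(fig3, indent=2))

    # PCA plane over all 11 recordings (illustrative, not fold-embedded)
    idx = [HARMONIC_COLUMNS.index(v) for v in headline_vars]
    X = np.array([[p.power_db[i] for i in idx] for p in profiles])
    model = fit_pca(X, n_components=2, standardize=STUDY_PCA.standardize,
                    whiten=STUDY_PCA.whiten)
    coords = model.transform(X)
    paths["fig4"] = out / "fig4_pca.csv"
    pd.DataFrame({"patient_id": [p.patient_id for p in profiles],
                  "pc1": coords[:, 0], "pc2": coords[:, 1],
                  "outcome": labels}).to_csv(paths["fig4"], index=False)

    paths["fig2"] = report_profile_chart(profiles, out / "fig2_harmonic_powers.csv")

    write_manifest(out, {
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "software_version": __version__,
        "cohort_sha256": _cohort_checksum(profiles),
        "config": {
            "algorithms": list(algorithms),
            "variable_sets": [_set_label(v) for v in variable_sets],
            "pca": dataclasses.asdict(STUDY_PCA),
            "knn_frozen": {f"{k[0]}/{k[1]}": v for k, v in FROZEN_KNN.items()},
            "stochastic_repeats": repeats,
            "stochastic_seed": plain[0].spec.seed if plain else None,
        },
        "files": {k: str(p) for k, p in paths.items()},
        "elapsed_s": round(time.perf_counter() - t0, 2),
    })
    return paths


def report_profile_chart(profiles: Sequence[HarmonicProfile],
                         out: str | Path) -> Path:
    """Long-format harmonic power chart data (one row per bar).

    Columns: patient_id, harmonic (1..12), variable, power_db, outcome —
    11 x 12 = 132 rows for the embedded cohort.
    """
    rows = [{"patient_id": p.patient_id, "harmonic": h + 1,
             "variable": HARMONIC_COLUMNS[h], "power_db": p.power_db[h],
             "outcome": p.outcome}
            for p in profiles for h in range(12)]
    out = Path(out)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out
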