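"""SURG-TLX skill classification from approximate-entropy features.

Reduces each trial's eleven time-series channels to ApEn features,
binarizes the six questionnaire targets against their cohort means, and
grid-searches the four-classifier battery under stratified 5- and 10-fold
cross-validation.  Writes results/cv_records.csv and
results/accuracy_matrix.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from surgstress.classification import (
    TLX_QUESTIONS,
    accuracy_matrix,
    binarize_target,
    build_feature_matrix,
    classification_report,
)
from surgstress.cohort import CohortSpec, generate_cohort
from surgstress.io import read_manifest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1234)
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--schemes", type=int, nargs="+", default=[5, 10],
                    help="k-fold splits to evaluate")
    args = ap.parse_args()

    manifest = args.cohort / "manifest.yaml"
    if manifest.exists():
        trials = read_manifest(manifest)
    else:
        trials = generate_cohort(CohortSpec(seed=args.seed))[0]

    features, dropped = build_feature_matrix(trials)
    if dropped:
        print(f"dropped trials missing channels: {', '.join(dropped)}")
    kept = [t for t in trials if f"{t.subject_id}/task{t.task_id}" in features.index]
    targets = pd.DataFrame(
        {q: binarize_target([t.tlx.as_metrics()[q] for t in kept])
         for q in TLX_QUESTIONS},
        index=features.index,
    )

    records = classification_report(features, targets, schemes=tuple(args.schemes))
    matrix = accuracy_matrix(records)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    records.drop(columns=["best_params"]).to_csv(results / "cv_records.csv", index=False)
    matrix.to_csv(results / "accuracy_matrix.csv", index_label="target")

    print(f"{len(features)} trials, {features.shape[1]} ApEn features")
    print("best accuracy per question x classifier (scheme:accuracy):")
    print(matrix.to_string())
    best = records.loc[records.groupby("target")["accuracy"].idxmax()]
    print("\nbest classifier per question:")
    print(best[["target", "classifier", "scheme", "accuracy"]]
          .round(6).to_string(index=False))


if __name__ == "__main__":
    main()
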