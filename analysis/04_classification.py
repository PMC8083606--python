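#!/usr/bin/env python
"""LDA classification of smell group from subtest features.

For each pairwise contrast (anosmic vs normosmic, other vs normosmic,
anosmic vs other): repeated stratified 10-fold x 5 cross-validation on an 80%
training split, final metrics on the withheld 20%, single-subtest ROC AUCs,
and greedy backward feature selection.  The second identification attempt is
excluded (structurally missing after a correct first attempt).

Writes results/classification.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

from scentinel.discriminate import (
    backward_feature_selection,
    cv_evaluate,
    one_hot,
    roc_auc,
)
from scentinel.io import read_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42
CONTRASTS = [("anosmic", "normosmic"), ("other", "normosmic"), ("anosmic", "other")]


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    report = {}
    for neg, pos in CONTRASTS:
        key = f"{neg}_vs_{pos}"
        fm = one_hot(cohort, (neg, pos))
        cv = cv_evaluate(fm, seed=SEED)
        single = {
            feat: roc_auc(fm.X[feat].to_numpy(float), fm.y).auc
            for feat in ("detection", "intensity", "id_first")
        }
        selection = backward_feature_selection(fm, seed=SEED)
        report[key] = {
            "holdout": asdict(cv),
            "single_feature_auc": single,
            "selection_path": [
                {"k": len(h["features"]), "cv_auc": h["cv_auc"],
                 "eliminated_next": h["eliminated_next"]}
                for h in selection
            ],
        }
        best_single = max(single, key=single.get)
        print(f"{key}: holdout AUC {cv.auc:.3f} "
              f"(CV {cv.cv_auc_mean:.3f}+-{cv.cv_auc_sd:.3f}); "
              f"sens {cv.sensitivity:.2f} spec {cv.specificity:.2f}; "
              f"best single subtest {best_single} "
              f"(AUC {single[best_single]:.3f})")

    (OUT / "classification.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT / 'classification.json'}")


if __name__ == "__main__":
    main()
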