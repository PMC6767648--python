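"""Train on one part of a cohort, then predict held-out individuals — with a
planted batch effect that the per-individual ComBat adjustment removes.

Run: python examples/03_train_and_predict.py  (about a minute)
"""

from avadx import (CohortConfig, PipelineConfig, filter_training_variants,
                   generate_cohort, plant_batch_shift, roc_auc,
                   run_predict_panel, run_train)
from avadx.cohort import restrict_test_variants

cohort = generate_cohort(CohortConfig(seed=31, n_cases=80, n_controls=80))
train_cohort, test_cohort = cohort.split(n_test_cases=20, n_test_controls=20)

# family-aware LOOCV with in-fold feature selection, then a fixed top-125
# gene set selected on the whole training panel
artifacts = run_train(filter_training_variants(train_cohort.to_panel()),
                      PipelineConfig(cv_repeats=2, seed=1))
print(f"cross-validated ROC AUC: {artifacts.cv.roc_aucs.mean():.3f}")


def predict(cohort_part, label):
    panel = cohort_part.to_panel()
    panel = panel.subset_variants(
        (panel.variants["filter_status"] == "PASS").to_numpy())
    # a test panel may only contribute loci seen in training
    panel = restrict_test_variants(panel, artifacts.train_loci)
    # one batch adjustment + one fresh model per test individual
    preds = run_predict_panel(artifacts, panel, seed=2)
    truth = panel.individuals["status"].loc[preds.index]
    print(f"{label}: ROC AUC {roc_auc(preds['score'], truth):.3f}, "
          f"calls at default cutoff: {preds['default'].value_counts().to_dict()}")


predict(test_cohort, "clean test panel")

# simulate the test panel coming from a different sequencing batch
shifted = plant_batch_shift(test_cohort, shift=2.0, affected_fraction=0.3,
                            seed=3)
predict(shifted, "batch-shifted test panel (adjusted)")
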