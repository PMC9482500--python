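"""Nested cross-validated SVM evaluation, plus published-table arithmetic.

Runs stratified 5-fold CV with gene selection nested inside each training
fold, reports the confusion-derived metrics as percentages, and shows the
comparison arithmetic used for published per-method metric tables.
"""

from batsel import (
    compare_reports,
    cross_validate,
    generate_dataset,
    ibo_select,
    mean_tpr,
    report_from_percent_metrics,
)

x, y, _ = generate_dataset(n_genes=100, n_samples=60, n_informative=8,
                           effect_size=1.5, seed=3)


def selector(G, y_train, fold_seed):
    return ibo_select(G, y_train, k=8, seed=fold_seed).mask


report = cross_validate(x, y, selector=selector, folds=5, seed=3)
print("nested-CV metrics (%):", report.as_percent())
print(f"mean TPR over tabulated ROC points: {100 * report.mean_tpr:.1f}%, "
      f"trapezoidal AUC: {report.auc:.3f}")

# comparison arithmetic on published percent metrics of two baselines
reports = {
    "proposed": report_from_percent_metrics(91.59, 90.66, 91.13, 90.5, 91.56),
    "dca": report_from_percent_metrics(89.75, 70.0, 80.92, 69.45, 83.50),
}
print("gain over the weaker baseline (percentage points):")
print(compare_reports(reports, reference="proposed"))
dca_roc = [(0.02, 0.72), (0.04, 0.76), (0.06, 0.77), (0.08, 0.783), (1.0, 0.790)]
print(f"baseline mean tabulated TPR: {100 * mean_tpr(dca_roc):.1f}%")
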