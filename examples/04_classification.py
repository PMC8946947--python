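"""Small end-to-end classification run: phantoms -> features -> RBF-SVM.

Generates a reduced MSA-P/PD phantom cohort, extracts putaminal features
from the truth masks, and runs the repeated-split evaluation harness with
Fisher top-10 selection (a scaled-down version of the full protocol).
"""

import pandas as pd

from ironmap import PhantomSpec, extract_all, generate_cohort, run_task
from ironmap.feature_selection import FeatureTable

cohort = generate_cohort({"MSA-P": 15, "PD": 20}, PhantomSpec(), master_seed=7)

rows = {}
labels = {}
for i, s in enumerate(cohort):
    sid = f"sub-{i:03d}"
    labels[sid] = s.class_name
    rows[sid] = extract_all(s.swi, s.truth, "putamen").texture_safe().to_series()
label_series = pd.Series(labels, name="class")
table = FeatureTable(pd.DataFrame(rows).T.loc[label_series.index], label_series)

reports = run_task(
    table, ("MSA-P", "PD"), classifiers=("RBFSVC", "GNB"),
    n_repeats=10, k_features=10, master_seed=1,
)
for name, rep in reports.items():
    print(
        f"{name:7s} test AUC {rep.mean('test', 'AUC'):.3f}  "
        f"bAcc {rep.mean('test', 'bAcc'):.3f}  "
        f"Sen {rep.mean('test', 'Sen'):.3f}  Spe {rep.mean('test', 'Spe'):.3f}"
    )
print()
print("Each repeat draws a stratified 7:3 split, selects the Fisher top-10")
print("features on the training rows only, tunes by 3-fold cross-validation,")
print("and scores the held-out subjects; the numbers are means over repeats.")
print("AUC near 0.9 reflects the controlled class overlap of the phantoms.")
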