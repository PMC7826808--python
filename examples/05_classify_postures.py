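"""Classify sitting postures from three regional pressure features.

For each image the pipeline localizes the hips, then sums the normalized
pressure over discs at the left hip (r=7), right hip (r=7) and caudal
vertebra (r=3).  Those three weight fractions feed one-vs-rest SVMs;
here the polynomial kernel at its canonical parameters (C=1.3, beta=1.4,
theta=0.8, degree=3) is evaluated with 5-fold cross-validation.
"""

from sitmap import (SVMConfig, build_bank, cross_validate, features_from_samples,
                    generate_dataset)

samples = generate_dataset(3, subjects=4, seed=7)    # 4 x 4 x 4 x 3 = 192 images
bank = build_bank()
X, y = features_from_samples(samples, bank=bank)
print(f"{len(samples)} images -> feature matrix {X.shape}")

res = cross_validate(X, y, SVMConfig(kernel="polynomial"), folds=5, seed=0)
print(f"fold accuracies: {[round(a, 3) for a in res.fold_accuracies]}")
print(f"mean CV accuracy: {res.mean_accuracy:.3f}")
print(f"labels: {res.labels}")
print("confusion matrix (rows = true, cols = predicted):")
print(res.confusion)
# Off-diagonal counts show which postures get confused; lean_left vs
# lean_right should be nearly disjoint since they shift mass to opposite
# hips, while upright vs lean_back differ mainly in the caudal feature.
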