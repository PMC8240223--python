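"""Train the MLP ancestry classifier on SVD-embedded genotypes.

Splits a simulated panel 80/20 (stratified by population), fits the SVD on
the training side only, trains the 2 x 100-unit relu network with the
squared-error-on-softmax loss, and prints held-out accuracy plus the
confusion matrix (rows = true population, columns = predicted).
"""

import numpy as np

from snpclassify import (
    PopulationModel,
    TrainConfig,
    evaluate,
    fit_svd,
    init_model,
    project,
    simulate_panel,
    split_train_test,
    train,
)

gm, labels = simulate_panel(
    PopulationModel(n_populations=4, samples_per_population=60,
                    n_variants=2000, divergence=0.1, seed=3)
)
(x_tr, l_tr), (x_te, l_te) = split_train_test(gm, labels, test_fraction=0.2, seed=0)

emb = fit_svd(x_tr, k=12)
xp_tr, xp_te = project(x_tr, emb), project(x_te, emb)

model = init_model(
    k_in=12, c=labels.n_classes, seed=0,
    feature_mean=xp_tr.mean(axis=0), feature_scale=xp_tr.std(axis=0),
)
w_star = train(model, xp_tr, l_tr.one_hot(x_tr.sample_ids),
               TrainConfig(epochs=150, seed=0))
print(f"epochs run: {len(w_star.loss_curve_)}, "
      f"final mean training loss: {w_star.loss_curve_[-1]:.5f}")

res = evaluate(w_star, xp_te, l_te.indices(x_te.sample_ids))
print(f"held-out accuracy: {res['accuracy']:.3f}")
print("confusion matrix (rows true, columns predicted):")
print(np.array2string(res["confusion"]))
print("\nA diagonal matrix means every held-out individual was assigned to")
print("its simulated population of origin.")
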