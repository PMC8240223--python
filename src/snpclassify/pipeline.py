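"""End-to-end runs of the three evaluation modes.

* **MLP** — embed with the training-set projection (SVD U^k or per-class
  histogram), train the classifier, score held-out samples on X_test . U^k.
* **MLP-IP** — perturb the embedded training inputs (IFGSM toward true
  classes), recover the perturbed projection U*, score the *frozen* weights
  on X_test . U*.
* **MLP-IP-R** — additionally re-train the classifier on X_train . U*
  (warm-started from W* by default) before scoring on X_test . U*.

Embeddings and class histograms are fit on the training split only; the test
split enters only through the final matrix products, so there is no label or
data leakage.  All randomness flows from three named seeds (split, init,
train).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mlp
from .embeddings import fit_class_histogram, fit_svd, project
from .io import GenotypeMatrix, LabelSet, split_train_test
from .perturb import PerturbConfig, perturb

MODES = ("mlp", "mlp_ip", "mlp_ip_r")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    embedding: str = "svd"
    k: int = 20
    test_fraction: float = 0.2
    train: mlp.TrainConfig = field(default_factory=mlp.TrainConfig)
    perturb: PerturbConfig = field(default_factory=PerturbConfig)
    retrain_init: str = "from_Wstar"
    retrain_epochs: int | None = None
    split_seed: int = 0
    init_seed: int = 0
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding not in ("svd", "class_histogram"):
            raise ValueError(f"unknown embedding kind {self.embedding!r}")
        if self.embedding == "svd" and self.k < 1:
            raise ValueError("k must be >= 1 for the SVD embedding")
        if self.retrain_init not in ("from_Wstar", "from_scratch"):
            raise ValueError(f"unknown retrain_init {self.retrain_init!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _metrics(model: mlp.MLPModel, X_emb, y_idx, labels: LabelSet, mode: str) -> dict:
    ev = mlp.evaluate(model, X_emb, y_idx)
    return {
        "mode": mode,
        "accuracy": ev["accuracy"],
        "confusion": ev["confusion"].tolist(),
        "confusion_normalized": ev["confusion_normalized"].tolist(),
        "classes": list(labels.classes),
        "n": int(X_emb.shape[0]),
    }


def run_pipeline(
    cfg: RunConfig,
    X: GenotypeMatrix,
    labels: LabelSet,
    modes: tuple[str, ...] = MODES,
) -> dict:
    """Run the requested modes, sharing split/embedding/training work.

    Returns a dict with per-mode train/test metrics under ``modes`` and the
    intermediate artifacts (embedding, models, perturbation result) under
    ``artifacts``.
    """
    unknown = set(modes) - set(MODES)
    if unknown:
        raise ValueError(f"unknown modes: {sorted(unknown)}")
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes to classify")

    (X_tr, L_tr), (X_te, L_te) = split_train_test(
        X, labels, cfg.test_fraction, cfg.split_seed
    )
    y_tr = L_tr.indices(X_tr.sample_ids)
    y_te = L_te.indices(X_te.sample_ids)
    Y_tr = L_tr.one_hot(X_tr.sample_ids)

    if cfg.embedding == "svd":
        emb = fit_svd(X_tr, cfg.k)
    else:
        emb = fit_class_histogram(X_tr, L_tr)
    Xp_tr = project(X_tr, emb)
    Xp_te = project(X_te, emb)

    model0 = mlp.init_model(
        Xp_tr.shape[1],
        labels.n_classes,
        seed=cfg.init_seed,
        feature_mean=Xp_tr.mean(axis=0),
        feature_scale=Xp_tr.std(axis=0),
    )
    train_cfg = dataclasses.replace(cfg.train, seed=cfg.train_seed)
    w_star = mlp.train(model0, Xp_tr, Y_tr, train_cfg)

    out: dict = {
        "config": cfg.to_dict(),
        "modes": {},
        "artifacts": {"embedding": emb, "model": w_star, "split": {
            "train_samples": list(X_tr.sample_ids),
            "test_samples": list(X_te.sample_ids),
        }},
    }
    if "mlp" in modes:
        out["modes"]["mlp"] = {
            "train": _metrics(w_star, Xp_tr, y_tr, labels, "mlp"),
            "test": _metrics(w_star, Xp_te, y_te, labels, "mlp"),
        }

    if "mlp_ip" in modes or "mlp_ip_r" in modes:
        pr = perturb(X_tr, Xp_tr, Y_tr, w_star, cfg.perturb, loss=train_cfg.loss)
        out["artifacts"]["perturbation"] = pr
        Xs_tr = X_tr.values.astype(float) @ pr.U_star
        Xs_te = X_te.values.astype(float) @ pr.U_star
        if "mlp_ip" in modes:
            out["modes"]["mlp_ip"] = {
                "train": _metrics(w_star, Xs_tr, y_tr, labels, "mlp_ip"),
                "test": _metrics(w_star, Xs_te, y_te, labels, "mlp_ip"),
            }
        if "mlp_ip_r" in modes:
            if cfg.retrain_init == "from_Wstar":
                start = w_star
            else:
                start = mlp.init_model(
                    Xs_tr.shape[1],
                    labels.n_classes,
                    seed=cfg.init_seed,
                    feature_mean=Xs_tr.mean(axis=0),
                    feature_scale=Xs_tr.std(axis=0),
                )
            retrain_cfg = dataclasses.replace(
                train_cfg,
                epochs=cfg.retrain_epochs if cfg.retrain_epochs is not None else train_cfg.epochs,
                seed=cfg.train_seed + 1,
            )
            w_r = mlp.train(start, Xs_tr, Y_tr, retrain_cfg)
            out["artifacts"]["model_retrained"] = w_r
            out["modes"]["mlp_ip_r"] = {
                "train": _metrics(w_r, Xs_tr, y_tr, labels, "mlp_ip_r"),
                "test": _metrics(w_r, Xs_te, y_te, labels, "mlp_ip_r"),
            }
    return out


def run_mlp(cfg: RunConfig, X: GenotypeMatrix, labels: LabelSet) -> dict:
    """Baseline mode: train W*, score on X_test . U^k."""
    return run_pipeline(cfg, X, labels, modes=("mlp",))["modes"]["mlp"]


def run_mlp_ip(cfg: RunConfig, X: GenotypeMatrix, labels: LabelSet) -> dict:
    """Frozen-weights mode: score W* on X_test . U*."""
    return run_pipeline(cfg, X, labels, modes=("mlp", "mlp_ip"))["modes"]["mlp_ip"]


def run_mlp_ip_r(cfg: RunConfig, X: GenotypeMatrix, labels: LabelSet) -> dict:
    """Re-trained mode: retrain on X_train . U*, score on X_test . U*."""
    return run_pipeline(cfg, X, labels, modes=MODES)["modes"]["mlp_ip_r"]


def sweep_modes(
    cfg: RunConfig,
    X: GenotypeMatrix,
    labels: LabelSet,
    ks: list[int],
) -> tuple[pd.DataFrame, dict]:
    """Accuracy table over embedding dimensions (rows k, columns modes).

    Mirrors the headline table layout: one row per k, columns MLP, MLP-IP,
    MLP-IP-R holding test accuracies.  A failing cell is recorded as NaN and
    the sweep continues.  Also returns per-(k, mode) confusion matrices.
    """
    rows = []
    confusions: dict = {}
    for k in ks:
        row = {"k": k}
        try:
            res = run_pipeline(dataclasses.replace(cfg, k=k), X, labels)
            for mode, label in zip(MODES, ("MLP", "MLP-IP", "MLP-IP-R")):
                row[label] = res["modes"][mode]["test"]["accuracy"]
                confusions[(k, label)] = np.array(
                    res["modes"][mode]["test"]["confusion"]
                )
        except Exception as exc:  # noqa: BLE001 - partial failures recorded per cell
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("k")
    return table, confusions
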