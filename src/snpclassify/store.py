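"""On-disk persistence for matrices, embeddings, and models.

The matrix store is a NumPy ``.npz`` archive holding the dense values plus
the two identifier lists; round-trips are bit-exact.  Embeddings and models
get a JSON sidecar (same path with ``.json`` appended) recording their
metadata so artifacts are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .embeddings import ClassHistogramEmbedding, SVDProjection
from .io import GenotypeMatrix
from .mlp import MLPModel


def _npz_path(path: str) -> str:
    path = str(path)
    return path if path.endswith(".npz") else path + ".npz"


def save_genotype_matrix(gm: GenotypeMatrix, path: str) -> None:
    np.savez_compressed(
        _npz_path(path),
        values=gm.values,
        sample_ids=np.array(gm.sample_ids, dtype=str),
        variant_ids=np.array(gm.variant_ids, dtype=str),
    )


def load_genotype_matrix(path: str) -> GenotypeMatrix:
    with np.load(_npz_path(path), allow_pickle=False) as z:
        return GenotypeMatrix(
            values=z["values"],
            sample_ids=[str(s) for s in z["sample_ids"]],
            variant_ids=[str(v) for v in z["variant_ids"]],
        )


def save_embedding(emb: SVDProjection | ClassHistogramEmbedding, path: str) -> None:
    path = _npz_path(path)
    if isinstance(emb, SVDProjection):
        np.savez_compressed(
            path,
            basis=emb.basis,
            singular_values=emb.singular_values,
            variant_ids=np.array(emb.fitted_on_variant_ids, dtype=str),
        )
        meta = {"kind": "svd", "k": emb.k}
    else:
        np.savez_compressed(
            path,
            basis=emb.basis,
            variant_ids=np.array(emb.fitted_on_variant_ids, dtype=str),
        )
        meta = {"kind": "class_histogram", "classes": emb.classes}
    _write_sidecar(path, meta)


def load_embedding(path: str) -> SVDProjection | ClassHistogramEmbedding:
    path = _npz_path(path)
    meta = _read_sidecar(path)
    with np.load(path, allow_pickle=False) as z:
        variant_ids = [str(v) for v in z["variant_ids"]]
        if meta["kind"] == "svd":
            return SVDProjection(
                basis=z["basis"],
                singular_values=z["singular_values"],
                k=int(meta["k"]),
                fitted_on_variant_ids=variant_ids,
            )
        return ClassHistogramEmbedding(
            basis=z["basis"],
            classes=list(meta["classes"]),
            fitted_on_variant_ids=variant_ids,
        )


def save_model(model: MLPModel, path: str, meta: dict | None = None) -> None:
    path = _npz_path(path)
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    if model.input_mean is not None:
        arrays["input_mean"] = model.input_mean
    if model.input_scale is not None:
        arrays["input_scale"] = model.input_scale
    np.savez_compressed(path, n_layers=np.array(len(model.weights)), **arrays)
    _write_sidecar(path, {"layer_sizes": list(model.layer_sizes), **(meta or {})})


def load_model(path: str) -> tuple[MLPModel, dict]:
    path = _npz_path(path)
    meta = _read_sidecar(path)
    with np.load(path, allow_pickle=False) as z:
        n = int(z["n_layers"])
        weights = [z[f"W{i}"] for i in range(n)]
        biases = [z[f"b{i}"] for i in range(n)]
        input_mean = z["input_mean"] if "input_mean" in z else None
        input_scale = z["input_scale"] if "input_scale" in z else None
    return MLPModel(
        weights=weights, biases=biases,
        input_mean=input_mean, input_scale=input_scale,
    ), meta


def _sidecar_path(path: str) -> Path:
    p = Path(path)
    if p.suffix != ".npz":
        p = p.with_suffix(p.suffix + ".npz")
    return Path(str(p) + ".json")


def _write_sidecar(path: str, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_sidecar(path: str) -> dict:
    return json.loads(_sidecar_path(path).read_text())
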