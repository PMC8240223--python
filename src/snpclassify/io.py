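"""Genotype and label input/output.

Genotypes are held as dense dosage matrices (samples x SNPs) with entries in
{0, 1, 2}: homozygous reference = 0, heterozygous = 1, homozygous alternate = 2
at a biallelic site.  Readers accept PLINK additive-recode text (``.raw``) and
VCF with GT fields; population labels come from a two-column TSV.  Missing
calls are imputed at read time (per-variant mode by default) so every matrix
entry downstream is a valid dosage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PLINK_META_COLUMNS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
_VALID_DOSAGE_TOKENS = {"0", "1", "2", "NA"}


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with aligned sample and variant identifiers.

    Parameters
    ----------
    values
        Integer array of shape ``(n_samples, m_variants)`` with entries in
        {0, 1, 2}.
    sample_ids
        Unique sample identifiers, one per row.
    variant_ids
        Unique variant identifiers, one per column.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.variant_ids) != m:
            raise ValueError(f"{len(self.variant_ids)} variant_ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if len(set(self.variant_ids)) != m:
            raise ValueError("duplicate variant_ids")
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            bad = self.values[~np.isin(self.values, (0, 1, 2))][0]
            raise ValueError(f"dosage values must be in {{0,1,2}}; found {bad!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, row_indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(row_indices)
        return GenotypeMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variant_ids=list(self.variant_ids),
        )


@dataclass
class LabelSet:
    """Ordered class list plus per-sample class assignment.

    ``classes`` fixes the class-index order (lexicographic when built through
    :func:`read_labels` or :meth:`from_assignments`), so confusion-matrix
    layouts are reproducible across runs.
    """

    classes: list[str]
    assignment: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class codes")
        c = len(self.classes)
        for sid, k in self.assignment.items():
            if not (0 <= k < c):
                raise ValueError(f"class index {k} for sample {sid!r} out of range")

    @classmethod
    def from_assignments(cls, pairs: list[tuple[str, str]]) -> "LabelSet":
        """Build from (sample_id, class_code) pairs; classes sorted lexicographically."""
        if not pairs:
            raise ValueError("no label assignments given")
        seen: dict[str, str] = {}
        for sid, code in pairs:
            if sid in seen and seen[sid] != code:
                raise ValueError(
                    f"sample {sid!r} listed with conflicting classes "
                    f"{seen[sid]!r} and {code!r}"
                )
            seen[sid] = code
        classes = sorted(set(seen.values()))
        index = {code: i for i, code in enumerate(classes)}
        return cls(classes=classes, assignment={s: index[c] for s, c in seen.items()})

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def indices(self, sample_ids: list[str]) -> np.ndarray:
        """Class index for each sample, in the given order."""
        try:
            return np.array([self.assignment[s] for s in sample_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no class assignment") from exc

    def one_hot(self, sample_ids: list[str]) -> np.ndarray:
        """One-hot label matrix Y of shape (n_samples, n_classes)."""
        idx = self.indices(sample_ids)
        out = np.zeros((len(sample_ids), self.n_classes))
        out[np.arange(len(sample_ids)), idx] = 1.0
        return out

    def restrict(self, sample_ids: list[str]) -> "LabelSet":
        """Assignment restricted to the given samples; class order unchanged."""
        return LabelSet(
            classes=list(self.classes),
            assignment={s: self.assignment[s] for s in sample_ids},
        )


def _impute(values: np.ndarray, impute: str) -> np.ndarray:
    """Replace NaNs in a float dosage matrix; returns an integer matrix.

    ``mode``: per-variant mode over non-missing calls, ties broken toward the
    lower dosage.  ``zero``: missing -> 0.
    """
    if impute not in ("mode", "zero"):
        raise ValueError(f"impute must be 'mode' or 'zero', got {impute!r}")
    out = values.copy()
    missing = np.isnan(out)
    if missing.any():
        if impute == "zero":
            out[missing] = 0.0
        else:
            for j in np.flatnonzero(missing.any(axis=0)):
                col = out[:, j]
                obs = col[~np.isnan(col)]
                if obs.size == 0:
                    fill = 0.0
                else:
                    counts = np.bincount(obs.astype(np.int64), minlength=3)
                    fill = float(np.argmax(counts))  # argmax -> lowest dosage on ties
                col[np.isnan(col)] = fill
    return out.astype(np.int16)


def read_plink_raw(path: str, impute: str = "mode") -> GenotypeMatrix:
    """Read a PLINK additive-recode text file (``--recode A`` layout).

    The header row must start with ``FID IID PAT MAT SEX PHENOTYPE``; every
    later column is a variant.  Genotype cells are ``0``/``1``/``2`` or the
    missing token ``NA``.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    if tuple(df.columns[:6]) != _PLINK_META_COLUMNS:
        raise ValueError(
            "malformed PLINK .raw header: expected leading columns "
            f"{' '.join(_PLINK_META_COLUMNS)}, got {' '.join(df.columns[:6])}"
        )
    variant_ids = list(df.columns[6:])
    sample_ids = list(df["IID"].astype(str))
    cells = df.iloc[:, 6:].to_numpy(dtype=str) if variant_ids else np.empty((len(df), 0), dtype=str)
    bad = ~np.isin(cells, list(_VALID_DOSAGE_TOKENS))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype cell {cells[i, j]!r} at sample {sample_ids[i]!r}, "
            f"variant {variant_ids[j]!r}"
        )
    values = np.where(cells == "NA", "nan", cells).astype(float)
    return GenotypeMatrix(_impute(values, impute), sample_ids, variant_ids)


def read_vcf_dosages(path: str, impute: str = "mode") -> GenotypeMatrix:
    """Read GT fields from a VCF into a dosage matrix.

    Only biallelic records are retained (skipped multi-allelic records are
    counted in a log message).  ``0/0 -> 0``, ``0/1``/``1/0`` (phased or not)
    ``-> 1``, ``1/1 -> 2``; missing calls are imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        col = np.full(len(sample_ids), np.nan)
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1]]
            if any(a < 0 for a in alleles):
                continue
            col[i] = float(sum(alleles))
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}_{v.REF}_{v.ALT[0]}"
        variant_ids.append(vid)
        columns.append(col)
    if n_skipped:
        logger.info("skipped %d multi-allelic VCF records", n_skipped)
    if not columns:
        raise ValueError(f"no biallelic records with GT fields in {path}")
    values = np.column_stack(columns)
    return GenotypeMatrix(_impute(values, impute), sample_ids, variant_ids)


def read_labels(path: str) -> LabelSet:
    """Read a two-column sample->population TSV (optional header line)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"label file {path} is empty") from exc
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two tab-separated columns")
    if tuple(df.iloc[0, :2]) == ("sample_id", "population"):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"label file {path} has no assignments")
    pairs = [(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]
    return LabelSet.from_assignments(pairs)


def write_labels(labels: LabelSet, path: str, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("sample_id\tpopulation\n")
        for sid, k in labels.assignment.items():
            fh.write(f"{sid}\t{labels.classes[k]}\n")


def split_train_test(
    X: GenotypeMatrix,
    labels: LabelSet,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[tuple[GenotypeMatrix, LabelSet], tuple[GenotypeMatrix, LabelSet]]:
    """Stratified, seeded train/test split.

    Each class contributes ``round(class_n * test_fraction)`` test samples
    (at least 1, at most ``class_n - 1``); the split is a partition of the
    samples and is deterministic given ``seed``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = labels.indices(X.sample_ids)
    rng = np.random.default_rng(seed)
    test_rows: list[np.ndarray] = []
    train_rows: list[np.ndarray] = []
    for k in range(labels.n_classes):
        members = np.flatnonzero(y == k)
        if members.size == 0:
            continue
        if members.size < 2:
            raise ValueError(
                f"class {labels.classes[k]!r} has a single sample; merge it with a "
                "related class or exclude it before splitting"
            )
        n_test = int(round(members.size * test_fraction))
        n_test = min(max(n_test, 1), members.size - 1)
        perm = rng.permutation(members)
        test_rows.append(np.sort(perm[:n_test]))
        train_rows.append(np.sort(perm[n_test:]))
    test_idx = np.sort(np.concatenate(test_rows))
    train_idx = np.sort(np.concatenate(train_rows))
    X_train = X.subset_samples(train_idx)
    X_test = X.subset_samples(test_idx)
    return (
        (X_train, labels.restrict(X_train.sample_ids)),
        (X_test, labels.restrict(X_test.sample_ids)),
    )
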