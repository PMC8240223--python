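"""Synthetic multi-population genotype panels.

The generator follows the Balding–Nichols model of population structure: each
variant has an ancestral allele frequency p drawn uniformly from a configurable
interval, each population k perturbs it to q_k ~ Beta(p(1-F_k)/F_k,
(1-p)(1-F_k)/F_k) — so that E[q_k] = p and Var[q_k] = F_k * p(1-p) — and each
individual's dosage is Binomial(2, q_k), i.e. two independent allele draws
(Hardy–Weinberg proportions within a population).  The single divergence knob F
is an Fst analogue: larger F means more allele-frequency differentiation and
an easier classification problem.

The default panel (6 populations x 100 samples, 5000 variants, F = 0.1) is the
desk-scale stand-in used throughout the test-suite and examples: large enough
that SVD embeddings capture the population structure, small enough to run in
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix, LabelSet


@dataclass
class PopulationModel:
    """Parameters of a simulated multi-population panel.

    ``samples_per_population`` and ``divergence`` accept either a scalar
    (shared by all populations) or one value per population.
    """

    n_populations: int = 6
    samples_per_population: int | list[int] = 100
    n_variants: int = 5000
    divergence: float | list[float] = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                f"ancestral_freq_range must be a nonempty interval within (0,1), "
                f"got {self.ancestral_freq_range}"
            )
        if any(n < 1 for n in self.pop_sizes):
            raise ValueError("samples_per_population entries must be positive")
        if any(not (0.0 < f < 1.0) for f in self.divergences):
            raise ValueError("divergence values must lie in (0, 1)")

    @property
    def pop_sizes(self) -> list[int]:
        n = self.samples_per_population
        sizes = [n] * self.n_populations if np.isscalar(n) else list(n)
        if len(sizes) != self.n_populations:
            raise ValueError("samples_per_population length != n_populations")
        return [int(s) for s in sizes]

    @property
    def divergences(self) -> list[float]:
        f = self.divergence
        divs = [f] * self.n_populations if np.isscalar(f) else list(f)
        if len(divs) != self.n_populations:
            raise ValueError("divergence length != n_populations")
        return [float(x) for x in divs]

    @property
    def population_codes(self) -> list[str]:
        return [f"POP{k + 1:02d}" for k in range(self.n_populations)]

    def to_dict(self) -> dict:
        return {
            "n_populations": self.n_populations,
            "samples_per_population": self.pop_sizes,
            "n_variants": self.n_variants,
            "divergence": self.divergences,
            "ancestral_freq_range": list(self.ancestral_freq_range),
            "seed": self.seed,
        }


def simulate_panel(model: PopulationModel) -> tuple[GenotypeMatrix, LabelSet]:
    """Draw one genotype panel; fully deterministic given ``model.seed``."""
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_freq_range
    m = model.n_variants
    p = rng.uniform(lo, hi, size=m)

    blocks: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []
    sample_ids: list[str] = []
    for code, n_k, f_k in zip(model.population_codes, model.pop_sizes, model.divergences):
        shape_a = p * (1.0 - f_k) / f_k
        shape_b = (1.0 - p) * (1.0 - f_k) / f_k
        q = rng.beta(shape_a, shape_b)
        blocks.append(rng.binomial(2, q, size=(n_k, m)).astype(np.int16))
        for i in range(n_k):
            sid = f"{code}_S{i + 1:04d}"
            sample_ids.append(sid)
            pairs.append((sid, code))

    gm = GenotypeMatrix(
        values=np.vstack(blocks),
        sample_ids=sample_ids,
        variant_ids=[f"snp{j + 1:06d}" for j in range(m)],
    )
    return gm, LabelSet.from_assignments(pairs)


def expected_separability(model: PopulationModel) -> float:
    """Empirical Fst-like statistic from one simulated realization.

    Mean over variants of the between-population variance of sample allele
    frequencies divided by pbar(1-pbar).  Near 0 for K=1 or tiny F; grows
    with the divergence parameter, so tests can check that harder/easier
    panels order as expected.
    """
    gm, labels = simulate_panel(model)
    return separability_statistic(gm, labels)


def separability_statistic(gm: GenotypeMatrix, labels: LabelSet) -> float:
    """The statistic behind :func:`expected_separability`, on a given panel.

    Symmetric in the populations: any relabeling of classes leaves it
    unchanged.
    """
    y = labels.indices(gm.sample_ids)
    freqs = np.stack(
        [gm.values[y == k].mean(axis=0) / 2.0 for k in range(labels.n_classes)]
    )  # (K, m) sample allele frequencies
    pbar = freqs.mean(axis=0)
    between = freqs.var(axis=0)
    denom = pbar * (1.0 - pbar)
    keep = denom > 1e-12
    if not keep.any():
        return 0.0
    return float(np.mean(between[keep] / denom[keep]))
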