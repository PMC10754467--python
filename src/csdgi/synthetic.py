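"""Synthetic scRNA-seq-like matrices with planted structure.

Emulates a non-negative log-scale expression matrix (think logTPM) with
dropout zeros, planted cell subtypes, and planted subtype-specific
up-regulated driver genes, so that every pipeline stage can be tested
with known ground truth.  Effects are additive on the log scale
(multiplicative on the raw scale).

The default scenario — 200 cells, 100 genes, 2 equally sized subtypes with
10 disjoint driver genes each shifted by +2.0 log-units, dropout 0.3,
cell-level Gaussian noise sd 0.5 on a Gamma(shape=2, scale=0.5) baseline
(mean log-expression 1.0, typical of prevalence-filtered genes) — is the
package's standing parameter-recovery benchmark.  Because dropout variance
grows with the squared mean, the baseline level controls how much dropout
noise competes with the planted subtype signal; the default keeps the
planted structure dominant, as the premise of a planted-truth benchmark
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CellAnnotation, ExpressionMatrix

__all__ = ["SyntheticScenario", "SyntheticTruth", "generate", "generate_two_group"]


@dataclass
class SyntheticScenario:
    m_cells: int = 200
    n_genes: int = 100
    n_subtypes: int = 2
    drivers_per_subtype: int = 10
    effect_shift: float = 2.0  # log-expression units added on driver genes
    dropout_rate: float = 0.3
    baseline_shape: float = 2.0  # Gamma shape of per-gene baseline means
    baseline_scale: float = 0.5  # Gamma scale; mean baseline = shape * scale
    noise_sd: float = 0.5
    subtype_proportions: list[float] | None = None
    driver_overlap: float = 0.0  # fraction of drivers shared between consecutive subtypes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("m_cells", "n_genes", "n_subtypes", "drivers_per_subtype"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_subtypes * self.drivers_per_subtype > self.n_genes:
            raise ValueError(
                "n_subtypes * drivers_per_subtype exceeds n_genes"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.effect_shift < 0:
            raise ValueError("effect_shift must be non-negative")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0 or self.noise_sd < 0:
            raise ValueError("baseline shape/scale must be positive, noise_sd >= 0")
        if not 0 <= self.driver_overlap < 1:
            raise ValueError("driver_overlap must lie in [0, 1)")
        if self.subtype_proportions is None:
            self.subtype_proportions = [1.0 / self.n_subtypes] * self.n_subtypes
        props = np.asarray(self.subtype_proportions, dtype=float)
        if props.size != self.n_subtypes or not np.isclose(props.sum(), 1.0):
            raise ValueError("subtype_proportions must sum to 1, one per subtype")


@dataclass
class SyntheticTruth:
    labels: np.ndarray  # planted subtype per cell, 1-based
    driver_sets: dict[int, list[str]]  # planted driver genes per subtype
    group: list[str] | None = None  # tumor/nontumor flag for two-group runs


def _gene_names(n: int) -> list[str]:
    return [f"gene{j:04d}" for j in range(n)]


def _cell_ids(m: int) -> list[str]:
    return [f"cell{i:04d}" for i in range(m)]


def generate(scenario: SyntheticScenario) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one matrix with planted subtypes and driver genes.

    values = clip(baseline_g + shift(driver, subtype) + noise, 0), then
    dropout zeros each entry independently with probability dropout_rate.
    Fully reproducible from scenario.seed.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    genes = _gene_names(sc.n_genes)
    cells = _cell_ids(sc.m_cells)

    baseline = rng.gamma(shape=sc.baseline_shape, scale=sc.baseline_scale, size=sc.n_genes)
    labels = rng.choice(
        np.arange(1, sc.n_subtypes + 1), size=sc.m_cells, p=sc.subtype_proportions
    )
    # make sure every subtype is represented so downstream stages are testable
    for k in range(1, sc.n_subtypes + 1):
        if not np.any(labels == k):
            labels[rng.integers(sc.m_cells)] = k

    gene_perm = rng.permutation(sc.n_genes)
    n_overlap = int(round(sc.driver_overlap * sc.drivers_per_subtype))
    driver_sets: dict[int, list[str]] = {}
    driver_idx: dict[int, np.ndarray] = {}
    cursor = 0
    prev: np.ndarray | None = None
    for k in range(1, sc.n_subtypes + 1):
        take = sc.drivers_per_subtype - (n_overlap if prev is not None else 0)
        own = gene_perm[cursor : cursor + take]
        cursor += take
        idx = own if prev is None else np.concatenate([prev[:n_overlap], own])
        driver_idx[k] = idx
        driver_sets[k] = sorted(genes[j] for j in idx)
        prev = idx

    values = baseline[None, :] + rng.normal(0.0, sc.noise_sd, (sc.m_cells, sc.n_genes))
    for k, idx in driver_idx.items():
        rows = labels == k
        values[np.ix_(rows, idx)] += sc.effect_shift
    values = np.clip(values, 0.0, None)
    if sc.dropout_rate > 0:
        values[rng.random(values.shape) < sc.dropout_rate] = 0.0

    X = ExpressionMatrix(values, genes, cells)
    return X, SyntheticTruth(labels=labels, driver_sets=driver_sets)


def generate_two_group(
    scenario: SyntheticScenario,
    n_deg: int = 50,
    deg_shift: float = 2.0,
) -> tuple[ExpressionMatrix, SyntheticTruth, CellAnnotation]:
    """Tumor/non-tumor matrix for exercising the DEG stage.

    The first half of the cells is flagged tumor; ``n_deg`` randomly chosen
    genes are shifted by ``deg_shift`` in the tumor group.  Baseline, noise
    and dropout follow the scenario.
    """
    sc = scenario
    if n_deg > sc.n_genes:
        raise ValueError("n_deg exceeds n_genes")
    if n_deg < 0 or deg_shift < 0:
        raise ValueError("n_deg and deg_shift must be non-negative")
    rng = np.random.default_rng(sc.seed)
    genes = _gene_names(sc.n_genes)
    cells = _cell_ids(sc.m_cells)
    n_tumor = sc.m_cells // 2
    group = ["tumor"] * n_tumor + ["nontumor"] * (sc.m_cells - n_tumor)

    baseline = rng.gamma(shape=sc.baseline_shape, scale=sc.baseline_scale, size=sc.n_genes)
    deg_idx = rng.permutation(sc.n_genes)[:n_deg]
    values = baseline[None, :] + rng.normal(0.0, sc.noise_sd, (sc.m_cells, sc.n_genes))
    values[np.ix_(np.arange(n_tumor), deg_idx)] += deg_shift
    values = np.clip(values, 0.0, None)
    if sc.dropout_rate > 0:
        values[rng.random(values.shape) < sc.dropout_rate] = 0.0

    X = ExpressionMatrix(values, genes, cells)
    truth = SyntheticTruth(
        labels=np.where(np.arange(sc.m_cells) < n_tumor, 1, 2),
        driver_sets={0: sorted(genes[j] for j in deg_idx)} if n_deg else {0: []},
        group=group,
    )
    ann = CellAnnotation(cells, group)
    return X, truth, ann
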