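"""Standing synthetic benchmarks: parameter recovery, DEG calibration and
subtype-number estimation on the generator's default scenario.

These are the package's self-checks with known ground truth.  Driver
recovery is reported as the planted fraction of the reported driver set
(|top-fraction set ∩ planted drivers of the branch's majority subtype| /
|top-fraction set|): the top-5% set on the default scenario holds 5 genes
against 10 planted per subtype, so a recall against the planted set is
capped at 0.5 by arithmetic and the set-precision reading is the
informative one.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .drivers import rank_genes
from .evaluation import adjusted_rand_index, wss_curve
from .model import ModelConfig, fit
from .preprocessing import PreprocessConfig, deg_test
from .synthetic import SyntheticScenario, generate, generate_two_group

__all__ = [
    "parameter_recovery",
    "deg_null_and_power",
    "elbow_recovery",
]


def _branch_majority_subtype(truth_labels, assigned_labels, branch: int) -> int:
    served = truth_labels[assigned_labels == branch]
    if served.size == 0:
        return 1
    counts = np.bincount(served)
    return int(np.argmax(counts))


def parameter_recovery(
    seeds=range(5),
    scenario: SyntheticScenario | None = None,
    epochs: int = 400,
    fraction: float = 0.05,
) -> dict:
    """Fit the model on fresh scenario draws and score it against the
    planted truth.

    Returns per-seed planted-label ARIs and driver-recovery fractions plus
    their medians.  Each seed drives both the data draw and the model init.
    """
    base = scenario or SyntheticScenario()
    aris, recoveries = [], []
    for seed in seeds:
        sc = replace(base, seed=int(seed))
        X, truth = generate(sc)
        cfg = ModelConfig(n_subtypes=sc.n_subtypes, epochs=epochs, seed=int(seed))
        _, weights, assignment, _ = fit(X, cfg)
        aris.append(adjusted_rand_index(truth.labels, assignment.labels))
        per_branch = []
        for k in range(sc.n_subtypes):
            own = _branch_majority_subtype(truth.labels, assignment.labels, k + 1)
            planted = set(truth.driver_sets[own])
            ranking = rank_genes(weights.lam[k], X.gene_names, subtype=k + 1, fraction=fraction)
            top = set(ranking.driver_set)
            per_branch.append(len(top & planted) / len(top))
        recoveries.append(float(np.mean(per_branch)))
    return {
        "ari": aris,
        "driver_recovery": recoveries,
        "median_ari": float(np.median(aris)),
        "median_driver_recovery": float(np.median(recoveries)),
    }


def deg_null_and_power(
    seed: int = 0,
    n_genes: int = 500,
    cells_per_group: int = 100,
    n_deg: int = 50,
    shift: float = 2.0,
    alpha: float = 0.05,
    n_permutations: int = 100,
) -> dict:
    """Type-I error and power of the EMD permutation test.

    Null run: no gene differs between the groups, so the selected fraction
    estimates the test's size (should sit near alpha).  Power run: n_deg
    genes are shifted by ``shift`` log-units in the tumor group and the
    selected set is scored for recall of the planted genes.
    """
    sc = SyntheticScenario(
        m_cells=2 * cells_per_group, n_genes=n_genes, seed=seed,
        n_subtypes=1, drivers_per_subtype=1,
    )
    cfg = PreprocessConfig(alpha=alpha, emd_score_min=0.0, n_permutations=n_permutations, seed=seed)

    X0, _, ann0 = generate_two_group(sc, n_deg=0, deg_shift=0.0)
    null_records = deg_test(X0, ann0, cfg)
    null_fraction = float(np.mean([r.selected for r in null_records]))

    X1, truth1, ann1 = generate_two_group(sc, n_deg=n_deg, deg_shift=shift)
    power_records = deg_test(X1, ann1, cfg)
    planted = set(truth1.driver_sets[0])
    selected = {r.gene for r in power_records if r.selected}
    recall = len(selected & planted) / len(planted)
    return {
        "null_selected_fraction": null_fraction,
        "power_recall": float(recall),
        "alpha": alpha,
        "n_genes": n_genes,
    }


def elbow_recovery(seeds=range(5), separation: float = 10.0, per_blob: int = 50, k_max: int = 6) -> dict:
    """How often the WSS elbow picks k=2 on two well-separated Gaussian
    blobs (separation in units of the within-blob standard deviation)."""
    hits = 0
    chosen = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        a = rng.normal(0.0, 1.0, (per_blob, 5))
        b = rng.normal(separation, 1.0, (per_blob, 5))
        curve = wss_curve(np.vstack([a, b]), k_max=k_max, restarts=10, seed=int(seed))
        chosen.append(curve.chosen_k)
        hits += curve.chosen_k == 2
    return {"chosen_k": chosen, "correct": hits, "n_seeds": len(chosen)}
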