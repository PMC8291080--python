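"""Replication studies on simulated data: the paired benchmark harness.

One simulated dataset per replication; every method sees the identical
dataset and split, so differences in discovery counts isolate the scoring
method (p-values vs SVM weights vs relevance scores).
"""

from __future__ import annotations

import numpy as np

from . import association, lrp, nn, svm
from .evaluate import ReplicationSummary, replication_experiment
from .simulate import SimulationConfig, simulate_dataset


def _rpvt_method(ds, seed):
    res = association.rpvt(ds.genotypes, ds.phenotypes)
    return res.pvalues, res.significant, None


def _combi_method(ds, seed):
    res = svm.combi(ds.genotypes, ds.phenotypes, svm.SvmConfig(seed=seed))
    return (
        res.association.pvalues,
        res.association.significant,
        (res.test_accuracy, res.test_balanced_accuracy),
    )


def _make_deepcombi_method(epochs: int):
    def run(ds, seed):
        cfg = nn.TrainingConfig(seed=seed, epochs=epochs)
        res = lrp.deepcombi(ds.genotypes, ds.phenotypes, cfg)
        return (
            res.association.pvalues,
            res.association.significant,
            (res.test_accuracy, res.test_balanced_accuracy),
        )

    return run


def paired_benchmark(
    n_reps: int,
    seed: int = 0,
    n_noise_snps: int = 10_000,
    n_informative_snps: int = 20,
    gamma: float = 6.0,
    epochs: int = 500,
    methods: tuple[str, ...] = ("rpvt", "combi", "deepcombi"),
) -> ReplicationSummary:
    """Run the requested methods on ``n_reps`` paired simulated datasets."""

    def simulate_fn(rep_seed: int):
        cfg = SimulationConfig(
            n_noise_snps=n_noise_snps,
            n_informative_snps=n_informative_snps,
            gamma=gamma,
            seed=rep_seed,
        )
        return simulate_dataset(cfg)

    bank = {
        "rpvt": _rpvt_method,
        "combi": _combi_method,
        "deepcombi": _make_deepcombi_method(epochs),
    }
    chosen = {m: bank[m] for m in methods}
    return replication_experiment(n_reps, chosen, simulate_fn, seed=seed)
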