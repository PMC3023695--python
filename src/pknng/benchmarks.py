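"""Predefined replication studies on the synthetic benchmarks.

Each study runs the repeated-realization harness on a fixed family of
problems and returns the per-setting mean index values, mirroring the
package's headline comparisons: connection schemes on embedded manifolds,
the penalization ablation, the simulated-microarray metric comparison and
the insensitivity of the metric to the neighbor count k.

Problem sizes (realization counts, points per cluster) default to
scaled-down values chosen so a full study runs in minutes on one core;
they are parameters, not constants.
"""
from __future__ import annotations

from typing import Dict, Sequence

import numpy as np

from .clustering_eval import BenchmarkConfig, metric_label, run_benchmark

__all__ = ["scheme_comparison_study", "penalization_study",
           "microarray_study", "k_sensitivity_study"]

_SCHEME_METRICS = [
    {"name": "pknng", "scheme": "minspan", "label": "minspan"},
    {"name": "pknng", "scheme": "allsubgraphs", "label": "allsubgraphs"},
    {"name": "pknng", "scheme": "alledges", "label": "alledges"},
    {"name": "pknng", "scheme": "medoids", "label": "medoids"},
    {"name": "euclidean", "label": "euclidean"},
]


def _means(report, which: str) -> Dict[str, float]:
    raw = report.accuracy if which == "accuracy" else report.crand
    return {key.split("|")[0]: float(np.mean(vals)) for key, vals in raw.items()}


def scheme_comparison_study(shapes: Sequence[str] = ("moons", "spirals"),
                            embedding: str = "3dnoise", noise: str = "low",
                            n: int = 100, reps: int = 20, seed: int = 0,
                            k: int = 5) -> Dict[str, Dict[str, float]]:
    """Mean PAM accuracy of the four connection schemes vs plain Euclidean.

    Returns ``{shape: {scheme: mean accuracy %}}`` over ``reps`` seeded
    realizations of each embedded manifold problem.
    """
    out = {}
    n_clusters = {"moons": 2, "spirals": 3, "rings": 5}
    for shape in shapes:
        cfg = BenchmarkConfig(
            metrics=[dict(m, k=k) if m["name"] == "pknng" else m
                     for m in _SCHEME_METRICS],
            methods=["pam"], n_clusters=n_clusters[shape], generator=shape,
            generator_params={"n": n, "noise_level": noise,
                              "embedding": embedding},
            reps=reps, seed=seed, compute_accuracy=True)
        out[shape] = _means(run_benchmark(cfg), "accuracy")
    return out


def penalization_study(shape: str = "spirals", embedding: str = "10dnoise",
                       noise: str = "low", n: int = 100, reps: int = 20,
                       seed: int = 0, k: int = 5) -> Dict[str, float]:
    """Penalization ablation: exponential vs plain bridges vs the base metric.

    Mean PAM accuracy of exponentially penalized MinSpan, unpenalized
    ("plain") MinSpan, the min-k-connected-graph baseline and plain
    Euclidean on one embedded manifold problem.
    """
    n_clusters = {"moons": 2, "spirals": 3, "rings": 5}[shape]
    cfg = BenchmarkConfig(
        metrics=[{"name": "pknng", "scheme": "minspan",
                  "penalty": "exponential", "k": k, "label": "minspan-exp"},
                 {"name": "pknng", "scheme": "minspan", "penalty": "plain",
                  "k": k, "label": "minspan-plain"},
                 {"name": "min-k", "label": "min-k-connected"},
                 {"name": "euclidean", "label": "euclidean"}],
        methods=["pam"], n_clusters=n_clusters, generator=shape,
        generator_params={"n": n, "noise_level": noise, "embedding": embedding},
        reps=reps, seed=seed, compute_accuracy=True)
    return _means(run_benchmark(cfg), "accuracy")


def microarray_study(datasets: Sequence[str] = ("a1", "a2", "a3", "a4", "a5"),
                     reps: int = 20, seed: int = 0,
                     k: int = 5) -> Dict[str, Dict[str, float]]:
    """Mean PAM cRand of PKNNG vs plain Euclidean vs PBM (Euclidean base).

    Returns ``{dataset: {metric: mean cRand}}`` on the simulated-microarray
    problems, a fresh realization per repetition.
    """
    n_clusters = {"a1": 3, "a2": 2, "a3": 2, "a4": 3, "a5": 3}
    out = {}
    for name in datasets:
        cfg = BenchmarkConfig(
            metrics=[{"name": "pknng", "k": k, "label": "pknng"},
                     {"name": "euclidean", "label": "euclidean"},
                     {"name": "pbm", "label": "pbm"}],
            methods=["pam"], n_clusters=n_clusters[name], generator=name,
            reps=reps, seed=seed)
        out[name] = _means(run_benchmark(cfg), "crand")
    return out


def k_sensitivity_study(ks: Sequence[int] = (3, 4, 5, 6, 7),
                        dataset: str = "a1", reps: int = 20,
                        seed: int = 0) -> Dict[int, float]:
    """Mean PAM cRand of the penalized-graph metric as k varies.

    The metric's headline robustness claim: on the simulated-microarray
    problems the result barely depends on the neighbor count.
    """
    n_clusters = {"a1": 3, "a2": 2, "a3": 2, "a4": 3, "a5": 3}[dataset]
    out = {}
    for k in ks:
        cfg = BenchmarkConfig(
            metrics=[{"name": "pknng", "k": k, "label": f"pknng-k{k}"}],
            methods=["pam"], n_clusters=n_clusters, generator=dataset,
            reps=reps, seed=seed)
        report = run_benchmark(cfg)
        out[int(k)] = float(np.mean(report.crand[f"pknng-k{k}|pam"]))
    return out
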