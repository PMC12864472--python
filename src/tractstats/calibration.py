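"""Simulation-based calibration and recovery suites.

Each routine runs the full analysis path on replicated synthetic
datasets drawn under the study-scale conditions (group sizes 22/28,
the default nuisance structure of :mod:`tractstats.synthetic_data`)
and summarises frequentist operating characteristics:

* type-I error / family-wise error under the global null,
* uniformity of null association p-values,
* recovery of injected clusters, LI offsets and behaviour slopes.

They back both the test suite and the reproduction script; replicate
and permutation counts are arguments so callers can trade Monte-Carlo
error against runtime.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .association import behavior_assoc
from .data_model import demographics_frame
from .laterality import li_one_sample, li_table
from .linmod import PermutationConfig
from .synthetic_data import (
    BehaviorLink,
    GroupEffect,
    SimulationSpec,
    generate,
    null_dataset,
    null_spec,
)
from .tractometry import pointwise_compare


def mc_se(rate: float, n: int) -> float:
    """Monte-Carlo standard error of a binomial rate estimate."""
    return float(np.sqrt(rate * (1 - rate) / n))


def cluster_null_calibration(n_reps: int = 200, n_perm: int = 1000,
                             seed: int = 0, alpha: float = 0.05,
                             tracts=("L_AF", "R_SLF"),
                             metrics=("FA", "AD")) -> pd.DataFrame:
    """False-cluster rate per (tract, metric) under the global null.

    For each replicate a null dataset (no effects, no asymmetry, no
    links) is generated and ``pointwise_compare`` run on the given
    (tract, metric) subset; the statistic is the fraction of replicates
    reporting any cluster, which max-statistic FWE control plus the
    >= 4-node rule should keep at or below alpha.
    """
    counts: dict = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        ds, records, _ = null_dataset(SimulationSpec(seed=rep_seed))
        demo = demographics_frame(records)
        cfg = PermutationConfig(n_perm, rep_seed + 1)
        res = pointwise_compare(ds, demo, cfg, tracts=tracts,
                                metrics=metrics, alpha=alpha)
        for key, prof in res.items():
            counts[key] = counts.get(key, 0) + bool(prof.clusters)
    return pd.DataFrame([{
        "tract": t, "metric": m, "n_reps": n_reps,
        "cluster_rate": c / n_reps, "mc_se": mc_se(c / n_reps, n_reps),
    } for (t, m), c in counts.items()])


def li_null_calibration(n_reps: int = 200, n_perm: int = 1000,
                        seed: int = 0, alpha: float = 0.05,
                        metrics=("FA", "MD", "RD", "AD")) -> pd.DataFrame:
    """Family-wise error of the one-sample LI tests under zero asymmetry.

    Per replicate, both groups' LI tests run with sign-flip max-stat
    correction (family = tract pairs within metric); the reported rate
    is the fraction of replicates with any corrected rejection in the
    family, per (metric, group).
    """
    fwe: dict = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        ds, records, _ = null_dataset(SimulationSpec(seed=rep_seed))
        demo = demographics_frame(records)
        lt = li_table(ds, metrics=metrics)
        cfg = PermutationConfig(n_perm, rep_seed + 1)
        for group in ("TD", "ASD"):
            members = demo.index[demo["group"] == group]
            results = li_one_sample(lt, members, group, cfg, alpha,
                                    metrics=metrics)
            for r in results:
                key = (r.metric.value, group)
                fwe.setdefault(key, 0)
            for key in {(r.metric.value, group) for r in results
                        if r.p_corrected < alpha}:
                fwe[key] += 1
    return pd.DataFrame([{
        "metric": m, "group": g, "n_reps": n_reps,
        "fwe_rate": c / n_reps, "mc_se": mc_se(c / n_reps, n_reps),
    } for (m, g), c in fwe.items()])


def behavior_null_pvalues(n_reps: int = 200, n_perm: int = 199,
                          seed: int = 0, score: str = "gds_language",
                          tract: str = "L_AF",
                          metric: str = "FA") -> np.ndarray:
    """Parametric slope p of a null metric-behaviour association, one per
    replicate; uniform on (0, 1) when the analysis is calibrated."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        ds, records, _ = null_dataset(SimulationSpec(seed=rep_seed))
        demo = demographics_frame(records)
        cfg = PermutationConfig(n_perm, rep_seed + 1)
        res = behavior_assoc(ds, demo, score, "ASD", "tract", None, cfg,
                             tracts=(tract,), metrics=(metric,))
        out[i] = res[0].p_param
    return out


def cluster_recovery(n_reps: int = 200, n_perm: int = 1000, seed: int = 0,
                     d: float = 1.5, tract: str = "L_AF",
                     metric: str = "FA",
                     interval: tuple = (38, 42),
                     alpha: float = 0.05) -> dict:
    """Recovery of an injected localized group effect as a cluster.

    Injects an ASD-vs-TD difference of standardized amplitude ``d`` on
    ``interval`` and reruns the point-wise comparison per replicate.
    Reports the fraction of replicates with a reported cluster
    overlapping the true interval, and the fraction where some cluster
    matches both boundaries to within one node.
    """
    rng = np.random.default_rng(seed)
    overlap = exact1 = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        spec = null_spec(SimulationSpec(seed=rep_seed))
        spec.effects = [GroupEffect(tract, metric, interval[0], interval[1],
                                    d=d)]
        ds, records, _ = generate(spec)
        demo = demographics_frame(records)
        cfg = PermutationConfig(n_perm, rep_seed + 1)
        prof = pointwise_compare(ds, demo, cfg, tracts=(tract,),
                                 metrics=(metric,),
                                 alpha=alpha)[(tract, metric)]
        if any(a <= interval[1] and b >= interval[0]
               for a, b in prof.clusters):
            overlap += 1
        if any(abs(a - interval[0]) <= 1 and abs(b - interval[1]) <= 1
               for a, b in prof.clusters):
            exact1 += 1
    return {"n_reps": n_reps, "overlap_rate": overlap / n_reps,
            "within_one_node_rate": exact1 / n_reps,
            "mc_se": mc_se(overlap / n_reps, n_reps)}


def li_offset_recovery(n_reps: int = 200, seed: int = 0,
                       pair: str = "SLF", metric: str = "FA",
                       target: float = 0.0086) -> dict:
    """Bias of the recovered mean LI when one pair/metric carries a known
    asymmetry and everything else is null."""
    rng = np.random.default_rng(seed)
    means = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        spec = null_spec(SimulationSpec(seed=rep_seed))
        spec.asymmetry = {(pair, metric): target}
        ds, records, _ = generate(spec)
        lt = li_table(ds, pairs=(pair,), metrics=(metric,))
        means[i] = lt["li"].mean()
    est = means.mean()
    se = means.std(ddof=1) / np.sqrt(n_reps)
    return {"n_reps": n_reps, "target": target, "estimate": float(est),
            "bias": float(est - target), "mc_se": float(se)}


def slope_recovery(n_reps: int = 200, seed: int = 0,
                   slope: float = -0.001, tract: str = "L_AF",
                   metric: str = "FA", score: str = "gds_language",
                   group: str = "ASD") -> dict:
    """Bias of the recovered metric~score slope for an injected link."""
    rng = np.random.default_rng(seed)
    betas = np.empty(n_reps)
    for i in range(n_reps):
        rep_seed = int(rng.integers(2**31 - 1))
        spec = null_spec(SimulationSpec(seed=rep_seed))
        spec.behavior_links = [BehaviorLink(score, tract, metric, slope,
                                            group=group)]
        ds, records, _ = generate(spec)
        demo = demographics_frame(records)
        cfg = PermutationConfig(19, rep_seed + 1)   # beta needs no perms
        res = behavior_assoc(ds, demo, score, group, "tract", None, cfg,
                             tracts=(tract,), metrics=(metric,))
        betas[i] = res[0].beta
    est = betas.mean()
    se = betas.std(ddof=1) / np.sqrt(n_reps)
    return {"n_reps": n_reps, "target": slope, "estimate": float(est),
            "bias": float(est - slope), "mc_se": float(se)}


def uniformity_ks(pvalues: np.ndarray) -> tuple[float, float]:
    """KS statistic and p of p-values against Uniform(0, 1)."""
    stat, p = sps.kstest(pvalues, "uniform")
    return float(stat), float(p)
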