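"""Brain-behaviour association models.

Tract-wise and cluster-wise associations of the diffusion metrics with
behaviour scores: the language developmental quotient in both groups
(``metric ~ score + age + sex`` per group, plus the group x score
interaction model), and ADOS total severity in the ASD group only.
Effect sizes are reported as squared partial correlations controlling
for age and sex.

Cluster-level responses are the segment means over node intervals,
typically the clusters surviving the point-wise group comparison.
Because those intervals are selected on a group difference in the same
sample, cluster-level association statistics are selection-dependent;
outputs carry a ``selection_dependent`` flag to keep that caveat
visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import DEFAULT_TRACTS, METRICS, MetricName, TractProfileDataset
from .errors import SampleSizeError, TractStatsError
from .linmod import (
    PermutationConfig,
    build_design,
    maxstat_correct,
    ols_fit,
    partial_r2,
    perm_null_ts,
)

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """One association test (tract- or cluster-level)."""
    level: str                      # "tract" | "cluster"
    tract: str
    metric: MetricName
    group_scope: str                # "TD" | "ASD" | "interaction"
    score_name: str
    beta: float
    se: float
    t: float
    df: int
    p_param: float
    p_perm: float
    partial_r2: float
    node_interval: tuple | None = None   # cluster level only
    selection_dependent: bool = False

    def __post_init__(self):
        if (self.node_interval is not None) != (self.level == "cluster"):
            raise TractStatsError(
                "node_interval must be present exactly when level='cluster'")


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "level": r.level, "tract": r.tract, "metric": r.metric.value,
        "group_scope": r.group_scope, "score": r.score_name,
        "node_start": None if r.node_interval is None else r.node_interval[0],
        "node_end": None if r.node_interval is None else r.node_interval[1],
        "beta": r.beta, "se": r.se, "t": r.t, "df": r.df,
        "p_param": r.p_param, "p_perm": r.p_perm,
        "partial_r2": r.partial_r2,
        "selection_dependent": r.selection_dependent,
    } for r in results])


def _responses(ds, level, tracts, metric, clusters):
    """Response columns for one metric: per tract (tract level) or per
    discovered cluster (cluster level).  Yields (tract, interval, series)."""
    if level == "tract":
        for tract in tracts:
            yield tract, None, ds.tract_means(tract, metric)
    else:
        for (tract, m), intervals in clusters.items():
            if m != metric.value:
                continue
            for (a, b) in intervals:
                yield tract, (a, b), ds.segment_means(tract, metric, a, b)


def _fit_family(block: pd.DataFrame, frame: pd.DataFrame, terms, test_term,
                cfg: PermutationConfig, covar_cols=("age", "sex_f")):
    """Per-column fits with max-statistic-corrected permutation p on the
    tested term and partial r^2 of the tested score for each column."""
    X = build_design(frame, terms)
    Y = block.to_numpy(float)
    fits, obs_t = [], np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        fit = ols_fit(X, Y[:, j])
        obs_t[j] = fit.term(test_term).t
        fits.append(fit)
    nulls = perm_null_ts(X, Y, test_term, cfg)
    p_corr = maxstat_correct(obs_t, nulls)
    covs = frame[list(covar_cols)].to_numpy(float)
    return fits, p_corr, covs


def behavior_assoc(ds: TractProfileDataset, demographics: pd.DataFrame,
                   score: str, scope: str, level: str = "tract",
                   clusters: dict | None = None,
                   cfg: PermutationConfig | None = None,
                   tracts=DEFAULT_TRACTS,
                   metrics=METRICS) -> list[AssociationResult]:
    """Metric-behaviour associations at tract or cluster level.

    scope "TD"/"ASD" fits ``metric ~ score + age + sex`` within the
    group and tests the score slope; scope "interaction" fits
    ``metric ~ group * score + age + sex`` on both groups and tests the
    product term.  The tested term's permutation p is corrected across
    the responses (tracts, or discovered clusters) of each metric.
    ``clusters`` maps (tract, metric) -> [(start, end), ...] and is
    required at cluster level (typically ``{k: v.clusters}`` from
    ``pointwise_compare``).
    """
    cfg = cfg or PermutationConfig()
    if level not in ("tract", "cluster"):
        raise TractStatsError(f"unknown level {level!r}")
    if level == "cluster":
        if clusters is None:
            raise TractStatsError("cluster-level association needs clusters")
        if not any(clusters.values()):
            logger.warning("no clusters supplied; nothing to test")
            return []
    if scope == "interaction":
        terms = ["intercept", "group_asd", score, f"group_asd:{score}",
                 "age", "sex_f"]
        test_term = f"group_asd:{score}"
        frame0 = demographics
    elif scope in ("TD", "ASD"):
        terms = ["intercept", score, "age", "sex_f"]
        test_term = score
        frame0 = demographics.loc[demographics["group"] == scope]
    else:
        raise TractStatsError(f"unknown scope {scope!r}")
    ok = frame0[score].notna()
    if not ok.all():
        logger.warning("dropping %d subjects lacking %s", int((~ok).sum()),
                       score)
        frame0 = frame0.loc[ok]

    results = []
    for k, metric in enumerate(metrics):
        metric = MetricName.coerce(metric)
        cols, meta = {}, []
        for tract, interval, series in _responses(ds, level, tracts, metric,
                                                  clusters or {}):
            key = (tract, interval)
            cols[key] = series
            meta.append(key)
        if not cols:
            continue
        block = pd.DataFrame(cols).dropna(axis=0)
        frame = frame0.loc[frame0.index.intersection(block.index)]
        block = block.loc[frame.index]
        if len(frame) < len(terms) + 2:
            raise SampleSizeError(
                f"too few usable subjects ({len(frame)}) for scope {scope}")
        cfg_m = PermutationConfig(cfg.n_perm, cfg.seed + 100 + k, cfg.scheme)
        fits, p_corr, covs = _fit_family(block, frame, terms, test_term, cfg_m)
        score_vals = frame[score].to_numpy(float)
        for j, (tract, interval) in enumerate(meta):
            ts = fits[j].term(test_term)
            results.append(AssociationResult(
                level=level, tract=tract, metric=metric,
                group_scope=scope, score_name=score,
                beta=ts.beta, se=ts.se, t=ts.t, df=ts.df,
                p_param=ts.p_param, p_perm=float(p_corr[j]),
                partial_r2=partial_r2(score_vals,
                                      block.iloc[:, j].to_numpy(float), covs),
                node_interval=interval,
                selection_dependent=(level == "cluster")))
    return results


def severity_assoc(ds: TractProfileDataset, demographics: pd.DataFrame,
                   clusters: dict | None = None,
                   cfg: PermutationConfig | None = None,
                   tracts=DEFAULT_TRACTS, metrics=METRICS,
                   score: str = "ados_total") -> list[AssociationResult]:
    """Associations with ASD symptom severity (ADOS total), ASD group only.

    Runs ``metric ~ ADOS total + age + sex`` at tract level and, when
    clusters are supplied, on the cluster segment means too.
    """
    asd = demographics.loc[(demographics["group"] == "ASD")
                           & demographics[score].notna()]
    if len(asd) < 5:
        raise SampleSizeError(
            f"severity association needs >= 5 ASD subjects with {score}, "
            f"have {len(asd)}")
    out = behavior_assoc(ds, asd, score, "ASD", "tract", None, cfg,
                         tracts, metrics)
    if clusters is not None and any(clusters.values()):
        out += behavior_assoc(ds, asd, score, "ASD", "cluster", clusters,
                              cfg, tracts, metrics)
    return out
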