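"""Hemispheric lateralization of tract metrics.

The lateralization index of a tract pair is ``LI = (R - L) / (R + L)``
computed on the tract-wise means (mean over the node grid per
hemisphere first, then LI).  Positive LI means the right hemisphere
carries the larger value.  Three analyses mirror the study design:

1. one-sample t-tests of mean LI against zero within each group, with
   a sign-flip permutation null corrected across the tract pairs of
   each metric by the max-statistic method;
2. between-group LI comparison, ``LI ~ group + age + sex``;
3. LI-behaviour association within each group,
   ``LI ~ score + age + sex``, plus the group x score interaction model
   ``LI ~ group * score + age + sex``.

Direction labels follow the metric's semantics: for FA a significantly
*positive* t means rightward lateralization; for the diffusivities
(MD, RD, AD) larger values mean greater diffusivity, so a significantly
*negative* t means rightward lateralization (greater integrity on the
right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import METRICS, MetricName, TRACT_PAIRS, TractProfileDataset
from .errors import DegenerateDataError, SampleSizeError, TractStatsError
from .linmod import (
    DesignMatrix,
    PermutationConfig,
    RegressionResult,
    build_design,
    maxstat_correct,
    ols_fit,
    one_sample_t,
    perm_null_ts,
    signflip_null_ts,
)

logger = logging.getLogger(__name__)


@dataclass
class LateralityResult:
    """One-sample lateralization test for one (tract pair, metric, group)."""
    tract_pair: str
    metric: MetricName
    group: str
    n: int
    mean_li: float
    sd_li: float
    t: float
    df: int
    p_raw: float
    p_corrected: float
    direction: str  # "leftward" | "rightward" | "none"


def compute_li(left: float, right: float) -> float:
    """(R - L) / (R + L); in (-1, 1) for positive inputs."""
    denom = left + right
    if denom <= 0:
        raise DegenerateDataError(
            f"LI undefined: left + right = {denom} is not positive")
    return (right - left) / denom


def direction_label(metric: MetricName, t: float, significant: bool) -> str:
    """Map a signed t to a lateralization direction under the metric's
    semantics; non-significant tests get 'none'."""
    if not significant or t == 0:
        return "none"
    if metric is MetricName.FA:
        return "rightward" if t > 0 else "leftward"
    return "rightward" if t < 0 else "leftward"


def hemi_tracts(pair: str) -> tuple[str, str]:
    """Default (left, right) tract names for a pair label."""
    return f"L_{pair}", f"R_{pair}"


def li_table(ds: TractProfileDataset, subjects=None, pairs=TRACT_PAIRS,
             metrics=METRICS, pair_map=None) -> pd.DataFrame:
    """Per-subject LI for every tract pair and metric, on tract means.

    Returns a tidy frame (subject, tract_pair, metric, li).  Subjects
    missing either hemisphere of a pair are excluded from that pair
    with a logged warning.
    """
    subjects = list(subjects) if subjects is not None else list(ds.subjects)
    pair_map = pair_map or {p: hemi_tracts(p) for p in pairs}
    rows = []
    for pair in pairs:
        ltr, rtr = pair_map[pair]
        for metric in metrics:
            metric = MetricName.coerce(metric)
            lmeans = ds.tract_means(ltr, metric)
            rmeans = ds.tract_means(rtr, metric)
            for s in subjects:
                lv, rv = lmeans.get(s, np.nan), rmeans.get(s, np.nan)
                if np.isnan(lv) or np.isnan(rv):
                    logger.warning(
                        "subject %s missing a hemisphere of %s; excluded "
                        "from LI", s, pair)
                    continue
                rows.append({"subject": s, "tract_pair": pair,
                             "metric": metric.value,
                             "li": compute_li(lv, rv)})
    return pd.DataFrame(rows, columns=["subject", "tract_pair", "metric", "li"])


def _li_wide(li_tab: pd.DataFrame, metric: str, pairs) -> pd.DataFrame:
    """Subjects x pairs LI matrix for one metric (complete cases only)."""
    sub = li_tab[li_tab["metric"] == metric]
    wide = sub.pivot(index="subject", columns="tract_pair", values="li")
    wide = wide.reindex(columns=[p for p in pairs if p in wide.columns])
    return wide.dropna(axis=0)


def li_one_sample(li_tab: pd.DataFrame, group_subjects, group_label: str,
                  cfg: PermutationConfig, alpha: float = 0.05,
                  pairs=TRACT_PAIRS, metrics=METRICS) -> list[LateralityResult]:
    """One-sample LI tests for one group with sign-flip permutation FWE.

    The correction family is the set of tract pairs within each metric;
    all pairs of a metric share the sign-flip sequence and the corrected
    p compares each observed |t| to the family-wise max |t| null.
    """
    group_subjects = set(group_subjects)
    rng = cfg.rng()
    results = []
    for metric in metrics:
        metric = MetricName.coerce(metric)
        wide = _li_wide(li_tab, metric.value, pairs)
        wide = wide.loc[wide.index.isin(group_subjects)]
        n = len(wide)
        if n < 2:
            raise SampleSizeError(
                f"group {group_label}: only {n} subjects with complete LI "
                f"for metric {metric.value}")
        V = wide.to_numpy()
        obs = np.empty(V.shape[1])
        stats_per_pair = []
        for j, pair in enumerate(wide.columns):
            t, df, p_raw = one_sample_t(V[:, j])
            obs[j] = t
            stats_per_pair.append((pair, t, df, p_raw))
        nulls = signflip_null_ts(V, cfg.n_perm, rng)
        p_corr = maxstat_correct(obs, nulls)
        for j, (pair, t, df, p_raw) in enumerate(stats_per_pair):
            results.append(LateralityResult(
                tract_pair=pair, metric=metric, group=group_label, n=n,
                mean_li=float(V[:, j].mean()),
                sd_li=float(V[:, j].std(ddof=1)),
                t=t, df=df, p_raw=p_raw, p_corrected=float(p_corr[j]),
                direction=direction_label(metric, t, p_corr[j] < alpha)))
    return results


def laterality_table(results: list[LateralityResult]) -> pd.DataFrame:
    """Tidy export mirroring a per-group LI summary table."""
    return pd.DataFrame([{
        "tract_pair": r.tract_pair, "metric": r.metric.value,
        "group": r.group, "n": r.n, "mean_li": r.mean_li, "sd_li": r.sd_li,
        "t": r.t, "df": r.df, "p_raw": r.p_raw,
        "p_corrected": r.p_corrected, "direction": r.direction,
    } for r in results])


def _family_regression(responses: pd.DataFrame, frame: pd.DataFrame,
                       terms, test_term: str,
                       cfg: PermutationConfig) -> dict[str, RegressionResult]:
    """Fit one model per response column and correct the tested term's
    permutation p across the columns (max-statistic, shared permutations)."""
    X = build_design(frame, terms)
    Y = responses.to_numpy(float)
    obs_t = np.empty(Y.shape[1])
    fits = {}
    for j, col in enumerate(responses.columns):
        fit = ols_fit(X, Y[:, j])
        obs_t[j] = fit.term(test_term).t
        fits[col] = fit
    nulls = perm_null_ts(X, Y, test_term, cfg)
    p_corr = maxstat_correct(obs_t, nulls)
    for j, col in enumerate(responses.columns):
        fits[col].p_perm[test_term] = float(p_corr[j])
    return fits


def _aligned(li_tab, demographics, metric, pairs, subjects=None):
    wide = _li_wide(li_tab, metric, pairs)
    if subjects is not None:
        wide = wide.loc[wide.index.isin(set(subjects))]
    frame = demographics.loc[demographics.index.intersection(wide.index)]
    wide = wide.loc[frame.index]
    return wide, frame


def li_group_compare(li_tab: pd.DataFrame, demographics: pd.DataFrame,
                     cfg: PermutationConfig, pairs=TRACT_PAIRS,
                     metrics=METRICS) -> dict:
    """Between-group LI comparison: LI ~ group + age + sex per (pair, metric).

    Returns {(pair, metric): RegressionResult} with the group term's
    permutation p corrected across the pairs of each metric.
    """
    out = {}
    terms = ["intercept", "group_asd", "age", "sex_f"]
    for k, metric in enumerate(metrics):
        metric = MetricName.coerce(metric)
        wide, frame = _aligned(li_tab, demographics, metric.value, pairs)
        if frame["group_asd"].nunique() < 2:
            raise SampleSizeError("both groups required for LI comparison")
        cfg_m = PermutationConfig(cfg.n_perm, cfg.seed + k, cfg.scheme)
        fits = _family_regression(wide, frame, terms, "group_asd", cfg_m)
        for pair, fit in fits.items():
            out[(pair, metric.value)] = fit
    return out


def li_behavior(li_tab: pd.DataFrame, demographics: pd.DataFrame,
                score: str, cfg: PermutationConfig, pairs=TRACT_PAIRS,
                metrics=METRICS) -> dict:
    """LI-behaviour associations within groups plus group x score interaction.

    Returns {(pair, metric, scope): RegressionResult} where scope is
    "TD", "ASD" (model LI ~ score + age + sex within the group) or
    "interaction" (LI ~ group * score + age + sex on both groups, the
    product term tested).  Each scope's tested term is permutation-
    corrected across the pairs of its metric.
    """
    if score not in demographics.columns:
        raise TractStatsError(f"score column {score!r} not in demographics")
    out = {}
    for k, metric in enumerate(metrics):
        metric = MetricName.coerce(metric)
        for s, scope in enumerate(("TD", "ASD", "interaction")):
            if scope == "interaction":
                wide, frame = _aligned(li_tab, demographics, metric.value, pairs)
                terms = ["intercept", "group_asd", score,
                         f"group_asd:{score}", "age", "sex_f"]
                test_term = f"group_asd:{score}"
            else:
                members = demographics.index[demographics["group"] == scope]
                wide, frame = _aligned(li_tab, demographics, metric.value,
                                       pairs, subjects=members)
                terms = ["intercept", score, "age", "sex_f"]
                test_term = score
            ok = frame[score].notna()
            if not ok.all():
                logger.warning("dropping %d subjects lacking %s",
                               (~ok).sum(), score)
                frame = frame.loc[ok]
                wide = wide.loc[frame.index]
            if len(frame) < len(terms) + 1:
                logger.warning("scope %s skipped for metric %s: too few "
                               "subjects", scope, metric.value)
                continue
            cfg_ms = PermutationConfig(cfg.n_perm, cfg.seed + 16 * k + s,
                                       cfg.scheme)
            fits = _family_regression(wide, frame, terms, test_term, cfg_ms)
            for pair, fit in fits.items():
                out[(pair, metric.value, scope)] = fit
    return out
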