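"""Synthetic tract-profile and demographics generator.

Emulates the statistical structure the analysis modules assume: two
groups (TD / ASD, defaults n = 22 / 28, ages 1.5–6.07 years), eight
hemisphere-paired language tracts x 100 nodes x four coupled metrics,
smooth node-autocorrelated profiles, hemispheric asymmetry, localized
group effects on node intervals, age/sex covariate effects, and
behaviour scores coupled to tract metrics with configurable slopes.

Generative model
----------------
The axial (lambda1 = AD) and radial (lambda2 = RD) diffusivity fields
are primary; MD = (AD + 2 RD) / 3 and FA = (AD - RD) /
sqrt(AD^2 + 2 RD^2) (the prolate-tensor form with lambda2 = lambda3)
are derived, so RD <= AD, MD's identity, and FA in [0, 1] hold by
construction.  Each field is

    baseline(node) * tract factor * hemisphere-asymmetry factor
    * subject factors * (1 + covariate trend) * (1 + GP noise(node))

with a squared-exponential node-correlation kernel (default length 10
nodes) for the within-profile noise.  Group effects, metric-behaviour
links and FA asymmetry targets are then layered on the derived metric
arrays: AD effects act on lambda1, RD effects on lambda2, MD effects on
both (shifting MD by the stated amplitude), and FA effects act on the
derived FA with a smooth squashing clamp keeping it inside [0, 1].

Effect amplitudes may be given in metric units (``amplitude``) or as a
standardized ``d`` (units of the pre-effect between-subject node SD,
measured on the generated sample itself, so d is exact for the
realized nuisance structure).  A truth record captures every injected
parameter; identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    DEFAULT_TRACTS,
    GDS_DOMAINS,
    METRICS,
    MetricName,
    SubjectRecord,
    TRACT_PAIRS,
    TractProfileDataset,
)
from .errors import ConfigError

# -- study-scale default conditions ----------------------------------------

#: group sizes
N_TD, N_ASD = 22, 28

#: age models per group: (mean, sd, low, high) in years
AGE_MODELS = {"TD": (2.97, 1.31, 1.50, 5.81), "ASD": (3.24, 1.26, 1.67, 6.07)}

#: male fraction per group (17/22 and 24/28)
SEX_RATIO_M = {"TD": 17 / 22, "ASD": 24 / 28}

#: behaviour score models per group: (mean, sd, low, high, integer?)
SCORE_MODELS = {
    "TD": {
        "abc": (23.59, 7.7, 8, 40, True),
        "gds_language": (93.51, 4.03, 83.3, 101, False),
        "gds_personal_social": (94.07, 4.01, 83.3, 103, False),
        "gds_gross_motor": (98.38, 5.5, 83, 107, False),
        "gds_fine_motor": (96.43, 4.82, 86, 105, False),
        "gds_adaptive": (95.44, 4.09, 88, 105, False),
        "gds_total": (95.08, 3.85, 86.1, 100.8, False),
    },
    "ASD": {
        "abc": (70.25, 14.13, 53, 107, True),
        "gds_language": (46.8, 11.9, 23.6, 70.7, False),
        "gds_personal_social": (55.59, 9.15, 32.4, 70.2, False),
        "gds_gross_motor": (76.17, 7.07, 64.1, 89.3, False),
        "gds_fine_motor": (68.72, 9.61, 45.9, 84.2, False),
        "gds_adaptive": (60.54, 11.39, 38.6, 73.7, False),
        "gds_total": (61.58, 7.99, 43.5, 73.6, False),
        "ados_sa": (12.75, 3.69, 7, 22, True),
        "ados_rrb": (1.18, 0.77, 0, 3, True),
    },
}

#: default mean LI per (pair, metric, group); MD asymmetry is implied by
#: the AD and RD eigenvalue scalings and is not set directly.
DEFAULT_ASYMMETRY = {
    ("AF", "FA"): {"TD": -0.0029, "ASD": -0.0054},
    ("IFOF", "FA"): {"TD": 0.0040, "ASD": -0.0021},
    ("ILF", "FA"): {"TD": 0.0063, "ASD": 0.0047},
    ("SLF", "FA"): {"TD": 0.0086, "ASD": 0.0140},
    ("AF", "RD"): {"TD": -0.0034, "ASD": -0.0041},
    ("IFOF", "RD"): {"TD": -0.0067, "ASD": -0.0060},
    ("ILF", "RD"): {"TD": -0.0120, "ASD": -0.0111},
    ("SLF", "RD"): {"TD": -0.0145, "ASD": -0.0139},
    ("AF", "AD"): {"TD": -0.0057, "ASD": -0.0059},
    ("IFOF", "AD"): {"TD": -0.0040, "ASD": -0.0082},
    ("ILF", "AD"): {"TD": -0.0069, "ASD": -0.0064},
    ("SLF", "AD"): {"TD": -0.0038, "ASD": -0.0003},
}

#: per-pair multiplicative size differences (both hemispheres, both fields)
TRACT_FACTORS = {"AF": 1.00, "IFOF": 1.03, "ILF": 0.97, "SLF": 1.01}


@dataclass
class GroupEffect:
    """Localized group difference: ASD minus TD on one node interval.

    Exactly one of ``amplitude`` (metric units) or ``d`` (units of the
    pre-effect between-subject node SD) must be set.  The effect is
    full-strength on [node_start, node_end] and tapers to half at the
    single node beyond each edge.
    """
    tract: str
    metric: str
    node_start: int
    node_end: int
    amplitude: float | None = None
    d: float | None = None


@dataclass
class BehaviorLink:
    """Linear coupling of a tract metric to a behaviour score.

    Adds ``slope * (score - group mean score)`` to every node of the
    tract (plus optional extra per-subject noise), so a tract-wise
    regression of the metric on the score recovers ``slope`` in
    expectation.  ``group`` restricts the link to one group (None =
    both).
    """
    score: str
    tract: str
    metric: str
    slope: float
    noise_sd: float = 0.0
    group: str | None = None


@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults are the study-scale conditions."""
    n_td: int = N_TD
    n_asd: int = N_ASD
    node_grid: int = 100
    seed: int = 0
    # baseline eigenvalue fields, mm^2/s
    axial_base: float = 1.15e-3
    radial_base: float = 0.55e-3
    # noise layers (relative scales)
    subject_sd_shared: float = 0.05   # per (subject, pair): both hemis+fields
    subject_sd_eigen: float = 0.015   # per (subject, pair), each field
    hemi_sd: float = 0.010            # per (subject, tract), each field
    node_noise_sd: float = 0.03       # GP field, each eigenvalue
    corr_length: float = 10.0         # nodes
    # covariate trends (relative per year / for female sex)
    age_slope_axial: float = -0.020
    age_slope_radial: float = -0.030
    sex_effect: float = 0.005
    # injected structure
    asymmetry: dict = field(default_factory=lambda: dict(DEFAULT_ASYMMETRY))
    effects: list = field(default_factory=list)
    behavior_links: list = field(default_factory=list)
    age_models: dict = field(default_factory=lambda: dict(AGE_MODELS))
    sex_ratio_m: dict = field(default_factory=lambda: dict(SEX_RATIO_M))
    score_models: dict = field(
        default_factory=lambda: {g: dict(m) for g, m in SCORE_MODELS.items()})

    def __post_init__(self):
        if self.n_td < 2 or self.n_asd < 2:
            raise ConfigError("need at least 2 subjects per group")
        if self.node_grid < 2:
            raise ConfigError("node grid must have >= 2 nodes")
        for layer in ("subject_sd_shared", "subject_sd_eigen", "node_noise_sd"):
            if getattr(self, layer) < 0:
                raise ConfigError(f"{layer} must be >= 0")
        for e in self.effects:
            if not (0 <= e.node_start <= e.node_end < self.node_grid):
                raise ConfigError(
                    f"effect interval ({e.node_start}, {e.node_end}) is off "
                    f"the 0..{self.node_grid - 1} grid")
            if (e.amplitude is None) == (e.d is None):
                raise ConfigError(
                    "set exactly one of amplitude or d per effect")
            if e.amplitude is not None and not np.isfinite(e.amplitude):
                raise ConfigError("effect amplitude must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["effects"] = [GroupEffect(**e) for e in d.get("effects", [])]
        d["behavior_links"] = [BehaviorLink(**l)
                               for l in d.get("behavior_links", [])]
        if "asymmetry" in d and isinstance(d["asymmetry"], list):
            d["asymmetry"] = {(a["pair"], a["metric"]): a["li"]
                              for a in d["asymmetry"]}
        return cls(**d)


# -- helpers ----------------------------------------------------------------

def smooth_clip01(x: np.ndarray, margin: float = 0.02) -> np.ndarray:
    """C1 squashing clamp of x into (0, 1): identity on [margin, 1 - margin],
    smooth saturation outside."""
    y = np.asarray(x, float).copy()
    m = margin
    low = y < m
    y[low] = m * m / (2 * m - y[low])
    u = 1.0 - y
    high = u < m
    y[high] = 1.0 - m * m / (2 * m - u[high])
    return y


def _gp_chol(n_nodes: int, corr_length: float) -> np.ndarray:
    idx = np.arange(n_nodes)
    K = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / corr_length) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    return np.linalg.cholesky(K)


def _truncnorm(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def _effect_window(n_nodes: int, start: int, end: int) -> np.ndarray:
    """Full strength on [start, end], half at one node beyond each edge."""
    w = np.zeros(n_nodes)
    w[start:end + 1] = 1.0
    if start - 1 >= 0:
        w[start - 1] = 0.5
    if end + 1 < n_nodes:
        w[end + 1] = 0.5
    return w


def _prolate_fa(ad: np.ndarray, rd: np.ndarray) -> np.ndarray:
    return (ad - rd) / np.sqrt(ad ** 2 + 2 * rd ** 2)


def _make_subjects(spec: SimulationSpec,
                   rng: np.random.Generator) -> list[SubjectRecord]:
    records = []
    for group, n in (("TD", spec.n_td), ("ASD", spec.n_asd)):
        mean, sd, lo, hi = spec.age_models[group]
        ages = _truncnorm(rng, mean, sd, lo, hi, n)
        n_m = int(round(n * spec.sex_ratio_m[group]))
        sexes = rng.permutation(["M"] * n_m + ["F"] * (n - n_m))
        models = spec.score_models[group]
        draws = {}
        for name, (m, s, a, b, integer) in models.items():
            v = _truncnorm(rng, m, s, a, b, n)
            draws[name] = np.clip(np.round(v), a, b) if integer else v
        for i in range(n):
            gds = {dom: float(draws[f"gds_{dom}"][i])
                   for dom in GDS_DOMAINS if f"gds_{dom}" in draws}
            ados = None
            if "ados_sa" in draws:
                sa = float(draws["ados_sa"][i])
                rrb = float(draws["ados_rrb"][i])
                ados = {"SA": sa, "RRB": rrb, "total": sa + rrb}
            records.append(SubjectRecord(
                id=f"{group}{i + 1:03d}", group=group, age=float(ages[i]),
                sex=str(sexes[i]),
                abc_total=int(draws["abc"][i]) if "abc" in draws else None,
                gds=gds, ados=ados))
    return records


def _asym_mean(spec, pair, metric, group) -> float:
    val = spec.asymmetry.get((pair, metric), 0.0)
    if isinstance(val, dict):
        return float(val.get(group, 0.0))
    return float(val)


# -- main entry points ------------------------------------------------------

def generate(spec: SimulationSpec | None = None
             ) -> tuple[TractProfileDataset, list[SubjectRecord], dict]:
    """Generate (dataset, subject records, truth record) from a spec."""
    spec = spec if spec is not None else SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    records = _make_subjects(spec, rng)
    n = len(records)
    groups = np.array([r.group for r in records])
    ages = np.array([r.age for r in records])
    sex_f = np.array([1.0 if r.sex == "F" else 0.0 for r in records])
    age_c = ages - ages.mean()

    nn = spec.node_grid
    x = np.linspace(0.0, 1.0, nn)
    base_ax = spec.axial_base * (1 + 0.12 * np.sin(np.pi * x))
    base_rad = spec.radial_base * (1 - 0.08 * np.cos(2 * np.pi * x))
    L = _gp_chol(nn, spec.corr_length)

    tracts = list(DEFAULT_TRACTS)
    AD = np.empty((n, len(tracts), nn))
    RD = np.empty_like(AD)
    tract_idx0 = {t: i for i, t in enumerate(tracts)}
    trend_ax = 1 + spec.age_slope_axial * age_c + spec.sex_effect * sex_f
    trend_rad = 1 + spec.age_slope_radial * age_c + spec.sex_effect * sex_f
    for pair in TRACT_PAIRS:
        tf = TRACT_FACTORS.get(pair, 1.0)
        mu_ad = np.array([_asym_mean(spec, pair, "AD", g) for g in groups])
        mu_rd = np.array([_asym_mean(spec, pair, "RD", g) for g in groups])
        mu_md = np.array([_asym_mean(spec, pair, "MD", g) for g in groups])
        # pair-common subject factors: shared across hemispheres, so they
        # cancel in the LI (and the size factor cancels in FA too)
        common = 1 + rng.normal(0, spec.subject_sd_shared, n)
        g1 = 1 + rng.normal(0, spec.subject_sd_eigen, n)
        g2 = 1 + rng.normal(0, spec.subject_sd_eigen, n)
        for hemi, side in (("L", -1.0), ("R", +1.0)):
            t_idx = tract_idx0[f"{hemi}_{pair}"]
            h1 = 1 + rng.normal(0, spec.hemi_sd, n)
            h2 = 1 + rng.normal(0, spec.hemi_sd, n)
            e1 = (rng.standard_normal((n, nn)) @ L.T) * spec.node_noise_sd
            e2 = (rng.standard_normal((n, nn)) @ L.T) * spec.node_noise_sd
            s_ax = (common * g1 * h1 * trend_ax
                    * (1 + side * mu_ad) * (1 + side * mu_md))
            s_rad = (common * g2 * h2 * trend_rad
                     * (1 + side * mu_rd) * (1 + side * mu_md))
            AD[:, t_idx] = base_ax[None, :] * tf * s_ax[:, None] * (1 + e1)
            RD[:, t_idx] = base_rad[None, :] * tf * s_rad[:, None] * (1 + e2)
    RD = np.minimum(RD, 0.995 * AD)

    # pre-effect metric arrays define the standardized-amplitude scale
    MD0 = (AD + 2 * RD) / 3
    FA0 = _prolate_fa(AD, RD)
    pre = {"AD": AD.copy(), "RD": RD.copy(), "MD": MD0, "FA": FA0}

    asd = (groups == "ASD").astype(float)
    tract_idx = {t: i for i, t in enumerate(tracts)}
    fa_delta = np.zeros_like(AD)   # additive FA layer, applied after derivation
    truth_effects = []
    for eff in spec.effects:
        ti = tract_idx[eff.tract]
        w = _effect_window(nn, eff.node_start, eff.node_end)
        if eff.amplitude is not None:
            amp = float(eff.amplitude)
        else:
            node_sd = pre[eff.metric][:, ti,
                                      eff.node_start:eff.node_end + 1].std(
                axis=0, ddof=1)
            amp = float(eff.d * node_sd.mean())
        bump = asd[:, None] * w[None, :] * amp
        if eff.metric == "AD":
            AD[:, ti] += bump
        elif eff.metric == "RD":
            RD[:, ti] += bump
        elif eff.metric == "MD":
            AD[:, ti] += bump
            RD[:, ti] += bump
        elif eff.metric == "FA":
            fa_delta[:, ti] += bump
        else:
            raise ConfigError(f"unknown metric {eff.metric!r} in effect")
        truth_effects.append({**asdict(eff), "amplitude_realized": amp})

    truth_links = []
    for link in spec.behavior_links:
        ti = tract_idx[link.tract]
        score = _score_vector(records, link.score)
        in_scope = np.ones(n, bool) if link.group is None else \
            (groups == link.group)
        sc = np.where(in_scope & ~np.isnan(score), score, np.nan)
        centered = np.where(np.isnan(sc), 0.0, sc - np.nanmean(sc))
        delta = link.slope * centered
        if link.noise_sd:
            delta = delta + np.where(
                np.isnan(sc), 0.0, rng.normal(0, link.noise_sd, n))
        if link.metric == "AD":
            AD[:, ti] += delta[:, None]
        elif link.metric == "RD":
            RD[:, ti] += delta[:, None]
        elif link.metric == "MD":
            AD[:, ti] += delta[:, None]
            RD[:, ti] += delta[:, None]
        elif link.metric == "FA":
            fa_delta[:, ti] += delta[:, None]
        else:
            raise ConfigError(f"unknown metric {link.metric!r} in link")
        truth_links.append(asdict(link))

    RD = np.minimum(RD, 0.995 * AD)
    MD = (AD + 2 * RD) / 3
    FA = _prolate_fa(AD, RD)

    # FA asymmetry: residual multiplicative factor on top of what the
    # eigenvalue scalings already imply for the noise-free baseline
    fa_li_implied = {}
    for pair in TRACT_PAIRS:
        for group in ("TD", "ASD"):
            mu_t = {m: _asym_mean(spec, pair, m, group)
                    for m in ("AD", "RD", "MD", "FA")}
            fa_r = _prolate_fa(
                base_ax * (1 + mu_t["AD"]) * (1 + mu_t["MD"]),
                base_rad * (1 + mu_t["RD"]) * (1 + mu_t["MD"])).mean()
            fa_l = _prolate_fa(
                base_ax * (1 - mu_t["AD"]) * (1 - mu_t["MD"]),
                base_rad * (1 - mu_t["RD"]) * (1 - mu_t["MD"])).mean()
            li_implied = (fa_r - fa_l) / (fa_r + fa_l)
            fa_li_implied[(pair, group)] = li_implied
            members = groups == group
            ti_l, ti_r = tract_idx[f"L_{pair}"], tract_idx[f"R_{pair}"]
            FA[members, ti_r] *= (1 + mu_t["FA"]) / (1 + li_implied)
            FA[members, ti_l] *= (1 - mu_t["FA"]) / (1 - li_implied)

    FA = smooth_clip01(FA + fa_delta)

    values = np.stack(
        [{"FA": FA, "MD": MD, "RD": RD, "AD": AD}[m.value] for m in METRICS],
        axis=-1)
    ds = TractProfileDataset([r.id for r in records], tracts,
                             list(range(nn)), METRICS, values)
    truth = {
        "seed": spec.seed,
        "n_td": spec.n_td, "n_asd": spec.n_asd, "node_grid": nn,
        "effects": truth_effects,
        "behavior_links": truth_links,
        "asymmetry": {f"{p}:{m}": v if not isinstance(v, dict) else dict(v)
                      for (p, m), v in spec.asymmetry.items()},
        "fa_li_implied_by_eigen_scaling": {
            f"{p}:{g}": li for (p, g), li in fa_li_implied.items()},
        "noise": {"subject_sd_shared": spec.subject_sd_shared,
                  "subject_sd_eigen": spec.subject_sd_eigen,
                  "node_noise_sd": spec.node_noise_sd,
                  "corr_length": spec.corr_length},
        "fa_clip_margin": 0.02,
    }
    return ds, records, truth


def _score_vector(records, score: str) -> np.ndarray:
    out = np.full(len(records), np.nan)
    for i, r in enumerate(records):
        if score == "abc":
            v = r.abc_total
        elif score.startswith("gds_"):
            v = r.gds.get(score[4:])
        elif score.startswith("ados_"):
            key = {"sa": "SA", "rrb": "RRB", "total": "total"}[score[5:]]
            v = (r.ados or {}).get(key)
        else:
            raise ConfigError(f"unknown score {score!r}")
        if v is not None:
            out[i] = v
    return out


def null_spec(spec: SimulationSpec | None = None) -> SimulationSpec:
    """Copy of a spec with all effects, links and asymmetries zeroed."""
    spec = spec if spec is not None else SimulationSpec()
    d = asdict(spec)
    d["effects"], d["behavior_links"], d["asymmetry"] = [], [], {}
    d["age_models"] = spec.age_models
    d["sex_ratio_m"] = spec.sex_ratio_m
    d["score_models"] = spec.score_models
    return SimulationSpec(**d)


def null_dataset(spec: SimulationSpec | None = None):
    """Dataset sharing all nuisance structure with ``generate`` but with
    zero group effects, zero asymmetry and no behaviour links."""
    return generate(null_spec(spec))
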