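"""Domain types and I/O for AFQ-style tract-profile and demographics tables.

The central container is :class:`TractProfileDataset`: per-subject,
per-tract profiles of the four diffusion-tensor metrics (FA, MD, RD, AD)
sampled at a fixed grid of equidistant nodes along each tract (100 by
default, the pyAFQ convention).  Input is the long ("tidy") profile
format that ``ParticipantAFQ.export('profiles')`` writes: one row per
subject x tract x node, one column per metric.

A (subject, tract) profile is either complete on the node grid or absent
as a whole; ragged profiles are rejected at read time.  Node identifiers
are taken verbatim from the input file and treated as ordinal positions,
so reports echo whatever labelling the file uses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DemographicsError,
    GridRangeError,
    MissingProfileError,
    ProfileValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Hemisphere-paired language tracts analysed by default.
TRACT_PAIRS = ("AF", "IFOF", "ILF", "SLF")
DEFAULT_TRACTS = tuple(f"{h}_{t}" for t in TRACT_PAIRS for h in ("L", "R"))

#: Default column names of a pyAFQ profile export.
DEFAULT_PROFILE_SCHEMA = {
    "subject": "subjectID",
    "tract": "tractID",
    "node": "nodeID",
    "FA": "dti_fa",
    "MD": "dti_md",
    "RD": "dti_rd",
    "AD": "dti_ad",
}

DEMOGRAPHICS_COLUMNS = (
    "id", "group", "age", "sex", "abc",
    "gds_language", "gds_personal_social", "gds_gross_motor",
    "gds_fine_motor", "gds_adaptive", "gds_total",
    "ados_sa", "ados_rrb", "ados_total",
)

GDS_DOMAINS = ("language", "personal_social", "gross_motor",
               "fine_motor", "adaptive", "total")


class MetricName(enum.Enum):
    """The four diffusion-tensor metrics.

    ``FA`` is dimensionless in [0, 1] and larger means greater
    anisotropy; the three diffusivities (mm^2/s) are strictly positive
    and larger means greater diffusivity.
    """

    FA = "FA"
    MD = "MD"
    RD = "RD"
    AD = "AD"

    @property
    def is_diffusivity(self) -> bool:
        return self is not MetricName.FA

    @classmethod
    def coerce(cls, value) -> "MetricName":
        if isinstance(value, cls):
            return value
        return cls[str(value).upper()]


METRICS = tuple(MetricName)


def _parse_group(value) -> str:
    s = str(value).strip().upper()
    if s in ("TD", "CONTROL", "TYPICAL"):
        return "TD"
    if s == "ASD":
        return "ASD"
    raise DemographicsError(f"unknown group label {value!r} (expected TD or ASD)")


def _parse_sex(value) -> str:
    s = str(value).strip().upper()
    if s in ("M", "MALE"):
        return "M"
    if s in ("F", "FEMALE"):
        return "F"
    raise DemographicsError(f"unknown sex label {value!r} (expected M or F)")


@dataclass
class SubjectRecord:
    """One participant: group membership, covariates and behaviour scores.

    ``ados`` is present only for ASD subjects; when social-affect (SA),
    restricted-and-repetitive-behaviour (RRB) and total scores are all
    given, total must equal SA + RRB.
    """

    id: str
    group: str          # "TD" | "ASD"
    age: float          # years
    sex: str            # "M" | "F"
    abc_total: int | None = None
    gds: dict = field(default_factory=dict)
    ados: dict | None = None

    def __post_init__(self):
        self.group = _parse_group(self.group)
        self.sex = _parse_sex(self.sex)
        if self.age is None or not np.isfinite(self.age) or self.age <= 0:
            raise DemographicsError(f"subject {self.id}: age must be a positive number")
        if self.abc_total is not None and self.abc_total < 0:
            raise DemographicsError(f"subject {self.id}: ABC total must be >= 0")
        if self.ados is not None:
            if self.group != "ASD":
                raise DemographicsError(
                    f"subject {self.id}: ADOS scores present but group is {self.group}"
                )
            sa, rrb, tot = (self.ados.get(k) for k in ("SA", "RRB", "total"))
            if sa is not None and rrb is not None and tot is not None:
                if abs((sa + rrb) - tot) > 1e-9:
                    raise DemographicsError(
                        f"subject {self.id}: ADOS total {tot} != SA + RRB = {sa + rrb}"
                    )


class TractProfileDataset:
    """Along-tract metric profiles on a shared node grid.

    Values are stored dense as ``(n_subjects, n_tracts, n_nodes,
    n_metrics)`` with NaN marking whole-profile absence; the class
    guarantees there is no partial (ragged) profile.
    """

    def __init__(self, subjects, tracts, nodes, metrics, values, validate=True):
        self.subjects = list(subjects)
        self.tracts = list(tracts)
        self.nodes = list(nodes)
        self.metrics = [MetricName.coerce(m) for m in metrics]
        self.values = np.asarray(values, dtype=float)
        expected = (len(self.subjects), len(self.tracts),
                    len(self.nodes), len(self.metrics))
        if self.values.shape != expected:
            raise ProfileValidationError(
                f"values shape {self.values.shape} != {expected}")
        self._subject_idx = {s: i for i, s in enumerate(self.subjects)}
        self._tract_idx = {t: i for i, t in enumerate(self.tracts)}
        self._node_idx = {n: i for i, n in enumerate(self.nodes)}
        self._metric_idx = {m: i for i, m in enumerate(self.metrics)}
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self):
        v = self.values
        nan = np.isnan(v)
        # a profile is all-NaN (missing) or all-finite; anything else is ragged
        per_profile = nan.reshape(v.shape[0], v.shape[1], -1)
        frac = per_profile.mean(axis=2)
        ragged = np.argwhere((frac > 0) & (frac < 1))
        if len(ragged):
            pairs = [(self.subjects[i], self.tracts[j]) for i, j in ragged]
            raise ProfileValidationError(
                f"ragged profiles (incomplete node grid) for: {pairs[:10]}",
                details=pairs)
        for m, mi in self._metric_idx.items():
            sl = v[..., mi]
            with np.errstate(invalid="ignore"):
                if m is MetricName.FA:
                    bad = np.argwhere((sl < 0) | (sl > 1))
                    what = "FA outside [0, 1]"
                else:
                    bad = np.argwhere(sl <= 0)
                    what = f"{m.value} not strictly positive"
            if len(bad):
                cells = [(self.subjects[i], self.tracts[j], self.nodes[k])
                         for i, j, k in bad[:10]]
                raise ProfileValidationError(f"{what} at cells: {cells}",
                                             details=cells)
        if MetricName.RD in self._metric_idx and MetricName.AD in self._metric_idx:
            rd = v[..., self._metric_idx[MetricName.RD]]
            ad = v[..., self._metric_idx[MetricName.AD]]
            with np.errstate(invalid="ignore"):
                bad = np.argwhere(rd > ad + 1e-12)
            if len(bad):
                cells = [(self.subjects[i], self.tracts[j], self.nodes[k])
                         for i, j, k in bad[:10]]
                raise ProfileValidationError(
                    f"RD > AD (violates eigenvalue ordering) at cells: {cells}",
                    details=cells)

    # -- lookups ------------------------------------------------------

    def has_profile(self, subject, tract) -> bool:
        i = self._subject_idx[subject]
        j = self._tract_idx[tract]
        return not np.isnan(self.values[i, j]).any()

    def _node_pos(self, node) -> int:
        try:
            return self._node_idx[node]
        except KeyError:
            raise GridRangeError(f"node {node!r} is not on the grid") from None

    def profile(self, subject, tract, metric) -> np.ndarray:
        """The full node profile of one metric for one (subject, tract)."""
        i = self._subject_idx[subject]
        j = self._tract_idx[tract]
        arr = self.values[i, j, :, self._metric_idx[MetricName.coerce(metric)]]
        if np.isnan(arr).any():
            raise MissingProfileError(f"profile ({subject}, {tract}) is missing")
        return arr

    def tract_mean(self, subject, tract, metric) -> float:
        """Mean metric value across the full node grid (tract-wise value)."""
        return float(self.profile(subject, tract, metric).mean())

    def segment_mean(self, subject, tract, metric, node_start, node_end) -> float:
        """Mean over the inclusive node-label interval [node_start, node_end]."""
        a, b = self._node_pos(node_start), self._node_pos(node_end)
        if a > b:
            raise GridRangeError(
                f"node_start {node_start!r} comes after node_end {node_end!r}")
        return float(self.profile(subject, tract, metric)[a:b + 1].mean())

    # -- vectorised views used by the statistics modules ---------------

    def node_matrix(self, tract, metric) -> pd.DataFrame:
        """(subjects x nodes) values for one tract/metric; NaN rows = missing."""
        j = self._tract_idx[tract]
        arr = self.values[:, j, :, self._metric_idx[MetricName.coerce(metric)]]
        return pd.DataFrame(arr, index=self.subjects, columns=self.nodes)

    def tract_means(self, tract, metric) -> pd.Series:
        """Per-subject tract-wise mean; NaN for subjects missing the profile."""
        return self.node_matrix(tract, metric).mean(axis=1)

    def segment_means(self, tract, metric, node_start, node_end) -> pd.Series:
        a, b = self._node_pos(node_start), self._node_pos(node_end)
        if a > b:
            raise GridRangeError(
                f"node_start {node_start!r} comes after node_end {node_end!r}")
        return self.node_matrix(tract, metric).iloc[:, a:b + 1].mean(axis=1)

    # -- conversion ----------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame,
                  schema: Mapping[str, str] | None = None) -> "TractProfileDataset":
        schema = dict(DEFAULT_PROFILE_SCHEMA, **(schema or {}))
        for key in ("subject", "tract", "node"):
            if schema[key] not in df.columns:
                raise SchemaError(f"missing required column {schema[key]!r} "
                                  f"(maps to {key!r})")
        metric_cols = {m: schema[m.value] for m in METRICS
                       if schema[m.value] in df.columns}
        if not metric_cols:
            raise SchemaError("no metric column found; expected at least one of "
                              f"{[schema[m.value] for m in METRICS]}")
        subjects = list(pd.unique(df[schema["subject"]]))
        tracts = list(pd.unique(df[schema["tract"]]))
        nodes = list(pd.unique(df[schema["node"]]))
        metrics = list(metric_cols)
        shape = (len(subjects), len(tracts), len(nodes), len(metrics))
        values = np.full(shape, np.nan)
        si = df[schema["subject"]].map({s: i for i, s in enumerate(subjects)})
        ti = df[schema["tract"]].map({t: i for i, t in enumerate(tracts)})
        ni = df[schema["node"]].map({n: i for i, n in enumerate(nodes)})
        for mi, m in enumerate(metrics):
            values[si, ti, ni, mi] = df[metric_cols[m]].to_numpy(dtype=float)
        return cls(subjects, tracts, nodes, metrics, values)

    def to_long(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Long-format frame (missing profiles omitted), row order s > t > node."""
        schema = dict(DEFAULT_PROFILE_SCHEMA, **(schema or {}))
        ns, nt, nn, nm = self.values.shape
        si, ti, ni = np.meshgrid(np.arange(ns), np.arange(nt), np.arange(nn),
                                 indexing="ij")
        out = {
            schema["subject"]: np.asarray(self.subjects, dtype=object)[si.ravel()],
            schema["tract"]: np.asarray(self.tracts, dtype=object)[ti.ravel()],
            schema["node"]: np.asarray(self.nodes)[ni.ravel()],
        }
        for mi, m in enumerate(self.metrics):
            out[schema[m.value]] = self.values[..., mi].ravel()
        df = pd.DataFrame(out)
        keep = ~df[[schema[m.value] for m in self.metrics]].isna().all(axis=1)
        return df.loc[keep].reset_index(drop=True)


def read_profiles(path, schema: Mapping[str, str] | None = None,
                  sep: str = ",") -> TractProfileDataset:
    """Read a long-format tract-profile table and validate it.

    Parameters
    ----------
    path : file path
        Delimited text file with a header row.
    schema : mapping, optional
        Overrides for column names; keys ``subject``, ``tract``, ``node``,
        ``FA``, ``MD``, ``RD``, ``AD``.
    """
    df = pd.read_csv(path, sep=sep)
    return TractProfileDataset.from_long(df, schema)


def write_profiles(ds: TractProfileDataset, path,
                   schema: Mapping[str, str] | None = None, sep: str = ","):
    """Write a dataset back to the long delimited-text format."""
    ds.to_long(schema).to_csv(path, sep=sep, index=False)


def read_demographics(path, sep: str = ",") -> list[SubjectRecord]:
    """Read a demographics/behaviour table into subject records.

    Group and sex labels parse case-insensitively; ADOS columns may be
    empty for TD subjects (and must be — ADOS scores on a TD row raise).
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("id", "group", "age", "sex") if c not in df.columns]
    if missing:
        raise SchemaError(f"demographics file missing required columns {missing}")
    if df.empty:
        logger.warning("demographics file %s is empty", path)
        return []
    return [record_from_row(row) for _, row in df.iterrows()]


def record_from_row(row: Mapping) -> SubjectRecord:
    def get(col):
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        return val

    gds = {}
    for dom in GDS_DOMAINS:
        val = get(f"gds_{dom}")
        if val is not None:
            gds[dom] = float(val)
    ados_vals = {k: get(f"ados_{k.lower()}") for k in ("SA", "RRB", "total")}
    ados = ({k: float(v) for k, v in ados_vals.items() if v is not None}
            if any(v is not None for v in ados_vals.values()) else None)
    abc = get("abc")
    return SubjectRecord(
        id=str(row["id"]), group=row["group"], age=float(row["age"]),
        sex=row["sex"], abc_total=int(abc) if abc is not None else None,
        gds=gds, ados=ados,
    )


def write_demographics(records: Sequence[SubjectRecord], path, sep: str = ","):
    pd.DataFrame([_record_to_row(r) for r in records]).to_csv(
        path, sep=sep, index=False, columns=list(DEMOGRAPHICS_COLUMNS))


def _record_to_row(r: SubjectRecord) -> dict:
    row = {"id": r.id, "group": r.group, "age": r.age, "sex": r.sex,
           "abc": r.abc_total}
    for dom in GDS_DOMAINS:
        row[f"gds_{dom}"] = r.gds.get(dom)
    for k in ("SA", "RRB", "total"):
        row[f"ados_{k.lower()}"] = (r.ados or {}).get(k)
    return row


def demographics_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Analysis-ready frame: one row per subject, indexed by id.

    Adds the numeric codings used throughout the models: ``group_asd``
    (TD = 0, ASD = 1; a positive group coefficient means ASD > TD) and
    ``sex_f`` (M = 0, F = 1).
    """
    df = pd.DataFrame([_record_to_row(r) for r in records])
    df = df.set_index("id", drop=False)
    df["group_asd"] = (df["group"] == "ASD").astype(float)
    df["sex_f"] = (df["sex"] == "F").astype(float)
    return df
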