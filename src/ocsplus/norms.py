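"""Normative cut-offs, age-band stratification, impairment classification
and domain summative scores.

Cut-offs follow the standard one-tailed convention for screening
instruments: a score is flagged when it falls beyond 1.65 SDs from the
normative mean (z method, wide-range measures) or beyond the empirical
5th/95th percentile (centile method, restricted-range measures).  Error
counts whose 95th percentile is zero receive the conservative ">= 1" rule.

Age bands are <60, 60–70 and >70 years; ages exactly 60 and 70 fall in the
middle band (the boundary convention is configurable via ``assign_age_band``).
Cut-off values are rounded to 2 decimals (half-up, matching printed
normative tables) and classification compares against the rounded value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry import DOMAINS, HIGH_BAD, LOW_BAD, REGISTRY, validate_measure_name
from .scoring import SubtaskScores

AGE_BANDS = ("<60", "60-70", ">70")
ALL_BAND = "all"

IMPAIRED = "impaired"
WITHIN_NORMS = "within_norms"
NOT_ASSESSED = "not_assessed"


def assign_age_band(age: float, middle: tuple[float, float] = (60.0, 70.0)) -> str:
    """Assign an age (years) to its normative band; the closed interval
    ``middle`` belongs to the middle band."""
    if age <= 0:
        raise ValueError("age must be > 0")
    lo, hi = middle
    if age < lo:
        return AGE_BANDS[0]
    if age <= hi:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(x, 10))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CutoffSpec:
    """How to derive one measure's impairment cut-off from a sample."""

    measure: str
    method: str                  # "z" or "centile"
    tail: str                    # LOW_BAD or HIGH_BAD
    multiplier: float = 1.65
    centile: float = 5.0         # 5 (low_bad) or 95 (high_bad)
    conservative_floor: bool = False
    inclusive: bool = False
    rounding: int = 2

    @classmethod
    def for_measure(cls, name: str) -> "CutoffSpec":
        mdef = validate_measure_name(name)
        return cls(
            measure=name,
            method=mdef.cutoff_method,
            tail=mdef.direction,
            centile=5.0 if mdef.direction == LOW_BAD else 95.0,
            conservative_floor=mdef.conservative_floor,
            inclusive=mdef.inclusive_cutoff,
            rounding=0 if (mdef.integer and mdef.cutoff_method == "centile") else 2,
        )


@dataclass(frozen=True)
class Cutoff:
    value: float
    operator: str  # "<", "<=", ">", ">="

    def flags(self, score: float) -> bool:
        return {
            "<": score < self.value,
            "<=": score <= self.value,
            ">": score > self.value,
            ">=": score >= self.value,
        }[self.operator]

    def __str__(self) -> str:
        return f"{self.operator} {self.value:g}"


def derive_cutoff(values: Sequence[float], spec: CutoffSpec) -> Cutoff:
    """Derive an impairment cut-off from a normative sample.

    z method: mean − multiplier·sd (low_bad) or mean + multiplier·sd
    (high_bad), rounded half-up to ``spec.rounding`` decimals.  The mean and
    SD may also be supplied directly via :func:`cutoff_from_moments`.

    centile method: inclusive empirical percentile (linear interpolation,
    numpy default).  With ``conservative_floor`` a high_bad cut-off of 0
    becomes ">= 1"; an inclusive low_bad cut-off is floored at 1.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], float)
    if arr.size == 0:
        raise ValueError(f"{spec.measure}: empty sample")
    if spec.method == "z":
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if sd == 0:
            raise ValueError(
                f"{spec.measure}: zero SD under the z method; use the centile method"
            )
        return cutoff_from_moments(float(arr.mean()), sd, spec)
    if spec.method != "centile":
        raise ValueError(f"unknown cut-off method {spec.method!r}")
    value = float(np.percentile(arr, spec.centile))
    value = _round_half_up(value, spec.rounding)
    if spec.tail == HIGH_BAD:
        op = ">=" if spec.inclusive else ">"
        if spec.conservative_floor and value <= 0:
            return Cutoff(1.0, ">=")
        return Cutoff(value, op)
    op = "<=" if spec.inclusive else "<"
    if spec.inclusive and spec.conservative_floor:
        value = max(value, 1.0)
    return Cutoff(value, op)


def cutoff_from_moments(mean: float, sd: float, spec: CutoffSpec) -> Cutoff:
    """z cut-off directly from a mean and SD (e.g. a published table)."""
    if sd <= 0:
        raise ValueError("sd must be > 0 for the z method")
    if spec.tail == HIGH_BAD:
        return Cutoff(_round_half_up(mean + spec.multiplier * sd, spec.rounding), ">")
    return Cutoff(_round_half_up(mean - spec.multiplier * sd, spec.rounding), "<")


# --------------------------------------------------------------------------
# normative tables


#: default per-measure row filter: figure-copy norms use the larger single
#: site when a multi-site cohort shows a site difference on that task
DEFAULT_MEASURE_FILTERS: dict[str, tuple[str, str]] = {"figure_copy": ("site", "UK")}

_STAT_COLUMNS = (
    "measure", "band", "n", "mean", "sd", "median", "min", "max",
    "method", "cutoff_value", "cutoff_operator",
)


@dataclass
class NormativeTable:
    """Per (measure, age band) distribution summaries and cut-offs."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def row(self, measure: str, band: str) -> Optional[pd.Series]:
        sel = self.frame[(self.frame.measure == measure) & (self.frame.band == band)]
        if sel.empty:
            return None
        return sel.iloc[0]

    def cutoff(self, measure: str, band: str) -> Optional[Cutoff]:
        row = self.row(measure, band)
        if row is None or pd.isna(row.cutoff_value):
            return None
        return Cutoff(float(row.cutoff_value), str(row.cutoff_operator))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "schema": "ocsplus-norms/1",
            "meta": self.meta,
            "rows": self.frame.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeTable":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema") != "ocsplus-norms/1":
            raise ValueError(f"{path}: not an ocsplus norms file")
        frame = pd.DataFrame(payload["rows"], columns=list(_STAT_COLUMNS))
        return cls(frame=frame, meta=payload.get("meta", {}))


def build_normative_table(
    cohort: pd.DataFrame,
    measures: Sequence[str] | None = None,
    specs: dict[str, CutoffSpec] | None = None,
    stratify: bool = True,
    measure_filters: dict[str, tuple[str, str]] | None = None,
    min_n: int = 20,
    table_id: str = "norms",
) -> NormativeTable:
    """Derive a normative table (per age band + pooled) from a cohort.

    ``measure_filters`` maps a measure to a ``(column, value)`` row filter
    applied before norming that measure (default: figure_copy restricted to
    the 'UK' site when a site column is present).  Strata below ``min_n``
    non-missing observations are kept but flagged with a warning.
    """
    if measures is None:
        measures = [c for c in cohort.columns if c in REGISTRY]
    if measure_filters is None:
        measure_filters = DEFAULT_MEASURE_FILTERS
    specs = specs or {}
    if "age" not in cohort.columns:
        raise ValueError("cohort must have an 'age' column")
    bands = cohort["age"].map(assign_age_band)

    rows = []
    for name in measures:
        spec = specs.get(name, CutoffSpec.for_measure(name))
        data = cohort
        filt = measure_filters.get(name)
        if filt is not None and filt[0] in cohort.columns:
            data = cohort[cohort[filt[0]] == filt[1]]
        band_labels = ([*AGE_BANDS, ALL_BAND]) if stratify else [ALL_BAND]
        for band in band_labels:
            if name not in data.columns:
                sample = pd.Series(dtype=float)
            else:
                mask = slice(None) if band == ALL_BAND else (bands.loc[data.index] == band)
                sample = data.loc[mask, name].dropna()
            n = int(sample.size)
            if n == 0:
                warnings.warn(f"{name} [{band}]: empty stratum omitted")
                continue
            if n < min_n:
                warnings.warn(f"{name} [{band}]: only {n} observations (min {min_n})")
            try:
                cut = derive_cutoff(sample.to_numpy(), spec)
                cut_value, cut_op = cut.value, cut.operator
            except ValueError as exc:
                warnings.warn(f"{name} [{band}]: no cut-off ({exc})")
                cut_value, cut_op = float("nan"), ""
            rows.append(
                {
                    "measure": name,
                    "band": band,
                    "n": n,
                    "mean": float(sample.mean()),
                    "sd": float(sample.std(ddof=1)) if n > 1 else float("nan"),
                    "median": float(sample.median()),
                    "min": float(sample.min()),
                    "max": float(sample.max()),
                    "method": spec.method,
                    "cutoff_value": cut_value,
                    "cutoff_operator": cut_op,
                }
            )
    frame = pd.DataFrame(rows, columns=list(_STAT_COLUMNS))
    meta = {"table_id": table_id, "n_cohort": int(len(cohort)),
            "measure_filters": {k: list(v) for k, v in measure_filters.items()}}
    return NormativeTable(frame=frame, meta=meta)


# --------------------------------------------------------------------------
# classification


@dataclass
class ImpairmentProfile:
    participant_id: str
    age_band: str
    table_id: str
    measures: dict[str, dict] = field(default_factory=dict)
    domains: dict[str, dict] = field(default_factory=dict)
    skip_reasons: dict[str, str] = field(default_factory=dict)
    condition_flags: dict[str, list] = field(default_factory=dict)

    def status(self, measure: str) -> str:
        return self.measures[measure]["status"]


def classify_scores(
    scores: SubtaskScores,
    age: float,
    table: NormativeTable,
    use_bands: bool = True,
) -> ImpairmentProfile:
    """Classify one participant's measures against a normative table.

    low_bad measures are impaired when the score falls below the cut-off;
    high_bad measures (times, error counts) when it falls above.  Measures
    that were not assessed, or that are absent from the table, are
    classified ``not_assessed`` (with a warning for the latter — never
    silently dropped).
    """
    band = assign_age_band(age) if use_bands else ALL_BAND
    profile = ImpairmentProfile(
        participant_id=scores.participant_id,
        age_band=band,
        table_id=str(table.meta.get("table_id", "norms")),
        skip_reasons=dict(scores.skip_reasons),
        condition_flags=dict(scores.condition_flags),
    )
    for name, value in scores.values.items():
        entry: dict = {"band": band, "cutoff": None, "score": value}
        if value is None:
            entry["status"] = NOT_ASSESSED
            if name in scores.unscorable:
                entry["reason"] = scores.unscorable[name]
            profile.measures[name] = entry
            continue
        cut = table.cutoff(name, band)
        if cut is None and band != ALL_BAND:
            cut = table.cutoff(name, ALL_BAND)  # fall back to pooled norms
        if cut is None:
            warnings.warn(f"{name}: absent from normative table; not assessed")
            entry["status"] = NOT_ASSESSED
            entry["reason"] = "no normative data"
            profile.measures[name] = entry
            continue
        entry["cutoff"] = str(cut)
        entry["status"] = IMPAIRED if cut.flags(value) else WITHIN_NORMS
        profile.measures[name] = entry
    return profile


# --------------------------------------------------------------------------
# domain summative scores


def compute_domain_scores(scores: SubtaskScores) -> dict[str, Optional[float]]:
    """Signed sums of constituent measures per cognitive domain; a domain
    with any unassessed constituent is None (not assessed)."""
    out: dict[str, Optional[float]] = {}
    for name, dom in DOMAINS.items():
        total = 0.0
        ok = True
        for measure, w in dom.weights.items():
            v = scores.values.get(measure)
            if v is None:
                ok = False
                break
            total += w * v
        out[name] = total if ok else None
    return out


def domain_scores_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Domain summative scores for every cohort row (NaN-propagating)."""
    out = pd.DataFrame(index=cohort.index)
    if "participant_id" in cohort.columns:
        out["participant_id"] = cohort["participant_id"]
    for name, dom in DOMAINS.items():
        total = pd.Series(0.0, index=cohort.index)
        for measure, w in dom.weights.items():
            col = cohort[measure] if measure in cohort else pd.Series(np.nan, index=cohort.index)
            total = total + w * col
        out[name] = total
    return out


def build_domain_table(cohort: pd.DataFrame, centile: float = 5.0) -> pd.DataFrame:
    """Normative summaries and 5th-centile cut-offs for the domain scores,
    derived from a user cohort (domain cut-offs are never hard-coded)."""
    dom = domain_scores_frame(cohort)
    rows = []
    for name in DOMAINS:
        sample = dom[name].dropna()
        if sample.empty:
            continue
        cut = float(np.percentile(sample, centile))
        rows.append(
            {
                "domain": name,
                "n": int(sample.size),
                "mean": float(sample.mean()),
                "sd": float(sample.std(ddof=1)),
                "median": float(sample.median()),
                "min": float(sample.min()),
                "max": float(sample.max()),
                "cutoff_value": _round_half_up(cut, 2),
                "cutoff_operator": "<",
            }
        )
    return pd.DataFrame(rows)


def classify_domains(
    scores: SubtaskScores, domain_table: pd.DataFrame
) -> dict[str, dict]:
    """Classify a participant's domain scores against cohort-derived
    domain cut-offs."""
    values = compute_domain_scores(scores)
    out: dict[str, dict] = {}
    table = domain_table.set_index("domain")
    for name, value in values.items():
        entry: dict = {"score": value, "cutoff": None}
        if value is None:
            entry["status"] = NOT_ASSESSED
        elif name not in table.index:
            entry["status"] = NOT_ASSESSED
            entry["reason"] = "no normative data"
        else:
            cut = Cutoff(
                float(table.loc[name, "cutoff_value"]),
                str(table.loc[name, "cutoff_operator"]),
            )
            entry["cutoff"] = str(cut)
            entry["status"] = IMPAIRED if cut.flags(value) else WITHIN_NORMS
        out[name] = entry
    return out
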