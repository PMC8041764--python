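"""Canonical registry of OCS-Plus subtasks, measures and domain scores.

Every measure name used anywhere in the package resolves against this single
registry, which fixes the score range, the direction in which impairment
lies, the cut-off method used for norming, and the domain membership.

Two cut-off methods are distinguished, following standard neuropsychological
practice for bounded screens:

* ``z``        — mean ± 1.65·SD of the normative sample; used for measures
                 with sufficient range (trails, rule finding, figures,
                 cancellation accuracies).
* ``centile``  — empirical 5th (accuracy) or 95th (error count) percentile;
                 used for restricted-range measures whose healthy
                 distribution sits at ceiling (0–4/0–5 tasks, error counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field


LOW_BAD = "low_bad"    # impairment = abnormally LOW score
HIGH_BAD = "high_bad"  # impairment = abnormally HIGH score (times, errors)


@dataclass(frozen=True)
class MeasureDef:
    """Registry entry for a single OCS-Plus outcome measure."""

    name: str
    task: str                   # subtask the measure belongs to
    lo: float                   # inclusive lower bound of valid scores
    hi: float | None            # inclusive upper bound; None = unbounded
    direction: str              # LOW_BAD or HIGH_BAD
    cutoff_method: str          # "z" or "centile"
    integer: bool = True
    # error-count measures whose 95th centile may be 0; the cut-off is then
    # conservatively raised to ">= 1"
    conservative_floor: bool = False
    # cut-off comparison includes the boundary value (e.g. "<= 1" for the
    # number of rules learned, vs the default strict "< c")
    inclusive_cutoff: bool = False

    def in_range(self, value: float) -> bool:
        if value < self.lo:
            return False
        return self.hi is None or value <= self.hi


# Administration order of the ten subtasks.
SUBTASK_ORDER: tuple[str, ...] = (
    "picture_naming",
    "semantics",
    "orientation",
    "word_encoding",
    "trails",
    "verbal_recall",
    "episodic_recognition",
    "figure",
    "rule_finding",
    "cancellation",
)

# The fixed five-word list of the word-memory task.
WORD_TARGETS: tuple[str, ...] = ("bicycle", "mist", "wardrobe", "teacher", "rectangle")


def _m(name, task, lo, hi, direction, method, **kw) -> MeasureDef:
    return MeasureDef(name, task, lo, hi, direction, method, **kw)


_MEASURES: tuple[MeasureDef, ...] = (
    _m("picture_naming", "picture_naming", 0, 4, LOW_BAD, "centile"),
    _m("semantics", "semantics", 0, 4, LOW_BAD, "centile"),
    _m("orientation", "orientation", 0, 4, LOW_BAD, "centile"),
    _m("encoding1", "word_encoding", 0, 5, LOW_BAD, "centile"),
    _m("encoding2", "word_encoding", 0, 5, LOW_BAD, "centile"),
    _m("delayed_recall", "verbal_recall", 0, 5, LOW_BAD, "centile"),
    _m("delayed_recall_recognition", "verbal_recall", 0, 5, LOW_BAD, "centile"),
    _m("episodic_recognition", "episodic_recognition", 0, 4, LOW_BAD, "centile"),
    _m("processing_speed", "trails", 0, None, HIGH_BAD, "z", integer=False),
    _m("executive_score", "trails", 0, 100, LOW_BAD, "z", integer=False),
    _m("rule_accuracy", "rule_finding", 0, 46, LOW_BAD, "z"),
    _m("rules_learned", "rule_finding", 0, 5, LOW_BAD, "centile",
       conservative_floor=True, inclusive_cutoff=True),
    _m("figure_copy", "figure", 0, 60, LOW_BAD, "z"),
    _m("figure_recall", "figure", 0, 60, LOW_BAD, "z"),
    _m("cancellation_hits", "cancellation", 0, 30, LOW_BAD, "z"),
    _m("false_positives", "cancellation", 0, None, HIGH_BAD, "centile",
       conservative_floor=True, inclusive_cutoff=True),
    _m("invisible_hits", "cancellation", 0, 30, LOW_BAD, "z"),
    _m("correct_revisits", "cancellation", 0, None, HIGH_BAD, "centile",
       conservative_floor=True, inclusive_cutoff=True),
)

REGISTRY: dict[str, MeasureDef] = {m.name: m for m in _MEASURES}
MEASURE_NAMES: tuple[str, ...] = tuple(REGISTRY)
Z_MEASURES: tuple[str, ...] = tuple(m.name for m in _MEASURES if m.cutoff_method == "z")
CENTILE_MEASURES: tuple[str, ...] = tuple(
    m.name for m in _MEASURES if m.cutoff_method == "centile"
)


@dataclass(frozen=True)
class DomainDef:
    """A domain summative score: a signed sum of registered measures."""

    name: str
    weights: dict[str, int]     # measure -> +1 / -1
    lo: float
    hi: float


DOMAINS: dict[str, DomainDef] = {
    d.name: d
    for d in (
        DomainDef("executive_function",
                  {"rule_accuracy": 1, "rules_learned": 1,
                   "executive_score": 1, "false_positives": -1},
                  -float("inf"), 151),
        DomainDef("praxis", {"figure_copy": 1, "figure_recall": 1}, 0, 120),
        DomainDef("delayed_memory",
                  {"delayed_recall": 1, "delayed_recall_recognition": 1}, 0, 10),
        DomainDef("attention", {"cancellation_hits": 1, "invisible_hits": 1}, 0, 60),
        DomainDef("memory_encoding", {"encoding1": 1, "encoding2": 1}, 0, 10),
        DomainDef("naming_semantics", {"picture_naming": 1, "semantics": 1}, 0, 8),
    )
}


def measures_of_task(task: str) -> tuple[str, ...]:
    return tuple(m.name for m in _MEASURES if m.task == task)


def validate_measure_name(name: str) -> MeasureDef:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; registered measures: {', '.join(MEASURE_NAMES)}"
        ) from None
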