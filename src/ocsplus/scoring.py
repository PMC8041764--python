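"""Trial-level scoring of the ten OCS-Plus subtasks.

Converts a validated :class:`~ocsplus.session.SessionLog` into the full
vector of derived measures.  The scoring rules are:

* choice tasks (picture naming, semantics, orientation, episodic
  recognition): count of correct responses out of 4;
* word memory: each encoding attempt scored independently as the number of
  target words produced (0–5); delayed free recall 0–5, plus forced-choice
  recognition of the missed words for a combined 0–5 total;
* trails: correct connections out of 7 per baseline trail; the executive
  (switching) score is the switching-trail proportion over the summed
  baseline proportion, ×100 and capped at 100; processing speed is total
  baseline time divided by proportional baseline accuracy, so fast but
  inaccurate responding is penalised;
* rule finding: accuracy out of 46 scoreable anticipations (trials
  immediately after a rule change are excluded); a rule counts as learned
  when at least two consecutive scoreable guesses within its segment are
  correct;
* figure copy/recall: 20 elements × (presence, position, accuracy) ∈ {0,1},
  total 0–60 per drawing;
* cancellation: distinct targets selected (0–30) per condition; distractor
  selections are false positives (feedback condition) and repeat selections
  of an already-found target are correct revisits (no-feedback condition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .registry import MEASURE_NAMES, REGISTRY, WORD_TARGETS
from .session import SessionLog, SubtaskBlock

NOT_ASSESSED = None  # sentinel for skipped / unscorable measures

CHOICE_TASKS = ("picture_naming", "semantics", "orientation", "episodic_recognition")
CHOICE_TASK_MEASURE = {
    "picture_naming": "picture_naming",
    "semantics": "semantics",
    "orientation": "orientation",
    "episodic_recognition": "episodic_recognition",
}


class ScoringError(ValueError):
    """A block's event stream violates the task's scoring contract."""


# --------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class TrailsConfig:
    """Trail-making task structure.

    ``switch_max`` (length of the switching trail) is not part of the fixed
    task definition and is configurable; the default of 13 connections is a
    package choice, flagged here prominently.
    """

    circle_max: int = 7
    square_max: int = 7
    switch_max: int = 13
    cap_executive: bool = True  # cap the executive score at 100

    def __post_init__(self) -> None:
        if min(self.circle_max, self.square_max, self.switch_max) <= 0:
            raise ValueError("trail maxima must be > 0")


@dataclass(frozen=True)
class RuleFindingConfig:
    """Rule-finding task structure.

    Only the constraints "46 scoreable trials", "5 rules" and "exclude the
    trial immediately after each rule change" are fixed; the per-segment
    layout is configurable.  ``segment_sizes`` counts scoreable trials per
    rule segment and must sum to ``scoreable_trials``.
    """

    n_rules: int = 5
    scoreable_trials: int = 46
    segment_sizes: tuple[int, ...] = (9, 9, 9, 9, 10)
    consecutive_needed: int = 2

    def __post_init__(self) -> None:
        if len(self.segment_sizes) != self.n_rules:
            raise ValueError("segment_sizes must have one entry per rule")
        if sum(self.segment_sizes) != self.scoreable_trials:
            raise ValueError("segment sizes must sum to scoreable_trials")


@dataclass(frozen=True)
class FigureElementScore:
    element_id: int
    presence: int
    position: int
    accuracy: int

    def __post_init__(self) -> None:
        for v in (self.presence, self.position, self.accuracy):
            if v not in (0, 1):
                raise ValueError("element sub-scores are binary (0/1)")

    @property
    def total(self) -> int:
        return self.presence + self.position + self.accuracy


# --------------------------------------------------------------------------
# cancellation layout


@dataclass(frozen=True)
class LayoutItem:
    id: str
    role: str  # target | distractor
    x: float
    y: float
    w: float
    h: float

    def contains(self, x: float, y: float) -> bool:
        return self.x <= x <= self.x + self.w and self.y <= y <= self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class CancellationLayout:
    items: tuple[LayoutItem, ...]

    @property
    def targets(self) -> tuple[LayoutItem, ...]:
        return tuple(i for i in self.items if i.role == "target")

    @property
    def distractors(self) -> tuple[LayoutItem, ...]:
        return tuple(i for i in self.items if i.role == "distractor")

    def hit_test(self, x: float, y: float) -> Optional[LayoutItem]:
        """Item under a tap; overlapping boxes resolved by smallest area,
        ties by layout order. Taps outside every box return None."""
        hits = [i for i in self.items if i.contains(x, y)]
        if not hits:
            return None
        return min(hits, key=lambda i: i.area)


def load_layout(path: str | Path | None = None) -> CancellationLayout:
    """Load a cancellation layout JSON; default = the layout shipped with
    the package (synthetic 30-target array)."""
    if path is None:
        text = (
            resources.files("ocsplus").joinpath("data/cancellation_layout.json")
        ).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    payload = json.loads(text)
    items = tuple(
        LayoutItem(d["id"], d["role"], d["x"], d["y"], d["w"], d["h"])
        for d in payload["items"]
    )
    n_targets = sum(1 for i in items if i.role == "target")
    if n_targets != 30:
        raise ScoringError(f"layout must contain 30 targets, found {n_targets}")
    return CancellationLayout(items)


# --------------------------------------------------------------------------
# result container


@dataclass
class SubtaskScores:
    """The full set of derived OCS-Plus measures for one participant.

    Registry measures live in ``values`` (None = not assessed); auxiliary
    raw quantities (trail connection counts and times) are kept separately.
    """

    participant_id: str
    values: dict[str, Optional[float]] = field(
        default_factory=lambda: {m: None for m in MEASURE_NAMES}
    )
    raw: dict[str, float] = field(default_factory=dict)
    skip_reasons: dict[str, str] = field(default_factory=dict)     # task -> reason
    condition_flags: dict[str, list[str]] = field(default_factory=dict)
    unscorable: dict[str, str] = field(default_factory=dict)       # measure -> why

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            mdef = REGISTRY[name]
            if v is not None and not mdef.in_range(v):
                raise ScoringError(
                    f"{name}={v} outside registered range [{mdef.lo}, {mdef.hi}]"
                )

    def assessed(self, measure: str) -> bool:
        return self.values.get(measure) is not None

    def to_row(self) -> dict[str, Optional[float]]:
        row: dict[str, Optional[float]] = {"participant_id": self.participant_id}
        row.update(self.values)
        return row


# --------------------------------------------------------------------------
# per-task scoring operations


def score_choice_task(block: SubtaskBlock, n_items: int = 4) -> Optional[int]:
    """Score a 4-item choice task as the count of correct responses."""
    if block.subtask_id not in CHOICE_TASKS:
        raise ScoringError(f"{block.subtask_id!r} is not a choice task")
    if block.skipped:
        return NOT_ASSESSED
    scored = [e for e in block.events if e.correct is not None]
    if len(scored) > n_items:
        raise ScoringError(
            f"block {block.subtask_id!r}: {len(scored)} scored events exceed "
            f"{n_items} items"
        )
    return sum(1 for e in scored if e.correct)


def _match_targets(words: Iterable[str], targets: Sequence[str] = WORD_TARGETS) -> set:
    normalized = {w.strip().casefold() for w in words}
    return normalized & {t.casefold() for t in targets}


def score_word_memory(
    attempt1: Iterable[str],
    attempt2: Iterable[str],
    targets: Sequence[str] = WORD_TARGETS,
) -> tuple[int, int]:
    """Score the two encoding attempts independently (each 0–5).

    Words are matched by exact case-folded, whitespace-trimmed equality;
    duplicates collapse; non-target words simply do not count.
    """
    return (
        len(_match_targets(attempt1, targets)),
        len(_match_targets(attempt2, targets)),
    )


def score_delayed_recall(
    free: Iterable[str],
    recognized: dict[str, bool],
    targets: Sequence[str] = WORD_TARGETS,
) -> tuple[int, int]:
    """Score delayed free recall (0–5) and recall+recognition total (0–5).

    ``recognized`` maps each word missed in free recall to its forced-choice
    outcome; supplying an outcome for a freely-recalled word is an error.
    """
    target_set = {t.casefold() for t in targets}
    recalled = _match_targets(free, targets)
    for word in recognized:
        w = word.strip().casefold()
        if w in recalled:
            raise ScoringError(
                f"recognition outcome supplied for freely-recalled word {word!r}"
            )
        if w not in target_set:
            raise ScoringError(f"recognition outcome for non-target word {word!r}")
    recall = len(recalled)
    total = recall + sum(bool(v) for v in recognized.values())
    return recall, total


@dataclass(frozen=True)
class TrailsResult:
    executive_score: Optional[float]
    processing_speed: Optional[float]
    unscorable: bool = False


def compute_trails_metrics(
    circle_correct: int,
    square_correct: int,
    switch_correct: int,
    circle_time_s: float,
    square_time_s: float,
    cfg: TrailsConfig = TrailsConfig(),
) -> TrailsResult:
    """Executive (switching) score and accuracy-corrected processing speed.

    baseline_prop = (circle + square) / (circle_max + square_max)
    switch_prop   = switch / switch_max
    executive     = 100 × min(1, switch_prop / baseline_prop)
    speed         = (circle_time + square_time) / baseline_prop  [seconds]

    A baseline proportion of zero leaves both measures unscorable (explicit
    flag, never infinity).
    """
    if not (0 <= circle_correct <= cfg.circle_max):
        raise ScoringError("circle_correct outside [0, circle_max]")
    if not (0 <= square_correct <= cfg.square_max):
        raise ScoringError("square_correct outside [0, square_max]")
    if not (0 <= switch_correct <= cfg.switch_max):
        raise ScoringError("switch_correct outside [0, switch_max]")
    if circle_time_s <= 0 or square_time_s <= 0:
        raise ScoringError("trail times must be > 0")
    baseline_prop = (circle_correct + square_correct) / (cfg.circle_max + cfg.square_max)
    if baseline_prop == 0:
        return TrailsResult(None, None, unscorable=True)
    switch_prop = switch_correct / cfg.switch_max
    executive = 100.0 * (switch_prop / baseline_prop)
    if cfg.cap_executive:
        executive = min(100.0, executive)
    speed = (circle_time_s + square_time_s) / baseline_prop
    return TrailsResult(executive, speed)


def score_rule_finding(
    anticipations: Sequence[tuple[bool, int, bool]],
    cfg: RuleFindingConfig = RuleFindingConfig(),
) -> tuple[int, int]:
    """Score the rule-finding task.

    ``anticipations`` is the ordered sequence of
    ``(correct, rule_segment_id, immediately_after_change)`` triples,
    segments numbered 1..n_rules.  Returns ``(rule_accuracy,
    rules_learned)``.  Excluded (post-change) trials neither count toward
    nor break a run of consecutive correct responses.
    """
    segs = sorted({s for _, s, _ in anticipations})
    if segs != list(range(1, cfg.n_rules + 1)):
        raise ScoringError(
            f"segment ids must be contiguous 1..{cfg.n_rules}, got {segs}"
        )
    scoreable = [(c, s) for c, s, excluded in anticipations if not excluded]
    if len(scoreable) != cfg.scoreable_trials:
        raise ScoringError(
            f"expected {cfg.scoreable_trials} scoreable trials, got {len(scoreable)}"
        )
    accuracy = sum(1 for c, _ in scoreable if c)
    learned = 0
    for seg in range(1, cfg.n_rules + 1):
        run = best = 0
        for c, s in scoreable:
            if s != seg:
                continue
            run = run + 1 if c else 0
            best = max(best, run)
        if best >= cfg.consecutive_needed:
            learned += 1
    return accuracy, learned


def score_figure(elements: Sequence[FigureElementScore]) -> int:
    """Sum of per-element (presence, position, accuracy) scores; 0–60."""
    ids = sorted(e.element_id for e in elements)
    if ids != list(range(1, 21)):
        raise ScoringError(f"need 20 unique element ids 1–20, got {ids}")
    return sum(e.total for e in elements)


@dataclass(frozen=True)
class CancellationResult:
    hits: int
    false_positives: Optional[int] = None    # feedback condition
    correct_revisits: Optional[int] = None   # no-feedback condition


def score_cancellation(
    taps: Sequence[tuple[float, float]],
    layout: CancellationLayout,
    condition: str,
) -> CancellationResult:
    """Replay a tap stream against the layout for one condition.

    Taps outside any box are ignored.  ``hits`` counts distinct targets
    selected (capped at 30 by construction).  In the feedback condition
    every distractor selection adds a false positive; in the no-feedback
    condition every repeat selection of an already-found target adds a
    correct revisit.
    """
    if condition not in ("feedback", "no_feedback"):
        raise ScoringError(f"unknown cancellation condition {condition!r}")
    seen: set[str] = set()
    false_positives = 0
    revisits = 0
    for x, y in taps:
        item = layout.hit_test(x, y)
        if item is None:
            continue
        if item.role == "distractor":
            false_positives += 1
        elif item.id in seen:
            revisits += 1
        else:
            seen.add(item.id)
    if condition == "feedback":
        return CancellationResult(len(seen), false_positives=false_positives)
    return CancellationResult(len(seen), correct_revisits=revisits)


# --------------------------------------------------------------------------
# session orchestration — event-stream conventions per block
#
#   word_encoding  stimulus "attempt1"/"attempt2", response_value = word
#   trails         stimulus "<phase>:start" (unscored marker) then
#                  "<phase>:<k>" connection events, phase in
#                  circle/square/switch; phase time = last event - marker
#   verbal_recall  stimulus "free" (response_value = word) then
#                  "recognition:<word>" with correct flag
#   figure         stimulus "copy:<k>" / "recall:<k>", response_value
#                  "p,q,r" binary triple
#   rule_finding   stimulus "rule:<segment>", response_value "postchange"
#                  for excluded trials else "scored"
#   cancellation   stimulus "feedback" / "no_feedback", tap_xy set


def _score_word_encoding_block(block: SubtaskBlock) -> tuple[int, int]:
    a1 = [e.response_value or "" for e in block.events if e.stimulus_id == "attempt1"]
    a2 = [e.response_value or "" for e in block.events if e.stimulus_id == "attempt2"]
    return score_word_memory(a1, a2)


def _score_verbal_recall_block(block: SubtaskBlock) -> tuple[int, int]:
    free = [e.response_value or "" for e in block.events if e.stimulus_id == "free"]
    recognized = {
        e.stimulus_id.split(":", 1)[1]: bool(e.correct)
        for e in block.events
        if e.stimulus_id.startswith("recognition:")
    }
    return score_delayed_recall(free, recognized)


def _score_trails_block(
    block: SubtaskBlock, cfg: TrailsConfig
) -> tuple[TrailsResult, dict[str, float]]:
    counts: dict[str, int] = {}
    times: dict[str, float] = {}
    for phase in ("circle", "square", "switch"):
        marker = [e for e in block.events if e.stimulus_id == f"{phase}:start"]
        conn = [
            e
            for e in block.events
            if e.stimulus_id.startswith(f"{phase}:") and e.stimulus_id != f"{phase}:start"
        ]
        if not marker:
            raise ScoringError(f"trails: missing {phase}:start marker")
        counts[phase] = sum(1 for e in conn if e.correct)
        last = conn[-1].timestamp_ms if conn else marker[0].timestamp_ms
        times[phase] = (last - marker[0].timestamp_ms) / 1000.0
    result = compute_trails_metrics(
        counts["circle"],
        counts["square"],
        counts["switch"],
        max(times["circle"], 1e-9),
        max(times["square"], 1e-9),
        cfg,
    )
    raw = {
        "trails_circle": counts["circle"],
        "trails_square": counts["square"],
        "trails_switch_correct": counts["switch"],
        "trails_circle_time_s": times["circle"],
        "trails_square_time_s": times["square"],
    }
    return result, raw


def _score_rule_block(block: SubtaskBlock, cfg: RuleFindingConfig) -> tuple[int, int]:
    triples = []
    for e in sorted(block.events, key=lambda e: e.trial_index):
        if not e.stimulus_id.startswith("rule:"):
            continue
        seg = int(e.stimulus_id.split(":", 1)[1])
        excluded = e.response_value == "postchange"
        triples.append((bool(e.correct), seg, excluded))
    return score_rule_finding(triples, cfg)


def _score_figure_block(block: SubtaskBlock) -> tuple[Optional[int], Optional[int]]:
    out: list[Optional[int]] = []
    for kind in ("copy", "recall"):
        elements = []
        for e in block.events:
            if not e.stimulus_id.startswith(f"{kind}:"):
                continue
            k = int(e.stimulus_id.split(":", 1)[1])
            p, q, r = (int(v) for v in (e.response_value or "0,0,0").split(","))
            elements.append(FigureElementScore(k, p, q, r))
        out.append(score_figure(elements) if elements else None)
    return out[0], out[1]


def _score_cancellation_block(
    block: SubtaskBlock, layout: CancellationLayout
) -> dict[str, int]:
    streams = {"feedback": [], "no_feedback": []}
    for e in block.events:
        if e.stimulus_id in streams and e.tap_xy is not None:
            streams[e.stimulus_id].append(e.tap_xy)
    fb = score_cancellation(streams["feedback"], layout, "feedback")
    nf = score_cancellation(streams["no_feedback"], layout, "no_feedback")
    return {
        "cancellation_hits": fb.hits,
        "false_positives": fb.false_positives,
        "invisible_hits": nf.hits,
        "correct_revisits": nf.correct_revisits,
    }


def score_session(
    log: SessionLog,
    layout: CancellationLayout | None = None,
    trails_cfg: TrailsConfig = TrailsConfig(),
    rule_cfg: RuleFindingConfig = RuleFindingConfig(),
) -> SubtaskScores:
    """Score a full session; every measure is either scored or marked
    not-assessed (with the block's skip reason propagated)."""
    if layout is None:
        layout = load_layout()
    scores = SubtaskScores(participant_id=log.participant_id)

    for task in (
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
    ):
        block = log.block(task)
        if block is None or block.skipped:
            if block is not None and block.skip_reason:
                scores.skip_reasons[task] = block.skip_reason
            continue
        if block.condition_flags:
            scores.condition_flags[task] = list(block.condition_flags)

        if task in CHOICE_TASKS:
            scores.values[CHOICE_TASK_MEASURE[task]] = score_choice_task(block)
        elif task == "word_encoding":
            e1, e2 = _score_word_encoding_block(block)
            scores.values["encoding1"] = e1
            scores.values["encoding2"] = e2
        elif task == "verbal_recall":
            dr, drr = _score_verbal_recall_block(block)
            scores.values["delayed_recall"] = dr
            scores.values["delayed_recall_recognition"] = drr
        elif task == "trails":
            result, raw = _score_trails_block(block, trails_cfg)
            scores.raw.update(raw)
            if result.unscorable:
                scores.unscorable["executive_score"] = "baseline accuracy is zero"
                scores.unscorable["processing_speed"] = "baseline accuracy is zero"
            else:
                scores.values["executive_score"] = result.executive_score
                scores.values["processing_speed"] = result.processing_speed
        elif task == "rule_finding":
            acc, learned = _score_rule_block(block, rule_cfg)
            scores.values["rule_accuracy"] = acc
            scores.values["rules_learned"] = learned
        elif task == "figure":
            copy, recall = _score_figure_block(block)
            if copy is None:
                scores.unscorable["figure_copy"] = "no element scores supplied"
            else:
                scores.values["figure_copy"] = copy
            if recall is None:
                scores.unscorable["figure_recall"] = "no element scores supplied"
            else:
                scores.values["figure_recall"] = recall
        elif task == "cancellation":
            scores.values.update(_score_cancellation_block(block, layout))

    scores.__post_init__()  # re-validate ranges after in-place assembly
    return scores
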