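"""Synthetic cohorts, trial-level sessions, retest pairs and external
batteries with known ground truth.

The generator emulates the salient features of a healthy-ageing normative
cohort on a tablet cognitive screen: restricted-range subtasks sit at
ceiling (medians at or near the maximum), wide-range measures are
approximately truncated-normal with age-graded means/SDs (older bands
slower and less accurate), error counts are rare events, and the trail
subtask couples speed to accuracy.  Default distribution parameters are
illustrative values patterned on published healthy-ageing norms for this
kind of screen; they are NOT anyone's real data.

Ground truth is constructive: :func:`simulate_session` emits trial-level
event streams that the scoring module recovers *exactly*, so the full
simulate → score → norm pipeline can be verified end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import REGISTRY, WORD_TARGETS
from .scoring import CancellationLayout, RuleFindingConfig, TrailsConfig, load_layout
from .session import SessionLog, SubtaskBlock, TrialEvent

BANDS = ("<60", "60-70", ">70")
BAND_AGE_RANGE = {"<60": (23, 59), "60-70": (60, 70), ">70": (71, 95)}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic normative cohort."""

    n_participants: int = 320
    band_weights: tuple[float, float, float] = (111, 101, 108)  # <60 / 60-70 / >70
    uk_fraction: float = 234 / 320

    # wide-range measures: per-band (mean, sd) of the latent normal,
    # truncated to the registry range and rounded where integer-valued
    z_params: dict = field(default_factory=lambda: {
        "processing_speed": {"<60": (31.44, 16.78), "60-70": (31.67, 15.05), ">70": (39.54, 22.58)},
        "executive_score": {"<60": (88.48, 18.31), "60-70": (77.33, 27.90), ">70": (81.72, 25.40)},
        "rule_accuracy": {"<60": (29.17, 7.82), "60-70": (26.56, 7.99), ">70": (24.41, 8.15)},
        "rules_learned": {"<60": (3.34, 1.25), "60-70": (2.98, 1.30), ">70": (2.64, 1.31)},
        "figure_copy": {"<60": (56.85, 6.24), "60-70": (55.37, 6.09), ">70": (53.57, 7.35)},
        "figure_recall": {"<60": (47.02, 9.70), "60-70": (42.43, 11.27), ">70": (41.25, 9.88)},
        "cancellation_hits": {"<60": (29.8, 2.43), "60-70": (29.6, 3.62), ">70": (29.5, 6.78)},
        "invisible_hits": {"<60": (28.93, 1.43), "60-70": (28.46, 1.50), ">70": (27.94, 2.26)},
    })

    # restricted-range (ceiling) tasks: per-band per-item success rate
    choice_p: dict = field(default_factory=lambda: {
        "picture_naming": {"<60": 0.96, "60-70": 0.95, ">70": 0.93},
        "semantics": {"<60": 0.96, "60-70": 0.95, ">70": 0.94},
        "orientation": {"<60": 0.97, "60-70": 0.96, ">70": 0.94},
        "episodic_recognition": {"<60": 0.96, "60-70": 0.95, ">70": 0.93},
    })
    encoding1_p: dict = field(default_factory=lambda: {"<60": 0.90, "60-70": 0.87, ">70": 0.82})
    encoding2_p: dict = field(default_factory=lambda: {"<60": 0.97, "60-70": 0.96, ">70": 0.93})
    delayed_p: dict = field(default_factory=lambda: {"<60": 0.82, "60-70": 0.76, ">70": 0.70})
    recognition_p: float = 0.92

    # rare-event error counts (Poisson rates)
    false_positive_rate: float = 0.03
    revisit_rate: dict = field(default_factory=lambda: {"<60": 0.05, "60-70": 0.08, ">70": 0.15})

    # trail structure
    trail_miss_p: dict = field(default_factory=lambda: {"<60": 0.01, "60-70": 0.02, ">70": 0.04})
    processing_speed_range: tuple[float, float] = (8.0, 200.0)


@dataclass
class GroundTruth:
    """Latent state and intended (session-realisable) scores for one
    synthetic participant."""

    participant_id: str
    age: float
    band: str
    site: str
    education_band: str
    sex: str
    scores: dict[str, float]
    primitives: dict


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.random()
    return float(stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd))


def _rule_capacity(sizes: Sequence[int], learned: int) -> int:
    """Maximum accuracy achievable with exactly ``learned`` rules learned."""
    s = sorted(sizes, reverse=True)
    full = sum(s[:learned])
    partial = sum(math.ceil(v / 2) for v in s[learned:])
    return full + partial


def _feasible_rules_learned(acc: int, draw: int, sizes: Sequence[int]) -> int:
    lo = 0
    while _rule_capacity(sizes, lo) < acc:
        lo += 1
    hi = min(len(sizes), acc // 2)
    return int(min(max(draw, lo), hi))


def simulate_cohort(
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: int | None = 0,
    id_prefix: str = "P",
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Generate a cohort table plus per-participant ground truth.

    Deterministic under ``seed``; every intended score is realisable as a
    trial-level session (see :func:`simulate_session`), so the cohort table
    equals what ``score_session`` would produce.
    """
    rng = np.random.default_rng(seed)
    weights = np.asarray(cfg.band_weights, float)
    weights = weights / weights.sum()
    rule_cfg = RuleFindingConfig()
    truths: list[GroundTruth] = []
    rows = []

    for i in range(cfg.n_participants):
        band = BANDS[rng.choice(3, p=weights)]
        lo, hi = BAND_AGE_RANGE[band]
        age = int(rng.integers(lo, hi + 1))
        site = "UK" if rng.random() < cfg.uk_fraction else "DE"
        education = "higher" if rng.random() < 0.6 else "standard"
        sex = "male" if rng.random() < 0.55 else "female"
        pid = f"{id_prefix}{i:04d}"
        scores: dict[str, float] = {}
        prim: dict = {}

        for task, p_band in cfg.choice_p.items():
            scores[task] = int(rng.binomial(4, p_band[band]))
        scores["encoding1"] = int(rng.binomial(5, cfg.encoding1_p[band]))
        scores["encoding2"] = int(rng.binomial(5, cfg.encoding2_p[band]))
        d = int(rng.binomial(5, cfg.delayed_p[band]))
        r = int(rng.binomial(5 - d, cfg.recognition_p))
        scores["delayed_recall"] = d
        scores["delayed_recall_recognition"] = d + r
        prim["recognition_successes"] = r

        # trails: counts, then times consistent with the target speed
        miss = cfg.trail_miss_p[band]
        circle = 7 - int(rng.binomial(7, miss))
        square = 7 - int(rng.binomial(7, miss))
        prop = (circle + square) / 14.0
        zp = cfg.z_params
        speed_target = _truncnorm(rng, *zp["processing_speed"][band],
                                  *cfg.processing_speed_range)
        total_ms = max(2, int(round(speed_target * prop * 1000)))
        circle_ms = max(1, int(round(total_ms * rng.uniform(0.45, 0.55))))
        square_ms = max(1, total_ms - circle_ms)
        exec_target = _truncnorm(rng, *zp["executive_score"][band], 0.0, 100.0)
        switch = int(np.clip(round(exec_target / 100.0 * 13 * prop), 0, 13))
        # same float expression the scoring path evaluates, for exact recovery
        scores["processing_speed"] = (circle_ms / 1000.0 + square_ms / 1000.0) / prop
        scores["executive_score"] = 100.0 * min(1.0, (switch / 13.0) / prop)
        prim["trails"] = {
            "circle": circle, "square": square, "switch": switch,
            "circle_ms": circle_ms, "square_ms": square_ms,
        }

        acc = int(np.clip(round(rng.normal(*zp["rule_accuracy"][band])), 0, 46))
        learned = _feasible_rules_learned(
            acc, int(round(rng.normal(*zp["rules_learned"][band]))),
            rule_cfg.segment_sizes,
        )
        scores["rule_accuracy"] = acc
        scores["rules_learned"] = learned

        copy = int(np.clip(round(rng.normal(*zp["figure_copy"][band])), 0, 60))
        recall = min(copy, int(np.clip(round(rng.normal(*zp["figure_recall"][band])), 0, 60)))
        scores["figure_copy"] = copy
        scores["figure_recall"] = recall

        hits = int(np.clip(round(rng.normal(*zp["cancellation_hits"][band])), 0, 30))
        inv = int(np.clip(round(rng.normal(*zp["invisible_hits"][band])), 0, 30))
        fp = int(min(rng.poisson(cfg.false_positive_rate), 20))
        rev = int(min(rng.poisson(cfg.revisit_rate[band]), 10)) if inv > 0 else 0
        scores["cancellation_hits"] = hits
        scores["false_positives"] = fp
        scores["invisible_hits"] = inv
        scores["correct_revisits"] = rev

        truths.append(GroundTruth(pid, age, band, site, education, sex, scores, prim))
        rows.append({"participant_id": pid, "age": age, "education_band": education,
                     "sex": sex, "site": site, **scores})

    cohort = pd.DataFrame(rows)
    return cohort, truths


# --------------------------------------------------------------------------
# trial-level session synthesis


def _rule_sequence(
    acc: int, learned: int, cfg: RuleFindingConfig
) -> list[tuple[bool, int, bool]]:
    """Construct an anticipation sequence scoring exactly (acc, learned).

    Learned segments receive a consecutive block of correct responses
    (>= 2); unlearned segments receive correct responses only at
    alternating positions so no two are consecutive.  Segments 2..n start
    with one excluded (immediately-after-change) trial.
    """
    sizes = list(cfg.segment_sizes)
    order = sorted(range(len(sizes)), key=lambda i: -sizes[i])
    learned_set = set(order[:learned])
    correct_per_seg = [0] * len(sizes)
    remaining = acc
    for i in learned_set:
        correct_per_seg[i] = cfg.consecutive_needed
        remaining -= cfg.consecutive_needed
    if remaining < 0:
        raise ValueError(f"rule_accuracy {acc} infeasible with {learned} rules learned")
    for i in order[:learned]:  # top up learned segments first (stays consecutive)
        room = sizes[i] - correct_per_seg[i]
        take = min(room, remaining)
        correct_per_seg[i] += take
        remaining -= take
    for i in order[learned:]:  # then alternating positions in unlearned segments
        room = math.ceil(sizes[i] / 2)
        take = min(room, remaining)
        correct_per_seg[i] += take
        remaining -= take
    if remaining > 0:
        raise ValueError(f"rule_accuracy {acc} infeasible with {learned} rules learned")

    seq: list[tuple[bool, int, bool]] = []
    for i, size in enumerate(sizes):
        seg = i + 1
        if i > 0:  # excluded trial immediately after the rule change
            seq.append((False, seg, True))
        c = correct_per_seg[i]
        if i in learned_set:
            pattern = [k < c for k in range(size)]
        else:
            pattern = [False] * size
            placed = 0
            for k in range(0, size, 2):
                if placed == c:
                    break
                pattern[k] = True
                placed += 1
        seq.extend((flag, seg, False) for flag in pattern)
    return seq


def simulate_session(
    truth: GroundTruth,
    seed: int | None = None,
    layout: CancellationLayout | None = None,
    trails_cfg: TrailsConfig = TrailsConfig(),
    rule_cfg: RuleFindingConfig = RuleFindingConfig(),
    skip_tasks: dict[str, str] | None = None,
) -> SessionLog:
    """Emit a trial-level session whose scoring recovers ``truth.scores``
    exactly.  ``skip_tasks`` maps subtask ids to skip reasons."""
    if layout is None:
        layout = load_layout()
    rng = np.random.default_rng(seed)
    skip_tasks = skip_tasks or {}
    s = truth.scores
    blocks: list[SubtaskBlock] = []
    clock = 0  # ms since session start

    def tick(lo: int = 800, hi: int = 2500) -> int:
        nonlocal clock
        clock += int(rng.integers(lo, hi))
        return clock

    def maybe(task: str, builder) -> None:
        if task in skip_tasks:
            blocks.append(SubtaskBlock(subtask_id=task, skipped=True,
                                       skip_reason=skip_tasks[task]))
        else:
            blocks.append(builder())

    def choice_block(task: str) -> SubtaskBlock:
        score = int(s[task]) if task != "episodic_recognition" else int(s[task])
        events = [
            TrialEvent(trial_index=k + 1, stimulus_id=f"item{k + 1}",
                       response_value=f"resp{k + 1}", correct=k < score,
                       timestamp_ms=tick())
            for k in range(4)
        ]
        return SubtaskBlock(subtask_id=task, events=events)

    maybe("picture_naming", lambda: choice_block("picture_naming"))
    maybe("semantics", lambda: choice_block("semantics"))
    maybe("orientation", lambda: choice_block("orientation"))

    def encoding_block() -> SubtaskBlock:
        events = []
        idx = 0
        for attempt, n in (("attempt1", int(s["encoding1"])),
                           ("attempt2", int(s["encoding2"]))):
            for w in WORD_TARGETS[:n]:
                idx += 1
                events.append(TrialEvent(trial_index=idx, stimulus_id=attempt,
                                         response_value=w, timestamp_ms=tick()))
            # a non-target intrusion now and then; never affects the score
            if rng.random() < 0.3:
                idx += 1
                events.append(TrialEvent(trial_index=idx, stimulus_id=attempt,
                                         response_value="lantern",
                                         timestamp_ms=tick()))
        return SubtaskBlock(subtask_id="word_encoding", events=events)

    maybe("word_encoding", encoding_block)

    def trails_block() -> SubtaskBlock:
        t = truth.primitives["trails"]
        events = []
        idx = 0
        nonlocal clock
        for phase, n_correct, n_max, dur_ms in (
            ("circle", t["circle"], 7, t["circle_ms"]),
            ("square", t["square"], 7, t["square_ms"]),
            ("switch", t["switch"], 13, None),
        ):
            idx += 1
            start = tick()
            events.append(TrialEvent(trial_index=idx, stimulus_id=f"{phase}:start",
                                     timestamp_ms=start))
            attempts = n_max  # one attempt per node; incorrect beyond n_correct
            if dur_ms is None:
                dur_ms = int(rng.integers(8000, 30000))
            for k in range(attempts):
                idx += 1
                ts = start + max(1, int(round(dur_ms * (k + 1) / attempts)))
                events.append(TrialEvent(trial_index=idx,
                                         stimulus_id=f"{phase}:{k + 1}",
                                         correct=k < n_correct, timestamp_ms=ts))
            clock = start + dur_ms
        return SubtaskBlock(subtask_id="trails", events=events)

    maybe("trails", trails_block)

    def recall_block() -> SubtaskBlock:
        d = int(s["delayed_recall"])
        r = int(truth.primitives["recognition_successes"])
        events = []
        idx = 0
        for w in WORD_TARGETS[:d]:
            idx += 1
            events.append(TrialEvent(trial_index=idx, stimulus_id="free",
                                     response_value=w, timestamp_ms=tick()))
        missed = WORD_TARGETS[d:]
        for j, w in enumerate(missed):
            idx += 1
            events.append(TrialEvent(trial_index=idx, stimulus_id=f"recognition:{w}",
                                     response_value=w if j < r else "foil",
                                     correct=j < r, timestamp_ms=tick()))
        return SubtaskBlock(subtask_id="verbal_recall", events=events)

    maybe("verbal_recall", recall_block)
    maybe("episodic_recognition", lambda: choice_block("episodic_recognition"))

    def figure_block() -> SubtaskBlock:
        events = []
        idx = 0
        for kind, total in (("copy", int(s["figure_copy"])),
                            ("recall", int(s["figure_recall"]))):
            full, rem = divmod(total, 3)
            for k in range(1, 21):
                if k <= full:
                    triple = (1, 1, 1)
                elif k == full + 1:
                    triple = tuple(int(b < rem) for b in range(3))
                else:
                    triple = (0, 0, 0)
                idx += 1
                events.append(TrialEvent(
                    trial_index=idx, stimulus_id=f"{kind}:{k}",
                    response_value=",".join(map(str, triple)),
                    timestamp_ms=tick(100, 400)))
        return SubtaskBlock(subtask_id="figure", events=events)

    maybe("figure", figure_block)

    def rule_block() -> SubtaskBlock:
        seq = _rule_sequence(int(s["rule_accuracy"]), int(s["rules_learned"]), rule_cfg)
        events = [
            TrialEvent(trial_index=k + 1, stimulus_id=f"rule:{seg}",
                       response_value="postchange" if excl else "scored",
                       correct=c, timestamp_ms=tick(300, 1500))
            for k, (c, seg, excl) in enumerate(seq)
        ]
        return SubtaskBlock(subtask_id="rule_finding", events=events)

    maybe("rule_finding", rule_block)

    def cancellation_block() -> SubtaskBlock:
        targets = layout.targets
        distractors = layout.distractors
        events = []
        idx = 0

        def tap(item, phase) -> None:
            nonlocal idx
            idx += 1
            x = item.x + item.w / 2 + float(rng.uniform(-item.w / 4, item.w / 4))
            y = item.y + item.h / 2 + float(rng.uniform(-item.h / 4, item.h / 4))
            events.append(TrialEvent(trial_index=idx, stimulus_id=phase,
                                     tap_xy=(x, y), timestamp_ms=tick(200, 900)))

        for item in targets[: int(s["cancellation_hits"])]:
            tap(item, "feedback")
        for k in range(int(s["false_positives"])):
            tap(distractors[k % len(distractors)], "feedback")
        for item in targets[: int(s["invisible_hits"])]:
            tap(item, "no_feedback")
        for _ in range(int(s["correct_revisits"])):
            tap(targets[0], "no_feedback")
        return SubtaskBlock(subtask_id="cancellation", events=events)

    maybe("cancellation", cancellation_block)

    return SessionLog(
        participant_id=truth.participant_id,
        age=truth.age,
        education_band=truth.education_band,
        sex=truth.sex,
        site=truth.site,
        session_datetime="2024-01-01T10:00:00",
        blocks=blocks,
    )


# --------------------------------------------------------------------------
# retest pairs and external batteries


def simulate_retest(
    cohort: pd.DataFrame,
    reliability: dict[str, float],
    practice_effect: dict[str, float] | None = None,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw second-session scores with a target test–retest correlation.

    For each measure with target reliability ρ the second score is
    ρ-correlated with the first on the standardised scale (Gaussian
    residual), shifted by the configured practice effect (default 0), then
    truncated/rounded back to the registry range.  Returns (t1, t2) tables.
    """
    rng = np.random.default_rng(seed)
    practice_effect = practice_effect or {}
    t1 = cohort.copy()
    t2 = cohort.copy()
    for name, rho in reliability.items():
        if not 0 <= rho < 1:
            raise ValueError(f"{name}: reliability target must be in [0, 1)")
        mdef = REGISTRY[name]
        x = pd.to_numeric(cohort[name], errors="coerce").to_numpy(float)
        m, sd = np.nanmean(x), np.nanstd(x)
        if sd == 0:
            y = x.copy()
        else:
            z = (x - m) / sd
            y = m + sd * (rho * z + math.sqrt(1 - rho**2) * rng.standard_normal(x.size))
        y = y + practice_effect.get(name, 0.0)
        lo = mdef.lo
        hi = mdef.hi if mdef.hi is not None else np.inf
        y = np.clip(y, lo, hi)
        if mdef.integer:
            y = np.round(y)
        t2[name] = y
    return t1, t2


def simulate_external_battery(
    cohort: pd.DataFrame,
    mapping: pd.DataFrame,
    reliabilities: dict[str, float] | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """External-battery scores sharing a specified latent correlation with
    their mapped OCS-Plus measure.

    ``mapping`` columns: ocs_measure, external_measure, family, latent_r,
    external_reliability.  Measurement error is consolidated on the
    external side so the observed correlation is
    latent_r·√(rel_ocs·rel_ext) — the quantity the attenuation correction
    then recovers.  Divergent mappings default to latent_r = 0.
    """
    rng = np.random.default_rng(seed)
    reliabilities = reliabilities or {}
    out = pd.DataFrame({"participant_id": cohort["participant_id"]})
    for rec in mapping.to_dict(orient="records"):
        name = rec["ocs_measure"]
        rho = float(rec.get("latent_r", 0.0) or 0.0)
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"latent correlation {rho} outside [-1, 1]")
        rel_ext = float(rec.get("external_reliability", 1.0) or 1.0)
        rel_ocs = float(reliabilities.get(name, 1.0))
        x = pd.to_numeric(cohort[name], errors="coerce").to_numpy(float)
        sd = np.nanstd(x)
        z = (x - np.nanmean(x)) / sd if sd > 0 else np.zeros_like(x)
        r_obs = rho * math.sqrt(rel_ocs * rel_ext)
        noise = rng.standard_normal(x.size)
        out[rec["external_measure"]] = r_obs * z + math.sqrt(max(0.0, 1 - r_obs**2)) * noise
    return out
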