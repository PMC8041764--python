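"""Reliability and validity machinery.

* bootstrapped split-half internal consistency (random item splits with
  Spearman–Brown step-up, averaged over iterations);
* attenuation correction of observed correlations by the geometric mean of
  the two measures' reliabilities;
* test–retest statistics: paired Wilcoxon signed-rank (continuity-corrected
  normal approximation for larger samples, exact distribution below),
  rank-biserial effect size, Jacobson–Truax reliable change index;
* cohort-harmonisation comparisons via Mann–Whitney U with Bonferroni
  correction;
* convergent/divergent validity tables using Kendall tau-b with
  family-wise-corrected alpha thresholds;
* power of a correlation test by simulation (used to verify the minimum
  detectable latent correlation of a validity design).

All stochastic routines take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TIME_BASED_ASSUMED_RELIABILITY = 1.0  # declared assumption for duration measures


@dataclass
class ReliabilityResult:
    measure: str
    estimate: float
    ci_low: float
    ci_high: float
    n_iterations: int
    n_degenerate: int
    interpretable: bool
    reason: str = ""


def spearman_brown(r: float) -> float:
    """Step up a half-test correlation to full-test reliability."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    item_matrix: np.ndarray | pd.DataFrame,
    n_iter: int = 5000,
    seed: int | None = None,
    measure: str = "",
    scheme: str = "split",
) -> ReliabilityResult:
    """Bootstrapped split-half internal consistency of an item matrix.

    Each iteration randomly partitions the items (columns) into two halves,
    correlates the half sums across participants and applies the
    Spearman–Brown correction; the estimate is the mean over iterations
    with a percentile (2.5/97.5) interval.  Iterations in which either half
    has zero variance are skipped and counted; if fewer than half of the
    iterations survive, the estimate is flagged uninterpretable (the
    restricted-range / ceiling case).

    ``scheme='bootstrap_split'`` additionally resamples participants with
    replacement before each split (sensitivity variant).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("item matrix must be 2-D with >= 2 items")
    if x.shape[0] < 3:
        raise ValueError("need >= 3 participants")
    if scheme not in ("split", "bootstrap_split"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    n, k = x.shape
    half = k // 2
    estimates = []
    degenerate = 0
    for _ in range(n_iter):
        data = x[rng.integers(0, n, n)] if scheme == "bootstrap_split" else x
        perm = rng.permutation(k)
        a = data[:, perm[:half]].sum(axis=1)
        b = data[:, perm[half:]].sum(axis=1)
        if a.std() == 0 or b.std() == 0:
            degenerate += 1
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if r <= -1.0:  # Spearman-Brown undefined at r = -1
            degenerate += 1
            continue
        estimates.append(spearman_brown(r))
    if not estimates:
        return ReliabilityResult(
            measure, float("nan"), float("nan"), float("nan"),
            n_iter, degenerate, False, "all iterations degenerate (no variance)",
        )
    est = np.asarray(estimates)
    interpretable = degenerate <= n_iter // 2
    reason = "" if interpretable else (
        f"{degenerate}/{n_iter} degenerate splits (restricted range)"
    )
    return ReliabilityResult(
        measure,
        float(est.mean()),
        float(np.percentile(est, 2.5)),
        float(np.percentile(est, 97.5)),
        n_iter,
        degenerate,
        interpretable,
        reason,
    )


def attenuation_correct(
    coeff: float, rel_x: float, rel_y: float
) -> tuple[float, bool]:
    """Correct an observed correlation for measurement unreliability.

    corrected = coeff / sqrt(rel_x · rel_y).  Values exceeding |1| are
    flagged (non-random measurement error), never clamped.
    """
    if rel_x <= 0 or rel_y <= 0:
        raise ValueError("reliabilities must be > 0")
    corrected = coeff / math.sqrt(rel_x * rel_y)
    return corrected, abs(corrected) > 1.0


def reliable_change_index(
    x1: float, x2: float, sd_baseline: float, r_xx: float
) -> float:
    """Jacobson–Truax reliable change index for a retest score pair.

    rci = (x2 − x1) / (sd_baseline · √2 · √(1 − r_xx)); the denominator is
    the standard error of the difference implied by the baseline SD and
    test–retest reliability ``r_xx``.
    """
    if sd_baseline <= 0:
        raise ValueError("sd_baseline must be > 0")
    if not (0 <= r_xx < 1):
        raise ValueError("r_xx must be in [0, 1); rci undefined at r_xx = 1")
    sed = sd_baseline * math.sqrt(2.0) * math.sqrt(1.0 - r_xx)
    return (x2 - x1) / sed


@dataclass
class RetestResult:
    measure: str
    n_pairs: int
    n_nontied: int
    statistic: float
    p: float
    effect_size: float
    alpha_corrected: float
    significant_raw: bool
    significant_corrected: bool
    rci: np.ndarray = field(default_factory=lambda: np.array([]))
    note: str = ""


def paired_retest(
    t1: Sequence[float],
    t2: Sequence[float],
    family_size: int = 1,
    measure: str = "",
    r_xx: float | None = None,
    exact_below: int = 20,
) -> RetestResult:
    """Two-sided paired Wilcoxon signed-rank test of session 1 vs session 2.

    Zero differences are discarded (standard signed-rank convention); the
    exact null distribution is used below ``exact_below`` non-tied pairs,
    the continuity-corrected normal approximation above.  Bonferroni
    threshold = 0.05 / family_size.  Per-participant reliable change
    indices use the baseline SD and ``r_xx`` (defaults to the observed
    Pearson correlation between sessions).
    """
    a = np.asarray(t1, float)
    b = np.asarray(t2, float)
    if a.shape != b.shape:
        raise ValueError("sessions must have equal length")
    diffs = b - a
    nontied = int(np.sum(diffs != 0))
    alpha_corrected = 0.05 / family_size
    if nontied == 0:
        return RetestResult(
            measure, a.size, 0, float("nan"), float("nan"), 0.0,
            alpha_corrected, False, False,
            rci=np.zeros(a.size), note="all pairs tied; no change detectable",
        )
    method = "exact" if nontied < exact_below else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    # matched-pairs rank-biserial correlation
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    effect = 2.0 * w_pos / total - 1.0
    if r_xx is None:
        r_xx = float(np.corrcoef(a, b)[0, 1]) if np.std(a) > 0 and np.std(b) > 0 else 0.0
        r_xx = min(max(r_xx, 0.0), 0.999)
    sd1 = float(np.std(a, ddof=1))
    rci = (
        np.array([reliable_change_index(x, y, sd1, r_xx) for x, y in zip(a, b)])
        if sd1 > 0
        else np.zeros(a.size)
    )
    return RetestResult(
        measure, a.size, nontied, float(res.statistic), float(res.pvalue),
        effect, alpha_corrected,
        bool(res.pvalue < 0.05), bool(res.pvalue < alpha_corrected), rci,
    )


def compare_cohorts(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    measures: Sequence[str],
    family_size: int | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-measure two-sided Mann–Whitney U comparison of two cohorts with
    Bonferroni correction (harmonisation check before pooling)."""
    family_size = family_size or len(measures)
    rows = []
    for name in measures:
        a = pd.to_numeric(group_a[name], errors="coerce").dropna().to_numpy()
        b = pd.to_numeric(group_b[name], errors="coerce").dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{name}: need >= 2 observations per group")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        p = float(res.pvalue)
        rows.append(
            {
                "measure": name,
                f"n_{labels[0]}": a.size,
                f"n_{labels[1]}": b.size,
                f"mean_{labels[0]}": float(a.mean()),
                f"mean_{labels[1]}": float(b.mean()),
                "U": float(res.statistic),
                "p": p,
                "p_bonferroni": min(1.0, p * family_size),
                "significant_raw": p < 0.05,
                "significant_corrected": p < 0.05 / family_size,
            }
        )
    return pd.DataFrame(rows)


def validity_table(
    ocs_scores: pd.DataFrame,
    external_scores: pd.DataFrame,
    mapping: pd.DataFrame,
    reliabilities: dict[str, float],
    acceptable_threshold: float = 0.20,
) -> pd.DataFrame:
    """Convergent/divergent validity rows.

    ``mapping`` needs columns ``ocs_measure``, ``external_measure``,
    ``family`` (convergent | divergent); per pair a Kendall tau-b over
    pairwise-complete observations is attenuation-corrected by the two
    measures' reliabilities (``reliabilities`` keyed by measure name;
    time-based measures may carry the declared assumption of 1).  The
    family-wise alpha threshold is 0.05 divided by the family's number of
    comparisons in the mapping (never hard-coded).  Rows with fewer than 3
    complete pairs are reported with missing statistics.
    """
    required = {"ocs_measure", "external_measure", "family"}
    if not required.issubset(mapping.columns):
        raise ValueError(f"mapping needs columns {sorted(required)}")
    family_sizes = mapping["family"].value_counts().to_dict()
    merged = ocs_scores.merge(external_scores, on="participant_id", how="inner")
    rows = []
    for rec in mapping.to_dict(orient="records"):
        x_name, y_name, family = (
            rec["ocs_measure"], rec["external_measure"], rec["family"],
        )
        alpha = 0.05 / family_sizes[family]
        pair = merged[[x_name, y_name]].dropna()
        n = int(len(pair))
        row = {
            "ocs_measure": x_name,
            "external_measure": y_name,
            "family": family,
            "n": n,
            "tau": float("nan"),
            "p": float("nan"),
            "corrected_r": float("nan"),
            "exceeds_unity": False,
            "alpha_threshold": alpha,
            "significant_raw": False,
            "significant_corrected": False,
            "acceptable": False,
        }
        if n >= 3:
            tau, p = stats.kendalltau(pair[x_name], pair[y_name])
            rel_x = reliabilities.get(x_name, TIME_BASED_ASSUMED_RELIABILITY)
            rel_y = reliabilities.get(y_name, TIME_BASED_ASSUMED_RELIABILITY)
            corrected, exceeds = attenuation_correct(float(tau), rel_x, rel_y)
            row.update(
                tau=float(tau),
                p=float(p),
                corrected_r=corrected,
                exceeds_unity=exceeds,
                significant_raw=bool(p < 0.05),
                significant_corrected=bool(p < alpha),
                acceptable=bool(abs(corrected) > acceptable_threshold),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_power(
    latent_r: float,
    n: int,
    n_reps: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> float:
    """Monte-Carlo power of a Pearson correlation test at sample size ``n``.

    Simulates ``n_reps`` bivariate-normal samples with correlation
    ``latent_r`` and returns the rejection rate at level ``alpha``.  The
    default one-sided alternative matches a directional convergent-validity
    hypothesis (a predicted positive association); pass ``two-sided`` for a
    non-directional check.
    """
    if not -1.0 < latent_r < 1.0:
        raise ValueError("latent_r must be inside (-1, 1)")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((n_reps, n))
    z2 = latent_r * z1 + math.sqrt(1 - latent_r**2) * rng.standard_normal((n_reps, n))
    # vectorized Pearson r per replicate
    z1c = z1 - z1.mean(axis=1, keepdims=True)
    z2c = z2 - z2.mean(axis=1, keepdims=True)
    r = (z1c * z2c).sum(axis=1) / np.sqrt(
        (z1c**2).sum(axis=1) * (z2c**2).sum(axis=1)
    )
    t = r * np.sqrt((n - 2) / (1 - r**2))
    if alternative == "greater":
        p = stats.t.sf(t, n - 2)
    elif alternative == "less":
        p = stats.t.cdf(t, n - 2)
    elif alternative == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(np.mean(p < alpha))
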