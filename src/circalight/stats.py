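"""Paired phase comparisons: normality-gated tests, effect sizes, power.

The study design is a repeated-measures baseline/intervention contrast on the
same residents, so every comparison is paired. The protocol:

1. Shapiro-Wilk on the paired differences (appropriate for n < 50) decides
   the branch at ``alpha_norm``.
2. Parametric branch: two-tailed paired t test with Cohen's d_z
   (mean difference / SD of differences, the matched-pairs convention).
3. Nonparametric branch: Wilcoxon signed-rank (exact null for n <= 25,
   normal approximation with continuity correction above; zero differences
   dropped) with Cliff's delta.

Sample-size planning uses the noncentral t distribution for the paired t
test, the same computation a priori power software performs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    """Invalid statistical input (too few pairs, bad parameters)."""


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    contrast: str
    test: str  # "paired-t" | "wilcoxon-signed-rank" | "degenerate"
    p_value: float
    effect_size: float
    effect_type: str  # "cohen_d" | "cliff_delta" | "none"
    effect_label: str
    n_pairs: int
    flagged: bool = False


def normality_gate(paired_differences, alpha_norm: float = 0.05) -> str:
    """Shapiro-Wilk gate on paired differences: 'parametric' iff p >= alpha."""
    d = np.asarray(paired_differences, dtype=float)
    if d.size < 3:
        raise StatsError(f"normality gate needs n >= 3 differences, got {d.size}")
    if np.ptp(d) == 0:
        # Constant differences carry no distributional evidence either way.
        return "nonparametric"
    _, p = sps.shapiro(d)
    return "parametric" if p >= alpha_norm else "nonparametric"


def cohens_d_paired(baseline, follow_up, denominator: str = "diff_sd") -> float:
    """Cohen's d for paired samples.

    ``denominator="diff_sd"`` gives d_z = mean(diff) / SD(diff) (matched-pairs
    convention); ``"avg_sd"`` divides by the mean of the two group SDs.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(follow_up, dtype=float)
    diff = y - x
    if denominator == "diff_sd":
        sd = diff.std(ddof=1)
    elif denominator == "avg_sd":
        sd = (x.std(ddof=1) + y.std(ddof=1)) / 2.0
    else:
        raise StatsError(f"unknown denominator {denominator!r}")
    if sd == 0:
        return 0.0 if np.all(diff == 0) else math.nan
    return float(diff.mean() / sd)


def cliffs_delta(x, y) -> float:
    """Cliff's dominance delta: P(x > y) - P(x < y) over all pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("cliffs_delta needs nonempty samples")
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float((gt - lt) / (x.size * y.size))


# Effect-size bands (Cohen for d; Romano et al. thresholds for Cliff's delta).
_D_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))
_DELTA_BANDS = ((0.147, "negligible"), (0.33, "high overlap"), (0.474, "medium"))


def effect_label(effect_size: float, effect_type: str) -> str:
    """Qualitative magnitude band for an effect size.

    For Cliff's delta, magnitudes between the negligible and medium cut-offs
    are labelled "high overlap" (substantial distributional overlap despite a
    detectable shift).
    """
    if not math.isfinite(effect_size):
        return "undefined"
    mag = abs(effect_size)
    bands = _D_BANDS if effect_type == "cohen_d" else _DELTA_BANDS
    for cut, label in bands:
        if mag < cut:
            return label
    return "large"


def paired_compare(
    baseline_values,
    phase_values,
    parameter: str = "",
    contrast: str = "",
    forced_branch: str | None = None,
    alpha_norm: float = 0.05,
) -> ComparisonResult:
    """Normality-gated two-tailed paired comparison of two study phases.

    ``forced_branch`` ("parametric" / "nonparametric") overrides the
    Shapiro-Wilk gate, e.g. to treat specific well-being subscales as
    nonparametric regardless of the sample drawn.
    """
    x = np.asarray(baseline_values, dtype=float)
    y = np.asarray(phase_values, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired vectors must have equal length")
    n = x.size
    if n < 3:
        raise StatsError(f"paired comparison needs n >= 3 pairs, got {n}")
    diff = y - x

    if np.all(diff == 0):
        # No signal at all: sign-symmetric null is certain.
        return ComparisonResult(parameter, contrast, "degenerate", 1.0, 0.0,
                                "none", "negligible", n)

    branch = forced_branch or normality_gate(diff, alpha_norm)
    if branch == "parametric":
        if diff.std(ddof=1) == 0:
            # Constant nonzero shift: t statistic undefined.
            return ComparisonResult(parameter, contrast, "paired-t", math.nan,
                                    math.nan, "cohen_d", "undefined", n, flagged=True)
        _, p = sps.ttest_rel(y, x)
        es = cohens_d_paired(x, y)
        etype = "cohen_d"
        test = "paired-t"
    elif branch == "nonparametric":
        nz = diff[diff != 0]
        method = "exact" if nz.size <= 25 else "approx"
        _, p = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                            method=method, alternative="two-sided")
        es = cliffs_delta(y, x)
        etype = "cliff_delta"
        test = "wilcoxon-signed-rank"
    else:
        raise StatsError(f"unknown branch {branch!r}")
    return ComparisonResult(parameter, contrast, test, float(p), es, etype,
                            effect_label(es, etype), n)


def power_paired_t(n: int, effect_size: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a paired t test at n pairs and standardized effect d_z."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = math.sqrt(n) * effect_size
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, nc))


def required_sample_size(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.80,
    tails: int = 2,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n for which the paired t test reaches the requested power."""
    if effect_size <= 0:
        raise StatsError("effect_size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsError("alpha and power must lie in (0, 1)")
    n = 2
    while n <= max_n:
        if power_paired_t(n, effect_size, alpha, tails) >= power:
            return n
        n += 1
    raise StatsError("requested power unattainable within max_n pairs")


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; raw p is the default report)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
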