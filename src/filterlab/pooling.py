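"""Random-effects meta-analysis of proportions.

Per-review sensitivities and specificities are pooled with the
moment-based DerSimonian-Laird random-effects model on a
variance-stabilized scale.  The default transform is the Freeman-Tukey
double arcsine,

    t = asin(sqrt(x / (n + 1))) + asin(sqrt((x + 1) / (n + 1))),
    var(t) = 1 / (n + 0.5),

with the pooled value mapped back to a proportion by Miller's inverse
using the harmonic mean of the study sizes — the long-standing default
of Stata's ``metaprop``.  A logit transform with 0.5 continuity
correction at the boundaries is available as an alternative.  The 95%
confidence interval is the normal approximation on the transformed
scale, back-transformed and clamped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ProportionStudy",
    "PooledEstimate",
    "transform",
    "pool",
    "forest_plot",
]

METHODS = ("ft_dl", "logit_dl")
_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ProportionStudy:
    """One review's events/total (e.g. retrieved relevant / all relevant)."""

    label: str
    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"{self.label!r}: total must be positive")
        if not 0 <= self.events <= self.total:
            raise ValueError(f"{self.label!r}: events outside [0, total]")

    @property
    def proportion(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class PooledEstimate:
    """Back-transformed pooled percentage with 95% CI and heterogeneity."""

    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    method: str
    k: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown pooling method {self.method!r}")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("CI must bracket the estimate")


def transform(study: ProportionStudy, method: str = "ft_dl") -> tuple[float, float]:
    """Transformed proportion and its within-study variance."""
    x, n = study.events, study.total
    if method == "ft_dl":
        t = math.asin(math.sqrt(x / (n + 1))) + math.asin(math.sqrt((x + 1) / (n + 1)))
        return t, 1.0 / (n + 0.5)
    if method == "logit_dl":
        # 0.5 continuity correction only at the boundaries
        if x == 0 or x == n:
            x_, n_ = x + 0.5, n + 1.0
        else:
            x_, n_ = float(x), float(n)
        p = x_ / n_
        return math.log(p / (1 - p)), 1.0 / (n_ * p * (1 - p))
    raise ValueError(f"unknown pooling method {method!r}")


def _ft_back(t: float, harmonic_n: float) -> float:
    """Miller's inverse of the pooled double-arcsine value (a proportion)."""
    t = min(max(t, 0.0), math.pi)  # double arcsine lives in [0, pi]
    if t == 0.0:
        return 0.0
    if t == math.pi:
        return 1.0
    s = math.sin(t)
    inner = s + (s - 1.0 / s) / harmonic_n
    radicand = max(0.0, 1.0 - inner * inner)
    p = 0.5 * (1.0 - math.copysign(1.0, math.cos(t)) * math.sqrt(radicand))
    return min(max(p, 0.0), 1.0)


def _logit_back(t: float) -> float:
    return 1.0 / (1.0 + math.exp(-t))


def pool(
    studies: Sequence[ProportionStudy], method: str = "ft_dl"
) -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling of per-study proportions.

    tau-squared is the DL moment estimator on the transformed values;
    weights are inverse (within + between) variance; the pooled value
    and CI are back-transformed to the percentage scale.  A single study
    is returned as its own proportion with its own CI.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("pool: no studies")
    if method not in METHODS:
        raise ValueError(f"unknown pooling method {method!r}")

    ts, vs = zip(*(transform(s, method) for s in studies))
    ts = np.asarray(ts, dtype=float)
    vs = np.asarray(vs, dtype=float)
    k = len(studies)

    if k == 1:
        tau2 = 0.0
        pooled_t = float(ts[0])
        se = float(np.sqrt(vs[0]))
    else:
        w = 1.0 / vs
        t_fixed = float(np.sum(w * ts) / np.sum(w))
        q = float(np.sum(w * (ts - t_fixed) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (vs + tau2)
        pooled_t = float(np.sum(w_star * ts) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))

    lo_t, hi_t = pooled_t - _Z95 * se, pooled_t + _Z95 * se
    if method == "ft_dl":
        harmonic_n = k / sum(1.0 / s.total for s in studies)
        back = lambda t: _ft_back(t, harmonic_n)  # noqa: E731
    else:
        back = _logit_back
    estimate = 100.0 * back(pooled_t)
    ci_low = min(max(100.0 * back(lo_t), 0.0), 100.0)
    ci_high = min(max(100.0 * back(hi_t), 0.0), 100.0)
    ci_low, ci_high = min(ci_low, estimate), max(ci_high, estimate)
    return PooledEstimate(
        estimate=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        tau2=tau2,
        method=method,
        k=k,
    )


def study_interval(study: ProportionStudy) -> tuple[float, float]:
    """Exact (Clopper-Pearson) 95% CI for one study, percentage scale."""
    x, n = study.events, study.total
    lo = 0.0 if x == 0 else stats.beta.ppf(0.025, x, n - x + 1)
    hi = 1.0 if x == n else stats.beta.ppf(0.975, x + 1, n - x)
    return 100.0 * lo, 100.0 * hi


def forest_plot(
    studies: Sequence[ProportionStudy],
    pooled: PooledEstimate,
    path: str,
    title: str = "Pooled proportion",
) -> None:
    """Write a forest plot: per-study proportions with exact CIs and the
    pooled diamond at the bottom."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(studies)
    fig, ax = plt.subplots(figsize=(6, 0.5 * k + 2))
    ys = np.arange(k, 0, -1)
    for y, s in zip(ys, studies):
        lo, hi = study_interval(s)
        ax.plot([lo, hi], [y, y], color="black", lw=1)
        ax.plot(100 * s.proportion, y, "s", color="black", ms=5)
        ax.annotate(
            f"{s.label} ({s.events}/{s.total})",
            xy=(0, y),
            xytext=(-4, 0),
            textcoords="offset points",
            ha="right",
            va="center",
            fontsize=8,
            annotation_clip=False,
        )
    dx = [pooled.ci_low, pooled.estimate, pooled.ci_high, pooled.estimate]
    dy = [0, 0.25, 0, -0.25]
    ax.fill(dx, dy, color="steelblue")
    ax.axvline(pooled.estimate, color="steelblue", ls="--", lw=0.8)
    ax.set_xlim(-1, 101)
    ax.set_ylim(-1, k + 1)
    ax.set_yticks([])
    ax.set_xlabel("%")
    ax.set_title(
        f"{title}: {pooled.estimate:.0f}% "
        f"(95% CI {pooled.ci_low:.0f}-{pooled.ci_high:.0f}%), "
        f"tau² = {pooled.tau2:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
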