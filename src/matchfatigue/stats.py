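"""Statistical layer for paired match-fatigue comparisons.

Implements the inference toolkit used to compare game halves, kick sets and
before/after neuromuscular assessments: paired Student t, one-way ANOVA,
Pearson correlation, Cohen's d on the pooled SD of the two moments, the
smallest worthwhile change (SWC = 0.2 x between-subject SD), and
magnitude-based inference (MBI): the chances that the true change exceeds
+SWC / lies within +-SWC / falls below -SWC, mapped onto a qualitative
probabilistic scale with an "unclear" rule when both beneficial and harmful
chances exceed 5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "EffectReport",
    "delta_summary",
    "paired_t",
    "oneway_anova",
    "pearson_r",
    "cohens_d",
    "magnitude_label",
    "swc",
    "mbi_chances",
    "mbi_label",
    "effect_report",
    "effect_table",
]


@dataclass
class PairedSample:
    """Before/after measurements paired by subject."""

    subjects: np.ndarray
    before: np.ndarray
    after: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.before = np.asarray(self.before, dtype=float)
        self.after = np.asarray(self.after, dtype=float)
        if not (len(self.subjects) == len(self.before) == len(self.after)):
            raise ValueError("subjects, before and after must have equal length")
        if len(self.before) < 2:
            raise ValueError("paired sample needs n >= 2")
        if np.isnan(self.before).any() or np.isnan(self.after).any():
            raise ValueError("missing pairs are not allowed")

    @property
    def n(self) -> int:
        return len(self.before)

    @property
    def diffs(self) -> np.ndarray:
        return self.after - self.before


@dataclass
class EffectReport:
    """One table row of the before/after inference for a single variable.

    Mirrors the layout Before | After | Delta | P | ES | +ive | Trivial |
    -ive | Inference.  ``chances`` holds (positive, trivial, negative) in
    percent at full precision; ``chances_int`` the rounded display values.
    """

    variable: str
    n: int
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    delta_mean: float
    delta_sd: float
    t: float
    p: float
    d: float
    d_label: str
    swc: float
    chances: tuple[float, float, float]
    chances_int: tuple[int, int, int] = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.chances_int = tuple(_round_half_up(c) for c in self.chances)
        self.label = mbi_label(self.chances)

    def summary(self) -> str:
        pos, tri, neg = self.chances_int
        return (
            f"{self.variable:<12} {self.mean_before:8.2f}±{self.sd_before:<7.2f}"
            f" {self.mean_after:8.2f}±{self.sd_after:<7.2f}"
            f" Δ={self.delta_mean:+8.2f}±{self.delta_sd:<7.2f}"
            f" P={self.p:5.2f} ES={self.d:+5.2f} ({self.d_label})"
            f"  +ive/triv/−ive = {pos}/{tri}/{neg}  → {self.label}"
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def delta_summary(s: PairedSample) -> tuple[float, float]:
    """Mean and sample SD (n−1) of the per-subject after−before differences."""
    d = s.diffs
    return float(np.mean(d)), float(np.std(d, ddof=1))


def paired_t(s: PairedSample) -> tuple[float, float]:
    """Paired Student t statistic and two-sided p, df = n−1.

    Zero-variance differences are degenerate: t is ±inf (or 0 for identical
    vectors) and p is 0 (or 1).
    """
    dmean, dsd = delta_summary(s)
    n = s.n
    if dsd == 0.0:
        if dmean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, dmean), 0.0
    t = dmean / (dsd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def oneway_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across ≥2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Standardized mean difference using the pooled SD of the two moments.

    d = (mean2 − mean1) / sqrt((sd1² + sd2²) / 2)
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    pooled = math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if pooled == 0.0:
        raise ValueError("both SDs are zero")
    return (mean2 - mean1) / pooled


def magnitude_label(d: float) -> str:
    """Qualitative magnitude of an effect size: thresholds >0.2 small,
    >0.5 moderate, >0.8 large; |d| ≤ 0.2 is trivial."""
    a = abs(d)
    if a <= 0.2:
        return "trivial"
    if a <= 0.5:
        return "small"
    if a <= 0.8:
        return "moderate"
    return "large"


def swc(sd_between: float, factor: float = 0.2) -> float:
    """Smallest worthwhile change: 0.2 × the between-subject SD."""
    if sd_between <= 0:
        raise ValueError("between-subject SD must be positive")
    return factor * sd_between


def mbi_chances(
    delta_mean: float,
    delta_sd: float,
    n: int,
    swc: float,
    dist: str = "normal",
) -> tuple[float, float, float]:
    """Chances (%) that the true mean change is positive / trivial / negative.

    The true change is taken as distributed around the observed mean change
    with SE = delta_sd / sqrt(n); "positive" is mass above +swc, "negative"
    mass below −swc, "trivial" the remainder.  ``dist`` selects the sampling
    distribution: "normal" (default) or "t" (df = n−1).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if swc < 0:
        raise ValueError("swc must be >= 0")
    se = delta_sd / math.sqrt(n)
    if se == 0.0:
        if delta_mean > swc:
            return 100.0, 0.0, 0.0
        if delta_mean < -swc:
            return 0.0, 0.0, 100.0
        return 0.0, 100.0, 0.0
    if dist == "normal":
        def cdf(z):
            return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
    elif dist == "t":
        def cdf(z):  # noqa: ANN001 - scalar shim
            return sps.t.cdf(z, df=n - 1)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    # positive = 1 - cdf((swc - delta)/se), written via cdf symmetry so the
    # delta -> -delta swap of positive/negative is exact in floating point
    negative = float(cdf((-swc - delta_mean) / se)) * 100.0
    positive = float(cdf((delta_mean - swc) / se)) * 100.0
    trivial = 100.0 - negative - positive
    return positive, trivial, negative


_QUAL_SCALE = (
    (1.0, "almost certainly not"),
    (5.0, "very unlikely"),
    (25.0, "unlikely"),
    (75.0, "possibly"),
    (95.0, "likely"),
    (99.0, "very likely"),
    (math.inf, "almost certain"),
)


def _qualitative_term(chance_pct: float) -> str:
    for bound, term in _QUAL_SCALE:
        if chance_pct <= bound:
            return term
    raise AssertionError("unreachable")


def mbi_label(chances: tuple[float, float, float], unclear_pct: float = 5.0) -> str:
    """Qualitative inference for (positive, trivial, negative) chances.

    If both the positive and negative chances exceed ``unclear_pct`` the
    outcome is "unclear"; otherwise the dominant category is described with
    the probabilistic term matching its chance (e.g. "very likely negative").
    Ties for the dominant category are reported as "unclear".
    """
    pos, tri, neg = chances
    if pos > unclear_pct and neg > unclear_pct:
        return "unclear"
    cats = ("positive", "trivial", "negative")
    vals = (pos, tri, neg)
    mx = max(vals)
    winners = [c for c, v in zip(cats, vals) if v == mx]
    if len(winners) > 1:
        return "unclear"
    return f"{_qualitative_term(mx)} {winners[0]}"


def effect_report(
    s: PairedSample,
    variable: str = "",
    swc_basis: str = "pooled",
    dist: str = "normal",
) -> EffectReport:
    """Compose the full inference row for one paired variable.

    ``swc_basis`` selects the between-subject SD used for the smallest
    worthwhile change: "pooled" (pooled SD of the two moments, default) or
    "baseline" (SD of the before moment).
    """
    mb, sb = float(np.mean(s.before)), float(np.std(s.before, ddof=1))
    ma, sa = float(np.mean(s.after)), float(np.std(s.after, ddof=1))
    dmean, dsd = delta_summary(s)
    t, p = paired_t(s)
    d = cohens_d(mb, sb, ma, sa)
    if swc_basis == "pooled":
        sd_between = math.sqrt((sb ** 2 + sa ** 2) / 2.0)
    elif swc_basis == "baseline":
        sd_between = sb
    else:
        raise ValueError(f"unknown swc_basis {swc_basis!r}")
    w = swc(sd_between)
    chances = mbi_chances(dmean, dsd, s.n, w, dist=dist)
    return EffectReport(
        variable=variable,
        n=s.n,
        mean_before=mb,
        sd_before=sb,
        mean_after=ma,
        sd_after=sa,
        delta_mean=dmean,
        delta_sd=dsd,
        t=t,
        p=p,
        d=d,
        d_label=magnitude_label(d),
        swc=w,
        chances=chances,
    )


def effect_table(samples: dict[str, PairedSample], **kwargs) -> list[EffectReport]:
    """Effect reports for a dict of named paired samples, in input order."""
    return [effect_report(s, variable=name, **kwargs) for name, s in samples.items()]
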