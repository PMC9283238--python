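"""Group comparison statistics for the two study layers.

Periosteal layer (one averaged value per specimen): each parameter is
gated through a Shapiro-Wilk normality check per group; if every group
passes, a one-way ANOVA with post hoc Tukey HSD compares the three
groups, otherwise a Kruskal-Wallis test is used.

Perilacunar layer (pooled point distributions, 144 points per group per
lacunar distance in the reference design): pairs of group distributions
are compared with BOTH the two-sample Kolmogorov-Smirnov test (sensitive
to the bulk of the distribution) and the two-sample Anderson-Darling test
(sensitive to the tails), at a Bonferroni-adjusted level
``alpha = 0.05 / m`` (0.0167 for the three group pairs).  A pair is
called shifted only when both tests reject — a conservative conjunction —
and the direction ("right-shifted") is assigned to the sample with the
larger median.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "Route",
    "ShiftDirection",
    "ShiftResult",
    "GroupComparison",
    "normality_gate",
    "omnibus_and_posthoc",
    "compare_groups",
    "ks_two_sample",
    "ad_two_sample",
    "shift_call",
]

GROUPS = ("CTRL", "CKD", "CKD_KP")
DEFAULT_ALPHA = 0.05


class Route(str, enum.Enum):
    PARAMETRIC = "parametric"
    NONPARAMETRIC = "nonparametric"


class ShiftDirection(str, enum.Enum):
    RIGHT_SHIFTED_A = "right_shifted_A"
    RIGHT_SHIFTED_B = "right_shifted_B"
    NONE = "none"


class DecisionRule(str, enum.Enum):
    """Whether a shift call needs both tests to reject or either one."""

    BOTH = "both"
    EITHER = "either"


@dataclass(frozen=True)
class GroupTable:
    """Per-specimen values of one parameter, keyed by group label."""

    values: Mapping[str, np.ndarray]
    parameter: str = ""
    units: str = ""

    def __post_init__(self):
        clean = {g: np.asarray(v, dtype=float).ravel()
                 for g, v in self.values.items()}
        if len(clean) < 2:
            raise ValueError("need at least two groups")
        object.__setattr__(self, "values", clean)

    def require_min_n(self, n: int) -> None:
        for g, v in self.values.items():
            if v.size < n:
                raise ValueError(
                    f"group {g} has {v.size} specimens; need >= {n}")


@dataclass(frozen=True)
class RoutingDecision:
    route: Route
    shapiro_p: dict[str, float]
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    p_value: float | None  # None when the omnibus did not reject
    tested: bool


@dataclass(frozen=True)
class GroupComparison:
    parameter: str
    route: Route
    omnibus_stat: float
    omnibus_p: float
    pairwise: tuple[PairwiseResult, ...]


@dataclass(frozen=True)
class ShiftResult:
    """Distribution-shift call for one group pair (and optionally distance)."""

    pair: tuple[str, str]
    parameter: str
    ks_statistic: float
    ks_p: float
    ad_statistic: float
    ad_p: float
    adjusted_alpha: float
    significant: bool
    direction: ShiftDirection
    distance_um: float | None = None
    median_tie: bool = False


def normality_gate(t: GroupTable, alpha: float = 0.05) -> RoutingDecision:
    """Route to ANOVA only when every group passes Shapiro-Wilk at alpha.

    Constant (zero-variance) groups cannot be tested for normality and fall
    through to the nonparametric route with a degeneracy flag.
    """
    t.require_min_n(3)
    pvals: dict[str, float] = {}
    degenerate = False
    for g, v in t.values.items():
        if np.ptp(v) == 0.0:
            pvals[g] = float("nan")
            degenerate = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[g] = float(sps.shapiro(v).pvalue)
    if degenerate:
        return RoutingDecision(Route.NONPARAMETRIC, pvals, degenerate=True)
    route = Route.PARAMETRIC if all(p >= alpha for p in pvals.values()) \
        else Route.NONPARAMETRIC
    return RoutingDecision(route, pvals)


def omnibus_and_posthoc(t: GroupTable, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA; Tukey HSD pairwise p-values when the omnibus rejects.

    Tukey HSD uses the studentized-range distribution with the classical
    pooled within-group variance (balanced or unbalanced).
    """
    groups = list(t.values)
    arrays = [t.values[g] for g in groups]
    if all(np.ptp(a) == 0.0 for a in arrays):
        raise ValueError("zero within-group variance in every group; "
                         "ANOVA is degenerate")
    f, p = sps.f_oneway(*arrays)
    pairs = [(groups[i], groups[j]) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    if p < alpha:
        hsd = sps.tukey_hsd(*arrays)
        pairwise = tuple(
            PairwiseResult(pair=(a, b),
                           p_value=float(hsd.pvalue[groups.index(a),
                                                    groups.index(b)]),
                           tested=True)
            for a, b in pairs)
    else:
        pairwise = tuple(PairwiseResult(pair=pr, p_value=None, tested=False)
                         for pr in pairs)
    return GroupComparison(parameter=t.parameter, route=Route.PARAMETRIC,
                           omnibus_stat=float(f), omnibus_p=float(p),
                           pairwise=pairwise)


def compare_groups(t: GroupTable, alpha: float = 0.05) -> GroupComparison:
    """Normality-gated group comparison: ANOVA+Tukey or Kruskal-Wallis."""
    decision = normality_gate(t, alpha)
    if decision.route is Route.PARAMETRIC:
        return omnibus_and_posthoc(t, alpha)
    arrays = list(t.values.values())
    h, p = sps.kruskal(*arrays)
    pairs = [(a, b) for i, a in enumerate(t.values) for b in list(t.values)[i + 1:]]
    pairwise = tuple(PairwiseResult(pair=pr, p_value=None, tested=False)
                     for pr in pairs)
    return GroupComparison(parameter=t.parameter, route=Route.NONPARAMETRIC,
                           omnibus_stat=float(h), omnibus_p=float(p),
                           pairwise=pairwise)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def ad_two_sample(x: Sequence[float], y: Sequence[float], *,
                  permutation: bool = False, n_permutations: int = 2000,
                  seed: int = 0) -> tuple[float, float]:
    """Two-sample Anderson-Darling (rank form, midrank tie handling).

    The p-value comes from the standard k-sample approximation: a
    quadratic interpolation of log significance against the tabulated
    critical values of the normalized statistic, extrapolated (and clipped
    to (0, 1]) outside the tabulated 0.1%-25% range so that clearly
    non-separated samples report a large p instead of an artificial cap.
    With ``permutation=True`` the p-value is estimated instead by a seeded
    permutation resampling of the pooled sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("AD test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        raise ValueError("all observations tied; AD statistic degenerate")
    if permutation:
        method = sps.PermutationMethod(
            n_resamples=n_permutations, rng=np.random.default_rng(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.anderson_ksamp([x, y], midrank=True, method=method)
        return float(res.statistic), float(res.pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p-value capping notice
        res = sps.anderson_ksamp([x, y], midrank=True)
    levels = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])
    fit = np.polyfit(res.critical_values, np.log(levels), 2)
    p = float(np.exp(np.polyval(fit, res.statistic)))
    return float(res.statistic), min(max(p, np.finfo(float).tiny), 1.0)


def shift_call(x: Sequence[float], y: Sequence[float], *,
               m_comparisons: int = 3, alpha: float = DEFAULT_ALPHA,
               pair: tuple[str, str] = ("A", "B"), parameter: str = "",
               distance_um: float | None = None,
               rule: DecisionRule = DecisionRule.BOTH) -> ShiftResult:
    """Joint KS+AD distribution-shift call at a Bonferroni-adjusted level.

    ``adjusted_alpha = alpha / m_comparisons``; with the default BOTH rule
    a shift is significant only when the KS and the AD p-values are each
    below the adjusted level.  Direction goes to the sample with the larger
    median; a median tie with significance is reported as direction NONE
    with the tie flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    adjusted = alpha / m_comparisons
    ks_d, ks_p = ks_two_sample(x, y)
    ad_a2, ad_p = ad_two_sample(x, y)
    if rule is DecisionRule.BOTH:
        significant = (ks_p < adjusted) and (ad_p < adjusted)
    else:
        significant = (ks_p < adjusted) or (ad_p < adjusted)
    direction = ShiftDirection.NONE
    tie = False
    if significant:
        mx, my = float(np.median(x)), float(np.median(y))
        if mx > my:
            direction = ShiftDirection.RIGHT_SHIFTED_A
        elif my > mx:
            direction = ShiftDirection.RIGHT_SHIFTED_B
        else:
            tie = True
    return ShiftResult(pair=pair, parameter=parameter, ks_statistic=ks_d,
                       ks_p=ks_p, ad_statistic=ad_a2, ad_p=ad_p,
                       adjusted_alpha=adjusted, significant=significant,
                       direction=direction, distance_um=distance_um,
                       median_tie=tie)
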