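"""Geographical-detector engine: factor q, discretization search, interactions.

The q-statistic measures how much a stratification X of the study units
explains the spatial variation of a response Y (here, facility counts per
city). With N units split into m strata of sizes n_h,

    q = 1 - sum_h n_h * sigma_h^2 / (N * sigma^2)

using *population* variances throughout (the n_h sigma_h^2 weighting of the
within-stratum sum of squares only makes sense with the population
convention, so it is fixed package-wide). q = 1 - SSW/SST in ANOVA terms:
q = 0 when the stratification explains nothing, q = 1 when Y is constant
within every stratum.

Significance follows the standard geodetector test: the transformed statistic

    F = (N - m)/(m - 1) * q/(1 - q)

is referred to a noncentral F(m-1, N-m; lambda) with

    lambda = (1/sigma^2) * [ sum_h ybar_h^2 - (sum_h sqrt(n_h) ybar_h)^2 / N ]

(the standard geodetector significance test; note the first sum over squared
stratum means is unweighted).

Continuous covariates are discretized before detection; four classifiers
(Jenks natural breaks, quantiles, geometric intervals, standard deviations)
over k = 3..10 classes are searched, keeping the scheme that maximizes q.
Pairwise interactions overlay two stratifications and type the overlay q
against q1, q2 and q1 + q2 (enhancement/weakening taxonomy).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import CityRecord

METHODS = ("natural_breaks", "quantile", "geometric_interval", "std_dev")
DEFAULT_K_RANGE = (3, 10)
INTERACTION_EPS = 1e-9

INTERACTION_TYPES = (
    "nonlinear_weakening",
    "single_factor_nonlinear_weakening",
    "dual_factor_enhancement",
    "independent",
    "nonlinear_enhancement",
)


# ---------------------------------------------------------------------------
# stratified sample and the q statistic


@dataclass
class StratifiedSample:
    """Response values grouped by stratum labels (population variances)."""

    y: np.ndarray
    strata: np.ndarray
    N: int
    m: int
    n_h: np.ndarray
    ybar_h: np.ndarray
    sigma2: float
    sigma2_h: np.ndarray

    @classmethod
    def from_labels(cls, y: Sequence[float], strata: Sequence) -> "StratifiedSample":
        y = np.asarray(y, dtype=float)
        strata = np.asarray(strata)
        if y.shape[0] != strata.shape[0]:
            raise ValueError("y and strata must have equal length")
        if y.shape[0] < 1:
            raise ValueError("empty sample")
        labels, inverse = np.unique(strata, return_inverse=True)
        m = len(labels)
        n_h = np.bincount(inverse, minlength=m).astype(float)
        sums = np.bincount(inverse, weights=y, minlength=m)
        ybar_h = sums / n_h
        sq = np.bincount(inverse, weights=y**2, minlength=m)
        sigma2_h = sq / n_h - ybar_h**2
        sigma2_h = np.maximum(sigma2_h, 0.0)  # clip fp dust
        return cls(
            y=y,
            strata=strata,
            N=int(y.shape[0]),
            m=m,
            n_h=n_h,
            ybar_h=ybar_h,
            sigma2=float(np.var(y)),
            sigma2_h=sigma2_h,
        )


def q_statistic(sample: StratifiedSample) -> float:
    """Explained-variance fraction q = 1 - SSW / (N * sigma^2), in [0, 1]."""
    if sample.N < 2:
        raise ValueError("q-statistic needs at least 2 observations")
    if sample.sigma2 <= 0:
        raise ValueError("response has no variance")
    ssw = float(np.sum(sample.n_h * sample.sigma2_h))
    q = 1.0 - ssw / (sample.N * sample.sigma2)
    if q < 0:
        if q < -1e-12:
            raise AssertionError(f"q = {q} below 0 beyond floating-point dust")
        q = 0.0
    return min(q, 1.0)


def q_significance(sample: StratifiedSample) -> float:
    """Upper-tail p-value of q under the noncentral-F reference distribution."""
    N, m = sample.N, sample.m
    if m < 2:
        raise ValueError("significance needs at least 2 strata")
    if N <= m:
        raise ValueError("no residual degrees of freedom (N <= m)")
    q = q_statistic(sample)
    if q >= 1.0:
        return 0.0
    f_val = (N - m) / (m - 1) * q / (1.0 - q)
    lam = (
        np.sum(sample.ybar_h**2)
        - (np.sum(np.sqrt(sample.n_h) * sample.ybar_h)) ** 2 / N
    ) / sample.sigma2
    lam = max(float(lam), 0.0)
    return float(stats.ncf.sf(f_val, m - 1, N - m, lam))


# ---------------------------------------------------------------------------
# discretization


@dataclass
class DiscretizationScheme:
    method: str
    k: int
    breaks: np.ndarray  # inner break values, strictly ascending

    def assign(self, x: Sequence[float]) -> np.ndarray:
        """Class label (0..k-1) per value; classes are (-inf, b1], (b1, b2], ..."""
        return np.searchsorted(self.breaks, np.asarray(x, dtype=float), side="left")

    def to_dict(self) -> dict:
        return {"method": self.method, "k": self.k, "breaks": list(map(float, self.breaks))}


def _jenks_breaks(x_sorted: np.ndarray, k: int) -> np.ndarray:
    """Exact Jenks natural breaks by dynamic programming.

    Minimizes the within-class sum of squared deviations over all partitions
    of the sorted values into k contiguous classes. O(k n^2).
    """
    n = len(x_sorted)
    pref = np.concatenate([[0.0], np.cumsum(x_sorted)])
    pref2 = np.concatenate([[0.0], np.cumsum(x_sorted**2)])

    # cost[c][j]: best SSD for first j values in c classes
    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            # candidate last-class starts i in [c-1, j); SSD of x_sorted[i:j]
            i = np.arange(c - 1, j)
            s = pref[j] - pref[i]
            s2 = pref2[j] - pref2[i]
            val = cost[c - 1, i] + (s2 - s * s / (j - i))
            a = int(np.argmin(val))
            cost[c][j] = val[a]
            back[c][j] = i[0] + a
    # recover class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        i = back[c][j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop leading 0; indices where classes start
    breaks = [(x_sorted[b - 1] + x_sorted[b]) / 2.0 for b in bounds]
    return np.array(breaks)


def discretize(x: Sequence[float], method: str, k: int) -> DiscretizationScheme:
    """Break a continuous covariate into k ordered classes.

    ``natural_breaks`` is exact Jenks (DP); ``quantile`` uses equal-count
    sample quantiles; ``geometric_interval`` spaces class widths in geometric
    progression over the shifted range (min mapped to 1, ratio max'^(1/k));
    ``std_dev`` places breaks at mean + s*(j - k/2). Duplicate or empty
    classes are merged with a warning; the realized k is reported.
    """
    x = np.asarray(x, dtype=float)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("covariate is constant; cannot discretize")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds {len(distinct)} distinct values")
    if method == "natural_breaks":
        breaks = _jenks_breaks(np.sort(x), k)
    elif method == "quantile":
        qs = np.quantile(x, np.arange(1, k) / k)
        breaks = np.asarray(qs, dtype=float)
    elif method == "geometric_interval":
        lo, hi = float(distinct[0]), float(distinct[-1])
        shift = lo - 1.0  # map the minimum to 1 so ratios are well defined
        r = (hi - shift) ** (1.0 / k)
        breaks = shift + r ** np.arange(1, k)
    else:  # std_dev
        mean = float(np.mean(x))
        s = float(np.std(x, ddof=1))
        breaks = mean + s * (np.arange(1, k) - k / 2.0)
    breaks = np.unique(breaks)
    # drop breaks that produce empty classes
    labels = np.searchsorted(breaks, x, side="left")
    used = np.unique(labels)
    keep = []
    for bi, b in enumerate(breaks):
        # break bi separates class bi from bi+1; keep it only if it splits data
        left = np.any(labels <= bi)
        right = np.any(labels > bi)
        if left and right:
            keep.append(b)
    kept = np.array(keep)
    realized = len(kept) + 1
    if realized < k:
        warnings.warn(
            f"{method} k={k}: {k - realized} empty class(es) merged; realized k={realized}"
        )
    return DiscretizationScheme(method=method, k=realized, breaks=kept)


# ---------------------------------------------------------------------------
# factor detection


@dataclass
class FactorResult:
    factor: str
    q: float
    p: float
    scheme: DiscretizationScheme | str

    def to_dict(self) -> dict:
        scheme = self.scheme if isinstance(self.scheme, str) else self.scheme.to_dict()
        return {"factor": self.factor, "q": self.q, "p": self.p, "scheme": scheme}


def optimize_discretization(
    x: Sequence[float],
    y: Sequence[float],
    methods: Iterable[str] = METHODS,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
) -> tuple[DiscretizationScheme, FactorResult]:
    """Grid-search method x k for the stratification maximizing q.

    Candidates must yield >= 2 non-empty strata; k is silently clipped to the
    number of distinct covariate values. Ties break toward smaller k, then
    the fixed method order, for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    methods = [m for m in METHODS if m in set(methods)]
    if not methods:
        raise ValueError("no valid methods requested")
    k_lo, k_hi = k_range
    k_hi = min(k_hi, len(np.unique(x)))
    best: tuple[float, int, int, DiscretizationScheme] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(k_lo, k_hi + 1):
            for mi, method in enumerate(methods):
                try:
                    scheme = discretize(x, method, k)
                except ValueError:
                    continue
                labels = scheme.assign(x)
                if len(np.unique(labels)) < 2:
                    continue
                sample = StratifiedSample.from_labels(y, labels)
                q = q_statistic(sample)
                cand = (-q, scheme.k, mi, scheme)
                if best is None or cand[:3] < best[:3]:
                    best = cand
    if best is None:
        raise ValueError("no valid discretization candidate found")
    scheme = best[3]
    labels = scheme.assign(x)
    sample = StratifiedSample.from_labels(y, labels)
    q = q_statistic(sample)
    p = q_significance(sample) if sample.N > sample.m else float("nan")
    return scheme, FactorResult(factor="", q=q, p=p, scheme=scheme)


# ---------------------------------------------------------------------------
# interaction detection


@dataclass
class InteractionResult:
    pair: tuple[str, str]
    q1: float
    q2: float
    q12: float
    type: str

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "q1": self.q1,
            "q2": self.q2,
            "q12": self.q12,
            "type": self.type,
        }


def interaction_type(q1: float, q2: float, q12: float, eps: float = INTERACTION_EPS) -> str:
    """Type the overlay q against q1, q2 and their sum.

    Equalities are judged with relative tolerance ``eps``; "independent"
    (q12 exactly q1+q2) is therefore effectively measure-zero.
    """
    scale = max(abs(q1), abs(q2), abs(q12), 1.0)
    tol = eps * scale
    lo, hi, s = min(q1, q2), max(q1, q2), q1 + q2
    if abs(q12 - s) <= tol:
        return "independent"
    if q12 > s:
        return "nonlinear_enhancement"
    if q12 > hi + tol:
        return "dual_factor_enhancement"
    if q12 < lo - tol:
        return "nonlinear_weakening"
    if lo + tol < q12 < hi - tol:
        return "single_factor_nonlinear_weakening"
    # boundary with max(q1,q2): enhancement requires strict >, so treat as
    # the weaker single-factor case
    return "single_factor_nonlinear_weakening" if q12 <= hi + tol else "dual_factor_enhancement"


def interaction_detect(
    y: Sequence[float],
    strata_a: Sequence,
    strata_b: Sequence,
    names: tuple[str, str] = ("A", "B"),
) -> InteractionResult:
    """q of the overlay (cross-classification) of two stratifications."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(strata_a)
    b = np.asarray(strata_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y, strata_a, strata_b must have equal length")
    overlay = np.array([f"{u}|{v}" for u, v in zip(a, b)])
    if len(np.unique(overlay)) < 2:
        raise ValueError("overlay has fewer than 2 non-empty strata")
    q1 = q_statistic(StratifiedSample.from_labels(y, a))
    q2 = q_statistic(StratifiedSample.from_labels(y, b))
    q12 = q_statistic(StratifiedSample.from_labels(y, overlay))
    return InteractionResult(
        pair=names, q1=q1, q2=q2, q12=q12, type=interaction_type(q1, q2, q12)
    )


# ---------------------------------------------------------------------------
# full detection run


def run_factor_detection(
    cities: list[CityRecord],
    response_field: str = "facility_count",
    factors: Sequence[str] | None = None,
    methods: Iterable[str] = METHODS,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
) -> tuple[list[FactorResult], list[InteractionResult]]:
    """Per-factor optimal q plus all pairwise interactions, ranked by q.

    ``response_field`` may be ``facility_count``, ``elderly_pop``,
    ``total_pop`` or any covariate name. Factors default to every covariate
    present in all cities.
    """
    if len(cities) < 3:
        raise ValueError("need at least 3 cities")

    def get(c: CityRecord, name: str) -> float:
        if name in ("facility_count", "elderly_pop", "total_pop", "area_km2"):
            v = getattr(c, name)
            if v is None:
                raise ValueError(f"city {c.region_id!r}: missing {name}")
            return float(v)
        if name not in c.covariates:
            raise ValueError(f"city {c.region_id!r}: missing covariate {name!r}")
        return float(c.covariates[name])

    if factors is None:
        common = set(cities[0].covariates)
        for c in cities[1:]:
            common &= set(c.covariates)
        factors = sorted(common)
    y = np.array([get(c, response_field) for c in cities])
    if np.var(y) == 0:
        raise ValueError("response has no variance")
    factor_results: list[FactorResult] = []
    strata_by_factor: dict[str, np.ndarray] = {}
    for name in factors:
        x = np.array([get(c, name) for c in cities])
        scheme, res = optimize_discretization(x, y, methods=methods, k_range=k_range)
        res.factor = name
        factor_results.append(res)
        strata_by_factor[name] = scheme.assign(x)
    interactions: list[InteractionResult] = []
    for fa, fb in itertools.combinations(factors, 2):
        interactions.append(
            interaction_detect(
                y, strata_by_factor[fa], strata_by_factor[fb], names=(fa, fb)
            )
        )
    factor_results.sort(key=lambda r: (-r.q, r.factor))
    return factor_results, interactions
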