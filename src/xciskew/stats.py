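"""Concordance and reproducibility statistics for paired XCI assays.

Implements the comparisons used to validate the FMR1-based XCI categorisation
against HUMARA:

* a chi-square homogeneity test on per-category sample counts, decomposed
  into per-category partial chi-squares with the expected count taken as the
  two-assay mean within each category — the decomposition under which the
  published per-category partials (0.014 / 0.286 / 1.00 for 36/6/6 vs 37/8/3)
  are reproduced exactly;
* a two-sample Kolmogorov-Smirnov test on per-category values, with the
  asymptotic Kolmogorov p-value under Stephens' small-sample effective-size
  correction (an exact option is available for tiny samples);
* the Brown-Forsythe (median-centred Levene) test for homogeneity of
  replicate variances;
* Shapiro-Wilk normality;
* a concordance summary: category confusion matrix, concordant fraction and
  the accounting of uninformative / borderline ("not accurately defined")
  samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .methylation import CATEGORY_ORDER, Category, Status, XCICall
from .peak_io import DegenerateDataError, PairingError

__all__ = [
    "CategoryCounts",
    "ChiSquareResult",
    "KSResult",
    "BrownForsytheResult",
    "ConcordanceResult",
    "chi2_homogeneity",
    "ks_two_sample",
    "brown_forsythe",
    "normality_test",
    "concordance_summary",
]


@dataclass(frozen=True)
class CategoryCounts:
    """Per-category sample counts for two assays over the same cohort."""

    labels: tuple[str, ...]
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.counts_a) == len(self.counts_b)):
            raise ValueError("labels, counts_a and counts_b must have equal length")
        if any(c < 0 for c in self.counts_a + self.counts_b):
            raise ValueError("counts must be non-negative")
        if sum(self.counts_a) == 0 or sum(self.counts_b) == 0:
            raise ValueError("each count vector needs at least one positive entry")


@dataclass(frozen=True)
class ChiSquareResult:
    labels: tuple[str, ...]
    partials: tuple[float, ...]
    total: float
    df: int
    p: float


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float


@dataclass(frozen=True)
class BrownForsytheResult:
    F: float
    df_between: int
    df_within: int
    p: float


def chi2_homogeneity(counts: CategoryCounts) -> ChiSquareResult:
    """Chi-square homogeneity of two per-category count vectors.

    For category j with counts a_j and b_j, the expected count is the mean
    e_j = (a_j + b_j)/2 and the partial chi-square is
    (a_j - e_j)^2/e_j + (b_j - e_j)^2/e_j; the total is the sum of partials
    with df = k - 1 (k categories contributing counts). Categories with zero
    total count contribute a partial of 0 and are excluded from df, with a
    warning.
    """
    k_effective = 0
    partials: list[float] = []
    for label, a, b in zip(counts.labels, counts.counts_a, counts.counts_b):
        e = (a + b) / 2.0
        if e == 0:
            warnings.warn(
                f"category {label!r} has zero total count; excluded from df",
                stacklevel=2,
            )
            partials.append(0.0)
            continue
        partials.append((a - e) ** 2 / e + (b - e) ** 2 / e)
        k_effective += 1
    if k_effective < 2:
        raise DegenerateDataError("chi-square needs at least two populated categories")
    total = float(sum(partials))
    df = k_effective - 1
    p = float(sps.chi2.sf(total, df))
    return ChiSquareResult(
        labels=counts.labels, partials=tuple(partials), total=total, df=df, p=p
    )


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |F_x(t) - F_y(t)| over the pooled sample points."""
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    fx = np.searchsorted(xs, grid, side="right") / xs.size
    fy = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.max(np.abs(fx - fy)))


def kolmogorov_sf(lam: float, terms: int = 100) -> float:
    """Upper tail of the Kolmogorov distribution, 2*sum (-1)^(j-1) exp(-2 j^2 lam^2)."""
    if lam <= 0:
        return 1.0
    j = np.arange(1, terms + 1)
    s = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * j**2 * lam**2))
    return float(min(1.0, max(0.0, s)))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two right-continuous empirical
    CDFs. The default p-value uses the asymptotic Kolmogorov distribution at
    Stephens' corrected argument

        lambda = (sqrt(ne) + 0.12 + 0.11/sqrt(ne)) * D,  ne = n*m/(n+m),

    which behaves well down to very small samples. ``method='exact'``
    (available for n*m <= 100, tie-free data) uses exact enumeration of the
    D distribution instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    D = _ks_statistic(x, y)
    if method == "exact":
        if x.size * y.size > 100:
            raise ValueError("exact method supported only for n*m <= 100")
        if np.unique(np.concatenate([x, y])).size < x.size + y.size:
            raise ValueError("exact method requires tie-free data")
        p = float(sps.ks_2samp(x, y, method="exact").pvalue)
    elif method == "asymptotic":
        ne = math.sqrt(x.size * y.size / (x.size + y.size))
        lam = (ne + 0.12 + 0.11 / ne) * D
        p = kolmogorov_sf(lam)
    else:
        raise ValueError(f"method must be 'asymptotic' or 'exact', got {method!r}")
    return KSResult(D=D, p=p)


def brown_forsythe(groups: Sequence[Sequence[float]]) -> BrownForsytheResult:
    """Brown-Forsythe homogeneity of variances across replicate groups.

    One-way ANOVA on the absolute deviations from each group's median
    (median-centred Levene test).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    transformed = [np.abs(a - np.median(a)) for a in arrays]
    if all(np.all(t == 0) for t in transformed):
        raise DegenerateDataError(
            "all absolute deviations from group medians are zero — "
            "the variance-homogeneity statistic is undefined"
        )
    F, p = sps.levene(*arrays, center="median")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    return BrownForsytheResult(
        F=float(F), df_between=k - 1, df_within=n_total - k, p=float(p)
    )


def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value for 3 <= n <= 5000."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={arr.size}")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("constant sample — normality is undefined")
    res = sps.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ConcordanceResult:
    """Assay-vs-assay concordance over one sample set.

    ``confusion`` is a k x k matrix over the category order (rows: assay A,
    columns: assay B) counting samples categorised by both assays;
    ``concordant_fraction`` is its trace over its total. The accounting
    fields tally, per assay, the uninformative (homozygous) and borderline
    samples and the combined "not accurately defined" fraction
    (borderline or uninformative, over all samples).
    """

    labels: tuple[str, ...]
    confusion: tuple[tuple[int, ...], ...]
    n_samples: int
    n_categorized_both: int
    n_concordant: int
    concordant_fraction: float
    accounting: Mapping[str, Mapping[str, float]]


def _not_defined(call: XCICall) -> bool:
    return call.status is Status.UNINFORMATIVE_HOMOZYGOUS or call.borderline


def concordance_summary(
    calls_a: Sequence[XCICall], calls_b: Sequence[XCICall]
) -> ConcordanceResult:
    """Pair two call sets by sample and summarise their agreement."""
    a_by_id = {c.sample_id: c for c in calls_a}
    b_by_id = {c.sample_id: c for c in calls_b}
    if len(a_by_id) != len(calls_a) or len(b_by_id) != len(calls_b):
        raise PairingError("duplicate sample ids within a call set")
    only_a = sorted(set(a_by_id) - set(b_by_id))
    only_b = sorted(set(b_by_id) - set(a_by_id))
    if only_a or only_b:
        raise PairingError(
            f"sample sets differ — only in A: {only_a or '—'}; only in B: {only_b or '—'}"
        )

    idx = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    confusion = np.zeros((len(CATEGORY_ORDER), len(CATEGORY_ORDER)), dtype=int)
    for sid, ca in a_by_id.items():
        cb = b_by_id[sid]
        if ca.category is not None and cb.category is not None:
            confusion[idx[ca.category], idx[cb.category]] += 1

    n_both = int(confusion.sum())
    n_conc = int(np.trace(confusion))
    n = len(a_by_id)

    def per_assay(calls: Mapping[str, XCICall]) -> dict[str, float]:
        vals = list(calls.values())
        uninform = sum(c.status is Status.UNINFORMATIVE_HOMOZYGOUS for c in vals)
        borderline = sum(c.borderline for c in vals)
        informative = n - uninform
        return {
            "n": n,
            "uninformative": uninform,
            "uninformative_fraction": uninform / n if n else math.nan,
            "borderline": borderline,
            "borderline_fraction_informative": (
                borderline / informative if informative else math.nan
            ),
            "not_defined": sum(_not_defined(c) for c in vals),
            "not_defined_fraction": (
                sum(_not_defined(c) for c in vals) / n if n else math.nan
            ),
        }

    return ConcordanceResult(
        labels=tuple(c.value for c in CATEGORY_ORDER),
        confusion=tuple(tuple(int(v) for v in row) for row in confusion),
        n_samples=n,
        n_categorized_both=n_both,
        n_concordant=n_conc,
        concordant_fraction=n_conc / n_both if n_both else math.nan,
        accounting={
            "A": per_assay(a_by_id),
            "B": per_assay(b_by_id),
        },
    )
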