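"""Per-allele methylation, XCI skew, category ranges and the stepwise QC call.

The quantitative core of the pipeline. For a heterozygous sample with alleles
1 and 2, each allele's methylation ratio is

    r_i = digested_i / undigested_i

on the assay's configured quantity (areas for HUMARA, heights for the FMR1
mPCR), and the per-allele methylation percentage is the sum-normalised

    percent_i = 100 * r_i / (r1 + r2).

Because the inactive X is methylated and survives methylation-sensitive
digestion, percent_i estimates the fraction of cells in which allele i's X is
inactive; the XCI skew is max(percent_1, percent_2), on the 50-100 scale.
Dividing each digested signal by its own undigested signal cancels the
allele's amplification efficiency, which is what makes the estimator immune
to moderate preferential amplification.

Skew is classified against three boundaries (b1, b2, b3):

    RANDOM             50 <= skew <= b1
    MODERATELY_SKEWED  b1 < skew <= b2
    HIGHLY_SKEWED      b2 < skew <= b3
    COMPLETELY_SKEWED  b3 < skew <= 100

with closed upper endpoints, and a result within +/-``borderline_margin`` of
any boundary is flagged borderline (still categorised, but not accurately).

``stepwise_call`` runs the full decision procedure on all replicates of one
sample x assay: homozygotes are uninformative; allele gaps <= 2 repeats are
unreliable because of stutter overlap; gaps >= 7 repeats require triplicates
(the mean of replicates is more accurate under preferential amplification);
amplification bias beyond 1.3-fold on the replicate-mean undigested signals
disqualifies the result; borderline results are flagged; everything else
is OK.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence

from .allele_call import GenotypeCall, QCFlag, call_alleles
from .peak_io import (
    AggregationError,
    Assay,
    AssayConfig,
    CompleteDigestionError,
    SampleRun,
    UninformativeSampleError,
    XCIError,
)

__all__ = [
    "Category",
    "CATEGORY_ORDER",
    "Status",
    "MethylationResult",
    "XCICall",
    "methylation_percentages",
    "aggregate_replicates",
    "classify",
    "flag_borderline",
    "ratio_display",
    "stepwise_call",
]


class Category(str, enum.Enum):
    RANDOM = "RANDOM"
    MODERATELY_SKEWED = "MODERATELY_SKEWED"
    HIGHLY_SKEWED = "HIGHLY_SKEWED"
    COMPLETELY_SKEWED = "COMPLETELY_SKEWED"


#: Category order used for monotonicity checks and confusion matrices.
CATEGORY_ORDER = (
    Category.RANDOM,
    Category.MODERATELY_SKEWED,
    Category.HIGHLY_SKEWED,
    Category.COMPLETELY_SKEWED,
)


class Status(str, enum.Enum):
    OK = "OK"
    UNINFORMATIVE_HOMOZYGOUS = "UNINFORMATIVE_HOMOZYGOUS"
    UNRELIABLE_STUTTER = "UNRELIABLE_STUTTER"
    TRIPLICATE_REQUIRED = "TRIPLICATE_REQUIRED"
    BIASED = "BIASED"
    BORDERLINE = "BORDERLINE"

    @property
    def usable(self) -> bool:
        """Whether the category counts as accurately defined."""
        return self is Status.OK


@dataclass(frozen=True)
class MethylationResult:
    """Per-allele methylation percentages; the two always sum to 100."""

    percent_allele1: float
    percent_allele2: float
    ratios: tuple[float, float]


@dataclass(frozen=True)
class XCICall:
    """Final per-sample XCI determination for one assay."""

    sample_id: str
    assay: Assay
    status: Status
    n_replicates: int
    repeats: tuple[int, ...]
    repeat_difference: int
    bias_ratio: float
    percent_allele1: float | None
    percent_allele2: float | None
    skew: float | None
    ratio: str | None  # display form "[x:y]", allele order ascending by repeat
    category: Category | None
    borderline: bool


def methylation_percentages(genotype: GenotypeCall, config: AssayConfig) -> MethylationResult:
    """Sum-normalised per-allele methylation percentages for one replicate."""
    if len(genotype.alleles) != 2:
        raise UninformativeSampleError(
            f"sample {genotype.sample_id!r} assay {genotype.assay.value}: "
            "homozygous — methylation percentages are uninformative for XCI"
        )
    a1, a2 = genotype.alleles
    if a1.undigested_signal <= 0 or a2.undigested_signal <= 0:
        raise UninformativeSampleError(
            f"sample {genotype.sample_id!r}: undigested signal missing for an allele"
        )
    r1 = a1.digested_signal / a1.undigested_signal
    r2 = a2.digested_signal / a2.undigested_signal
    total = r1 + r2
    if total <= 0:
        raise CompleteDigestionError(
            f"sample {genotype.sample_id!r} assay {genotype.assay.value} replicate "
            f"{genotype.replicate}: no digested signal on either allele — "
            "digestion control failed"
        )
    p1 = 100.0 * r1 / total
    return MethylationResult(percent_allele1=p1, percent_allele2=100.0 - p1, ratios=(r1, r2))


def aggregate_replicates(results: Sequence[MethylationResult]) -> MethylationResult:
    """Arithmetic mean of the replicate percentages (triplicate averaging)."""
    results = list(results)
    if not results:
        raise AggregationError("no replicate methylation results to aggregate")
    p1 = fmean(r.percent_allele1 for r in results)
    r1 = fmean(r.ratios[0] for r in results)
    r2 = fmean(r.ratios[1] for r in results)
    return MethylationResult(percent_allele1=p1, percent_allele2=100.0 - p1, ratios=(r1, r2))


def classify(skew: float, config: AssayConfig) -> Category:
    """Map a skew value onto the four XCI pattern categories."""
    if not (50.0 <= skew <= 100.0) or not math.isfinite(skew):
        raise ValueError(f"skew must lie in [50, 100], got {skew}")
    b1, b2, b3 = config.category_boundaries
    if skew <= b1:
        return Category.RANDOM
    if skew <= b2:
        return Category.MODERATELY_SKEWED
    if skew <= b3:
        return Category.HIGHLY_SKEWED
    return Category.COMPLETELY_SKEWED


def flag_borderline(skew: float, config: AssayConfig) -> bool:
    """True when the skew sits within the margin of any category boundary."""
    if not (50.0 <= skew <= 100.0) or not math.isfinite(skew):
        raise ValueError(f"skew must lie in [50, 100], got {skew}")
    return any(abs(skew - b) <= config.borderline_margin for b in config.category_boundaries)


def ratio_display(percent_allele1: float, percent_allele2: float) -> str:
    """Integer ``[x:y]`` display with x + y = 100 (largest-remainder rounding).

    The allele order (ascending repeat count) is preserved; classification
    always uses the unrounded values.
    """
    f1, f2 = math.floor(percent_allele1), math.floor(percent_allele2)
    x, y = f1, f2
    remainder = 100 - f1 - f2
    frac1 = percent_allele1 - f1
    frac2 = percent_allele2 - f2
    for _ in range(remainder):
        if frac1 >= frac2:
            x += 1
            frac1 -= 1.0
        else:
            y += 1
            frac2 -= 1.0
    return f"[{x}:{y}]"


def _uninformative_call(sample_id: str, assay: Assay, n: int, repeats: tuple[int, ...]) -> XCICall:
    return XCICall(
        sample_id=sample_id,
        assay=assay,
        status=Status.UNINFORMATIVE_HOMOZYGOUS,
        n_replicates=n,
        repeats=repeats,
        repeat_difference=0,
        bias_ratio=1.0,
        percent_allele1=None,
        percent_allele2=None,
        skew=None,
        ratio=None,
        category=None,
        borderline=False,
    )


def stepwise_call(runs: Sequence[SampleRun], config: AssayConfig) -> XCICall:
    """Run the full stepwise decision procedure on one sample x assay.

    ``runs`` are the replicates of a single sample under a single assay.
    Replicates must agree on the called genotype; methylation percentages are
    averaged across replicates before classification, and the amplification
    bias check is applied to the replicate-mean undigested signals.
    """
    runs = sorted(runs, key=lambda r: r.replicate)
    if not runs:
        raise AggregationError("stepwise_call requires at least one replicate run")
    key = {(r.sample_id, r.assay) for r in runs}
    if len(key) != 1:
        raise AggregationError(f"replicates span multiple sample/assay keys: {sorted(key)}")
    sample_id, assay = runs[0].sample_id, runs[0].assay

    genotypes: list[GenotypeCall] = []
    for run in runs:
        try:
            genotypes.append(call_alleles(run, config))
        except XCIError as exc:
            raise type(exc)(f"sample {sample_id!r}: {exc}") from exc

    repeat_sets = {tuple(a.repeat_count for a in g.alleles) for g in genotypes}
    if len(repeat_sets) != 1:
        raise AggregationError(
            f"sample {sample_id!r} assay {assay.value}: discordant genotypes across "
            f"replicates: {sorted(repeat_sets)}"
        )
    repeats = repeat_sets.pop()
    n = len(genotypes)

    if len(repeats) == 1:
        return _uninformative_call(sample_id, assay, n, repeats)

    diff = genotypes[0].repeat_difference
    # Bias is judged on replicate-mean undigested signals, not per replicate.
    u1 = fmean(g.alleles[0].undigested_signal for g in genotypes)
    u2 = fmean(g.alleles[1].undigested_signal for g in genotypes)
    bias = max(u1, u2) / min(u1, u2) if min(u1, u2) > 0 else math.inf

    meth = aggregate_replicates([methylation_percentages(g, config) for g in genotypes])
    skew = max(meth.percent_allele1, meth.percent_allele2)
    category = classify(skew, config)
    borderline = flag_borderline(skew, config)

    if 1 <= diff <= 2:
        status = Status.UNRELIABLE_STUTTER
    elif diff >= 7 and n < 3:
        status = Status.TRIPLICATE_REQUIRED
    elif bias > config.bias_ratio_max:
        status = Status.BIASED
    elif borderline:
        status = Status.BORDERLINE
    else:
        status = Status.OK

    return XCICall(
        sample_id=sample_id,
        assay=assay,
        status=status,
        n_replicates=n,
        repeats=repeats,
        repeat_difference=diff,
        bias_ratio=bias,
        percent_allele1=meth.percent_allele1,
        percent_allele2=meth.percent_allele2,
        skew=skew,
        ratio=ratio_display(meth.percent_allele1, meth.percent_allele2),
        category=category,
        borderline=borderline,
    )
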