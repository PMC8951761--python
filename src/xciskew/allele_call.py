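"""Allele calling from undigested/digested peak pairs.

Converts a :class:`~xciskew.peak_io.SampleRun` into at most two called
alleles: peaks are mapped to repeat counts, minus-one-repeat stutter bands are
absorbed into their parent allele's identity (discarded, not corrected), the
digested channel is paired to the undigested alleles by repeat number, and
the genotype is annotated with the QC flags that drive the stepwise decision:

* ``HOMOZYGOUS`` — a single allele; uninformative for XCI.
* ``STUTTER_OVERLAP_RISK`` — alleles 1-2 repeats apart: the larger allele's
  stutter band lands on (or next to) the smaller allele's primary band and
  corrupts its quantification.
* ``LARGE_REPEAT_GAP`` — alleles >= 7 repeats apart: preferential
  amplification of the shorter allele distorts the allele ratio.
* ``AMPLIFICATION_BIAS`` — the two undigested signals differ by more than
  the configured 1.3-fold limit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .peak_io import (
    AmbiguousGenotypeError,
    Assay,
    AssayConfig,
    CalibrationError,
    Channel,
    DropoutError,
    EmptyChannelError,
    Peak,
    SampleRun,
    UninformativeSampleError,
)

__all__ = [
    "QCFlag",
    "AlleleCall",
    "GenotypeCall",
    "size_to_repeats",
    "repeats_to_size",
    "call_alleles",
    "compute_bias_ratio",
]


class QCFlag(str, enum.Enum):
    HOMOZYGOUS = "HOMOZYGOUS"
    STUTTER_OVERLAP_RISK = "STUTTER_OVERLAP_RISK"
    LARGE_REPEAT_GAP = "LARGE_REPEAT_GAP"
    AMPLIFICATION_BIAS = "AMPLIFICATION_BIAS"


@dataclass(frozen=True)
class AlleleCall:
    """Paired digested/undigested signal for one allele."""

    repeat_count: int
    undigested_signal: float
    digested_signal: float
    size_bp: float


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    assay: Assay
    replicate: int
    alleles: tuple[AlleleCall, ...]  # ordered by ascending repeat_count
    repeat_difference: int
    bias_ratio: float  # >= 1; 1.0 for a single allele
    flags: frozenset[QCFlag]

    @property
    def is_homozygous(self) -> bool:
        return QCFlag.HOMOZYGOUS in self.flags


def size_to_repeats(size_bp: float, config: AssayConfig, sample_id: str | None = None) -> int:
    """Convert a fragment size to a repeat count.

    Nearest-integer rounding with half-repeat ties rounded away from zero;
    both channels are sized against the same ladder, so a sub-half-repeat bp
    discrepancy between channels is absorbed here.
    """
    if size_bp < config.size_offset_bp:
        who = f" (sample {sample_id})" if sample_id else ""
        raise CalibrationError(
            f"fragment size {size_bp} bp below calibration offset "
            f"{config.size_offset_bp} bp for locus {config.locus.value}{who}"
        )
    x = (size_bp - config.size_offset_bp) / config.repeat_unit_bp
    return int(math.floor(x + 0.5))  # half away from zero for x >= 0


def repeats_to_size(repeats: int, config: AssayConfig) -> float:
    """Inverse of :func:`size_to_repeats` on exact repeat counts."""
    return config.size_offset_bp + config.repeat_unit_bp * repeats


def _collapse_by_repeat(
    peaks: tuple[Peak, ...], config: AssayConfig, sample_id: str
) -> dict[int, float]:
    """Sum the configured quantity of peaks that round to the same repeat count."""
    out: dict[int, float] = {}
    for p in peaks:
        k = size_to_repeats(p.size_bp, config, sample_id)
        out[k] = out.get(k, 0.0) + p.quantity(config.quantity)
    return out


def _is_stutter(k: int, q: float, signal: dict[int, float], config: AssayConfig) -> bool:
    """Minus-one-repeat stutter: one repeat below a taller peak, and small."""
    parent = signal.get(k + 1)
    return parent is not None and parent > q and q < config.stutter_fraction_max * parent


def call_alleles(run: SampleRun, config: AssayConfig) -> GenotypeCall:
    """Call at most two alleles from one replicate run.

    In the undigested channel the tallest peak is allele 1 and the tallest
    remaining non-stutter peak (if any) is allele 2; more than two non-stutter
    peaks is an ambiguous genotype and the sample is referred to manual
    review. Digested-channel peaks are paired by repeat count; an allele with
    no digested counterpart gets a digested signal of zero (fully
    unmethylated). Calling depends only on relative peak quantities, so it is
    invariant to a global rescaling of the fluorescence scale.
    """
    undig = run.channel_peaks(Channel.UNDIGESTED)
    if not undig:
        raise EmptyChannelError(
            f"sample {run.sample_id!r} assay {run.assay.value} replicate "
            f"{run.replicate}: no undigested-channel peak"
        )
    u_signal = _collapse_by_repeat(undig, config, run.sample_id)
    d_signal = _collapse_by_repeat(run.channel_peaks(Channel.DIGESTED), config, run.sample_id)

    candidates = {
        k: q for k, q in u_signal.items() if not _is_stutter(k, q, u_signal, config)
    }
    if len(candidates) > 2:
        peaks_desc = ", ".join(
            f"{k} repeats ({q:g})" for k, q in sorted(candidates.items())
        )
        raise AmbiguousGenotypeError(
            f"sample {run.sample_id!r} assay {run.assay.value} replicate "
            f"{run.replicate}: {len(candidates)} non-stutter undigested peaks "
            f"({peaks_desc}); manual review required"
        )

    # Deterministic selection: quantity desc, then stutter support desc
    # (a true allele tends to carry its own stutter band), then smaller size.
    def support(k: int) -> int:
        q_below = u_signal.get(k - 1)
        return int(q_below is not None and _is_stutter(k - 1, q_below, u_signal, config))

    order = sorted(candidates, key=lambda k: (-candidates[k], -support(k), k))
    chosen = sorted(order[:2])

    alleles = tuple(
        AlleleCall(
            repeat_count=k,
            undigested_signal=u_signal[k],
            digested_signal=d_signal.get(k, 0.0),
            size_bp=repeats_to_size(k, config),
        )
        for k in chosen
    )

    diff = 0 if len(alleles) == 1 else abs(alleles[1].repeat_count - alleles[0].repeat_count)
    flags: set[QCFlag] = set()
    bias = 1.0
    if len(alleles) == 1:
        flags.add(QCFlag.HOMOZYGOUS)
    else:
        if 1 <= diff <= 2:
            flags.add(QCFlag.STUTTER_OVERLAP_RISK)
        if diff >= 7:
            flags.add(QCFlag.LARGE_REPEAT_GAP)
        u1, u2 = alleles[0].undigested_signal, alleles[1].undigested_signal
        if min(u1, u2) > 0:
            bias = max(u1, u2) / min(u1, u2)
            if bias > config.bias_ratio_max:
                flags.add(QCFlag.AMPLIFICATION_BIAS)

    return GenotypeCall(
        sample_id=run.sample_id,
        assay=run.assay,
        replicate=run.replicate,
        alleles=alleles,
        repeat_difference=diff,
        bias_ratio=bias,
        flags=frozenset(flags),
    )


def compute_bias_ratio(genotype: GenotypeCall, config: AssayConfig) -> float:
    """Undigested signal imbalance max(u1,u2)/min(u1,u2) between the alleles.

    The result exceeds ``config.bias_ratio_max`` exactly when the
    ``AMPLIFICATION_BIAS`` condition holds (the 1.3-fold limit is inclusive:
    a ratio of exactly 1.3 is tolerated).
    """
    if len(genotype.alleles) != 2:
        raise UninformativeSampleError(
            f"sample {genotype.sample_id!r} assay {genotype.assay.value}: "
            "bias ratio requires two called alleles (homozygous sample)"
        )
    u1, u2 = (a.undigested_signal for a in genotype.alleles)
    if min(u1, u2) <= 0:
        raise DropoutError(
            f"sample {genotype.sample_id!r}: undigested allele dropout "
            f"(signals {u1:g}, {u2:g})"
        )
    return max(u1, u2) / min(u1, u2)
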