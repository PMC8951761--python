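"""Peak-table and assay-configuration I/O.

Core record types for methylation-sensitive fragment analysis: a :class:`Peak`
is one sized, quantified capillary-electrophoresis band in either the digested
or the undigested reaction; a :class:`SampleRun` collects all peaks for one
sample x assay x replicate; an :class:`AssayConfig` carries the calibration
and decision parameters of one assay (HUMARA on the AR CAG repeat, "Assay A",
or the FMR1 mPCR on the CGG repeat, "Assay B").

The interchange format is a flat tab- or comma-delimited table with the seven
columns ``sample_id assay replicate channel size_bp height area`` — the shape
of a GeneMapper genotype-table export after dye channels have been reduced to
digested/undigested. Dye identity is deliberately not retained: Assay A runs
the two templates as separate single-dye reactions and Assay B as a FAM/HEX
duplex, but every downstream computation only needs the digested vs undigested
distinction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Channel",
    "Assay",
    "Locus",
    "Quantity",
    "Peak",
    "SampleRun",
    "AssayConfig",
    "PEAK_TABLE_COLUMNS",
    "read_peak_table",
    "write_peak_table",
    "load_config",
    "default_configs",
    "XCIError",
    "PeakTableError",
    "FormatError",
    "DuplicateRecordError",
    "EmptyInputError",
    "ConfigError",
    "CalibrationError",
    "AmbiguousGenotypeError",
    "EmptyChannelError",
    "DropoutError",
    "CompleteDigestionError",
    "UninformativeSampleError",
    "AggregationError",
    "PairingError",
    "DegenerateDataError",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class XCIError(Exception):
    """Base class for all pipeline errors."""


class PeakTableError(XCIError):
    """Problem with a peak-table file."""


class FormatError(PeakTableError):
    """Missing columns or malformed cells (reported with row numbers)."""


class DuplicateRecordError(PeakTableError):
    """Two rows describe the same (sample, assay, replicate, channel, size)."""


class EmptyInputError(PeakTableError):
    """The input contains no data rows."""


class ConfigError(XCIError):
    """Invalid assay or simulation configuration."""


class CalibrationError(XCIError):
    """Fragment size incompatible with the repeat calibration."""


class AmbiguousGenotypeError(XCIError):
    """More than two non-stutter peaks in the undigested channel."""


class EmptyChannelError(XCIError):
    """A required channel contains no peaks."""


class DropoutError(XCIError):
    """An undigested allele signal is zero (allele dropout)."""


class CompleteDigestionError(XCIError):
    """No digested signal on either allele — failed digestion control.

    Biologically implausible for a female sample: one X per cell is
    methylated, so some template must survive the methylation-sensitive
    digestion.
    """


class UninformativeSampleError(XCIError):
    """Homozygous at the repeat locus — no allele-specific signal."""


class AggregationError(XCIError):
    """Replicates cannot be combined (discordant genotypes, empty input)."""


class PairingError(XCIError):
    """The two call sets do not cover the same samples."""


class DegenerateDataError(XCIError):
    """A statistic is undefined on this input (e.g. zero spread everywhere)."""


# ---------------------------------------------------------------------------
# Enums and records
# ---------------------------------------------------------------------------

class Channel(str, enum.Enum):
    """Reaction channel: with (+) or without (-) methylation-sensitive digestion."""

    UNDIGESTED = "undigested"
    DIGESTED = "digested"

    @classmethod
    def parse(cls, value: str) -> "Channel":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise FormatError(
                f"unknown channel {value!r}; expected 'undigested' or 'digested'"
            ) from None


class Assay(str, enum.Enum):
    A = "A"  # HUMARA (AR CAG repeat), methylation quantified on peak areas
    B = "B"  # FMR1 mPCR (CGG repeat), methylation quantified on peak heights

    @classmethod
    def parse(cls, value: str) -> "Assay":
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise FormatError(f"unknown assay {value!r}; expected 'A' or 'B'") from None


class Locus(str, enum.Enum):
    AR_CAG = "AR_CAG"
    FMR1_CGG = "FMR1_CGG"


class Quantity(str, enum.Enum):
    """Which peak measurement feeds the methylation formula."""

    AREA = "area"
    HEIGHT = "height"


@dataclass(frozen=True)
class Peak:
    """One sized, quantified CE peak in a digested or undigested channel."""

    channel: Channel
    size_bp: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if not isinstance(self.channel, Channel):
            object.__setattr__(self, "channel", Channel.parse(self.channel))
        if not self.size_bp > 0:
            raise ValueError(f"size_bp must be positive, got {self.size_bp}")
        if self.height < 0 or self.area < 0:
            raise ValueError("height and area must be non-negative")

    def quantity(self, which: Quantity) -> float:
        return self.area if which is Quantity.AREA else self.height


@dataclass(frozen=True)
class SampleRun:
    """All peaks of one sample x assay x replicate, both channels together."""

    sample_id: str
    assay: Assay
    replicate: int
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if not isinstance(self.assay, Assay):
            object.__setattr__(self, "assay", Assay.parse(self.assay))
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    def channel_peaks(self, channel: Channel) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.channel is channel)

    @property
    def key(self) -> tuple[str, Assay, int]:
        return (self.sample_id, self.assay, self.replicate)


#: Table 1 closures for Assay B: random up to and including 75:25, moderate
#: up to and including 89:11, high up to and including 99:1, complete beyond.
DEFAULT_BOUNDARIES_B = (75.0, 89.0, 99.0)
#: Assay A ranges (previously established for HUMARA; surfaced as an
#: assumption — override in config if the laboratory uses different cut-offs).
DEFAULT_BOUNDARIES_A = (80.0, 90.0, 99.0)


@dataclass(frozen=True)
class AssayConfig:
    """Calibration and decision parameters of one assay.

    Parameters
    ----------
    locus
        Repeat locus the assay amplifies.
    repeat_unit_bp
        Size of one repeat unit in base pairs (3 for CAG/CGG).
    size_offset_bp
        Fragment length at zero repeats (primer flanks); instrument/kit
        specific and configurable — it cancels out of every downstream rule,
        which depends only on repeat differences.
    quantity
        Peak measurement used for methylation: areas for the AR assay,
        heights for the FMR1 assay (overridable).
    stutter_fraction_max
        A peak one repeat below a taller peak is treated as its stutter band
        when its quantity is below this fraction of the parent's.
    bias_ratio_max
        Maximum tolerated ratio between the two undigested allele signals
        before the result is considered distorted by preferential
        amplification (1.3, i.e. "1:1.3 or 1.3:1").
    borderline_margin
        Half-width (percentage points) of the borderline zone around each
        category boundary (+/-2).
    category_boundaries
        The three skew thresholds separating random / moderately skewed /
        highly skewed / completely skewed patterns, on the 50-100 scale.
    """

    locus: Locus
    repeat_unit_bp: float = 3.0
    size_offset_bp: float = 230.0
    quantity: Quantity = Quantity.HEIGHT
    stutter_fraction_max: float = 0.15
    bias_ratio_max: float = 1.3
    borderline_margin: float = 2.0
    category_boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES_B

    def __post_init__(self) -> None:
        if not isinstance(self.locus, Locus):
            object.__setattr__(self, "locus", Locus(str(self.locus)))
        if not isinstance(self.quantity, Quantity):
            object.__setattr__(self, "quantity", Quantity(str(self.quantity).lower()))
        b = tuple(float(x) for x in self.category_boundaries)
        object.__setattr__(self, "category_boundaries", b)
        if len(b) != 3 or not (b[0] < b[1] < b[2]):
            raise ConfigError(f"category boundaries must be strictly increasing, got {b}")
        if not all(50.0 < x < 100.0 for x in b):
            raise ConfigError(f"category boundaries must lie in (50, 100), got {b}")
        if self.repeat_unit_bp <= 0:
            raise ConfigError("repeat_unit_bp must be positive")
        if not (0.0 < self.stutter_fraction_max < 1.0):
            raise ConfigError("stutter_fraction_max must be in (0, 1)")
        if self.bias_ratio_max <= 1.0:
            raise ConfigError(f"bias_ratio_max must exceed 1, got {self.bias_ratio_max}")
        if self.borderline_margin < 0:
            raise ConfigError("borderline_margin must be >= 0")


def default_config_a() -> AssayConfig:
    """HUMARA defaults: AR CAG locus, area-based quantification."""
    return AssayConfig(
        locus=Locus.AR_CAG,
        size_offset_bp=170.0,
        quantity=Quantity.AREA,
        category_boundaries=DEFAULT_BOUNDARIES_A,
    )


def default_config_b() -> AssayConfig:
    """FMR1 mPCR defaults: CGG locus, height-based quantification."""
    return AssayConfig(
        locus=Locus.FMR1_CGG,
        size_offset_bp=230.0,
        quantity=Quantity.HEIGHT,
        category_boundaries=DEFAULT_BOUNDARIES_B,
    )


def default_configs() -> dict[Assay, AssayConfig]:
    return {Assay.A: default_config_a(), Assay.B: default_config_b()}


# ---------------------------------------------------------------------------
# Peak-table reading / writing
# ---------------------------------------------------------------------------

PEAK_TABLE_COLUMNS = (
    "sample_id",
    "assay",
    "replicate",
    "channel",
    "size_bp",
    "height",
    "area",
)

_CHANNEL_ORDER = {Channel.UNDIGESTED: 0, Channel.DIGESTED: 1}


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peak_table(path: str | Path, dialect: str | None = None) -> list[SampleRun]:
    """Read a peak table into grouped :class:`SampleRun` records.

    Rows are grouped by (sample_id, assay, replicate); the grouping is
    insensitive to input row order. Malformed numeric cells are reported with
    their (1-based, header-inclusive) row numbers.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty peak table") from None

    missing = [c for c in PEAK_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: peak table has a header but no data rows")

    bad: list[str] = []
    records: list[tuple] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        rowno = idx + 2  # 1-based with header
        try:
            assay = Assay.parse(getattr(row, "assay"))
            channel = Channel.parse(getattr(row, "channel"))
            replicate = int(str(getattr(row, "replicate")).strip())
            size_bp = float(getattr(row, "size_bp"))
            height = float(getattr(row, "height"))
            area = float(getattr(row, "area"))
            if not math.isfinite(size_bp) or not math.isfinite(height) or not math.isfinite(area):
                raise ValueError("non-finite value")
            peak = Peak(channel=channel, size_bp=size_bp, height=height, area=area)
        except (ValueError, FormatError) as exc:
            bad.append(f"row {rowno}: {exc}")
            continue
        records.append((str(getattr(row, "sample_id")), assay, replicate, size_bp, peak))
    if bad:
        raise FormatError(f"{path}: malformed cells — " + "; ".join(bad))

    seen: set[tuple] = set()
    groups: dict[tuple[str, Assay, int], list[Peak]] = {}
    for sample_id, assay, replicate, size_bp, peak in records:
        dup_key = (sample_id, assay, replicate, peak.channel, size_bp)
        if dup_key in seen:
            raise DuplicateRecordError(
                f"{path}: duplicate row for sample {sample_id!r} assay {assay.value} "
                f"replicate {replicate} channel {peak.channel.value} size {size_bp}"
            )
        seen.add(dup_key)
        groups.setdefault((sample_id, assay, replicate), []).append(peak)

    runs = []
    for (sample_id, assay, replicate), peaks in groups.items():
        peaks.sort(key=lambda p: (_CHANNEL_ORDER[p.channel], p.size_bp))
        runs.append(SampleRun(sample_id=sample_id, assay=assay, replicate=replicate, peaks=tuple(peaks)))
    runs.sort(key=lambda r: (r.sample_id, r.assay.value, r.replicate))
    return runs


def runs_to_frame(runs: Iterable[SampleRun]) -> pd.DataFrame:
    """Flatten runs into the canonical seven-column table, deterministically ordered."""
    rows = []
    for run in runs:
        for peak in run.peaks:
            rows.append(
                (
                    run.sample_id,
                    run.assay.value,
                    run.replicate,
                    peak.channel.value,
                    peak.size_bp,
                    peak.height,
                    peak.area,
                )
            )
    frame = pd.DataFrame(rows, columns=list(PEAK_TABLE_COLUMNS))
    frame["_chan"] = frame["channel"].map({c.value: i for c, i in _CHANNEL_ORDER.items()})
    frame = frame.sort_values(
        ["sample_id", "assay", "replicate", "_chan", "size_bp"], kind="mergesort"
    ).drop(columns="_chan")
    return frame.reset_index(drop=True)


def write_peak_table(runs: Sequence[SampleRun], path: str | Path, dialect: str | None = None) -> None:
    """Write runs as a re-readable peak table with deterministic row order."""
    runs = list(runs)
    if not runs:
        raise EmptyInputError("refusing to write an empty peak table")
    path = Path(path)
    sep = _infer_sep(path, dialect)
    frame = runs_to_frame(runs)
    frame.to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "locus": Locus,
    "repeat_unit_bp": float,
    "size_offset_bp": float,
    "quantity": Quantity,
    "stutter_fraction_max": float,
    "bias_ratio_max": float,
    "borderline_margin": float,
    "category_boundaries": tuple,
}


def _build_config(base: AssayConfig, section: Mapping) -> AssayConfig:
    updates = {}
    for key, value in section.items():
        if key not in _CONFIG_FIELDS:
            raise ConfigError(f"unknown config key {key!r}")
        caster = _CONFIG_FIELDS[key]
        if caster is Quantity:
            value = Quantity(str(value).lower())
        elif caster is Locus:
            value = Locus(str(value))
        elif caster is tuple:
            value = tuple(float(x) for x in value)
        else:
            value = caster(value)
        updates[key] = value
    return replace(base, **updates)


def load_config(path: str | Path) -> dict[Assay, AssayConfig]:
    """Load per-assay configuration from a YAML document.

    The document has one section per assay (keys ``A``/``B``); unspecified
    fields fall back to the assay's defaults. Boundary monotonicity and the
    bias-ratio lower bound are validated on construction.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: config must be a mapping of assay sections")
    configs = default_configs()
    for key, section in doc.items():
        assay = Assay.parse(str(key))
        if section is None:
            section = {}
        if not isinstance(section, Mapping):
            raise ConfigError(f"{path}: section {key!r} must be a mapping")
        try:
            configs[assay] = _build_config(configs[assay], section)
        except ConfigError as exc:
            raise ConfigError(f"{path}: assay {assay.value}: {exc}") from None
    return configs
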