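"""Bulk quantification arithmetic: qPCR, droplet digital PCR, alkali assays.

All operations are pure functions of their inputs.  Ct arithmetic assumes
a doubling per cycle (efficiency 2.0, configurable); droplet concentrations
come from the standard Poisson occupancy estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: fluorophore channel per strand-specific probe
CHANNEL_BY_STRAND = {"top": "FAM", "bottom": "HEX"}

#: default droplet volume for concentration conversion, in nanoliters
DEFAULT_DROPLET_VOLUME_NL = 0.85


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    target: str
    strand: str  # top or bottom
    channel: str  # FAM (top) or HEX (bottom)
    treatment: str  # mock, alkali or none
    ct: float
    spike_ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0 or self.spike_ct <= 0:
            raise ValueError("Ct values must be positive")
        if self.treatment not in ("mock", "alkali", "none"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        expected = CHANNEL_BY_STRAND.get(self.strand)
        if expected is None:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.channel != expected:
            raise ValueError(
                f"channel {self.channel!r} inconsistent with {self.strand} "
                f"strand (expected {expected})"
            )


@dataclass(frozen=True)
class DpcrCounts:
    positives: int
    total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total droplet count must be > 0")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be > 0")


def relative_abundance(ct: float, spike_ct: float, ref_ct: float,
                       ref_spike_ct: float, efficiency: float = 2.0) -> float:
    """Spike-in-normalised fold change: efficiency^-(dCt - dCt_ref).

    Each sample's Ct is first normalised against its spike-in control
    (electroporation/recovery), then expressed relative to the reference
    condition; with efficiency 2 this is the familiar 2^-ddCt.
    """
    ddct = (ct - spike_ct) - (ref_ct - ref_spike_ct)
    return efficiency ** -ddct


def fraction_rna(ct_mock: float, ct_alkali: float, clamp: bool = True) -> float:
    """Alkali-sensitive (ribonucleotide-containing) template fraction.

    fraction = 1 - 2^(ct_mock - ct_alkali).  Negative values arise only
    from Ct noise and are clamped to 0 (with a warning) unless ``clamp``
    is disabled.
    """
    value = 1.0 - 2.0 ** (ct_mock - ct_alkali)
    if value < 0 and clamp:
        logger.warning(
            "fraction_rna: alkali Ct %.3f below mock Ct %.3f gives %.4f; "
            "clamping to 0", ct_alkali, ct_mock, value,
        )
        return 0.0
    return value


@dataclass(frozen=True)
class DpcrEstimate:
    copies_per_droplet: float  # Poisson lambda
    copies_per_microliter: Optional[float]
    saturated: bool


def dpcr_concentration(counts: DpcrCounts) -> DpcrEstimate:
    """Poisson occupancy estimate of template concentration.

    lambda = -ln(1 - positives/total); a fully positive plate is flagged
    as saturated with no finite estimate.
    """
    if counts.positives == counts.total:
        return DpcrEstimate(float("inf"), None, True)
    lam = -math.log(1.0 - counts.positives / counts.total)
    per_ul = lam / (counts.droplet_volume_nl * 1e-3)
    return DpcrEstimate(lam, per_ul, False)


def _as_lambda(value: Union[DpcrCounts, float]) -> float:
    if isinstance(value, DpcrCounts):
        return dpcr_concentration(value).copies_per_droplet
    return float(value)


@dataclass(frozen=True)
class StrandRatio:
    ratio: Optional[float]
    flagged: bool
    reason: Optional[str] = None


def both_joined_fraction(bottom: Union[DpcrCounts, float],
                         top: Union[DpcrCounts, float]) -> StrandRatio:
    """Bottom-strand over top-strand copy ratio (complete-repair readout).

    Computed on the Poisson-lambda scale, so droplet volume cancels and raw
    droplet counts and pre-converted concentrations give identical ratios.
    """
    lam_bottom = _as_lambda(bottom)
    lam_top = _as_lambda(top)
    if math.isinf(lam_top) or math.isinf(lam_bottom):
        return StrandRatio(None, True, "saturated droplet counts")
    if lam_top <= 0:
        return StrandRatio(None, True, "top strand concentration is zero")
    return StrandRatio(lam_bottom / lam_top, False)


def assemble_timecourse(
    records: Union[pd.DataFrame, Sequence[Mapping]],
    reference: Mapping[str, object],
    value_column: str = "value",
) -> pd.DataFrame:
    """Tidy value-vs-time table scaled to a named reference condition.

    ``reference`` maps column names to the values identifying the reference
    rows (e.g. ``{"target": "direct", "strand": "top", "timepoint": 30}``);
    their mean becomes 1.0.  Output ordering is canonical (sorted by all
    non-value columns), so input row order is irrelevant.
    """
    frame = pd.DataFrame(records).copy()
    if value_column not in frame.columns:
        raise ValueError(f"missing value column {value_column!r}")
    mask = pd.Series(True, index=frame.index)
    for column, wanted in reference.items():
        if column not in frame.columns:
            raise KeyError(f"reference column {column!r} not in table")
        mask &= frame[column] == wanted
    if not mask.any():
        raise KeyError(f"reference condition {dict(reference)!r} not present")
    ref_value = frame.loc[mask, value_column].mean()
    if ref_value == 0:
        raise ValueError("reference condition has value 0; cannot scale")
    frame["scaled"] = frame[value_column] / ref_value
    key_columns = [c for c in frame.columns if c not in (value_column, "scaled")]
    frame = frame.sort_values(key_columns + [value_column], kind="mergesort")
    return frame.reset_index(drop=True)


def load_qpcr_csv(path) -> pd.DataFrame:
    """Read a Ct table (sample, target, strand, channel, treatment, ct,
    spike_ct), validating each row through QpcrRecord."""
    frame = pd.read_csv(path)
    required = {"sample", "target", "strand", "channel", "treatment", "ct",
                "spike_ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"qPCR CSV missing columns: {sorted(missing)}")
    for row in frame.itertuples(index=False):
        QpcrRecord(
            sample=row.sample, target=row.target, strand=row.strand,
            channel=row.channel, treatment=row.treatment,
            ct=float(row.ct), spike_ct=float(row.spike_ct),
        )
    return frame


def load_dpcr_csv(path) -> pd.DataFrame:
    """Read a droplet-count table (sample, target, positives, total[, droplet_volume_nl])."""
    frame = pd.read_csv(path)
    required = {"sample", "target", "positives", "total"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"dPCR CSV missing columns: {sorted(missing)}")
    return frame
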