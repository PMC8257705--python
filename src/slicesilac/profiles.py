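"""Per-slice ratio normalization, profile assembly and candidate filtering.

The H (heavy) channel is the untreated reference and the L (light) channel
the treated sample, so a treatment-induced species shows log2(H/L) < 0 and a
treatment-depleted one log2(H/L) > 0.  Each slice carries its own systematic
ratio bias (mixing accuracy, label incorporation, slice-specific losses);
zero-median normalization removes it by centring every slice's log2 ratio
distribution at exactly zero.  Normalization and calibration are strictly
per-dataset — ratios from different gels are never pooled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

from .calibration import Calibration, expected_slice
from .maxquant_io import ProteinGroupRecord

__all__ = [
    "SliceProfile",
    "FilterParams",
    "normalize_zero_median",
    "assemble_profiles",
    "filter_candidates",
]

logger = logging.getLogger(__name__)


@dataclass
class SliceProfile:
    """One protein group in one replicate: normalized log2(H/L) per slice."""

    group_id: str
    replicate_id: str
    condition: str  # e.g. "WT_mild", "DKO_apoptosis", "WT_untreated"
    log_ratio: dict[int, float] = field(default_factory=dict)
    ratio_count: dict[int, int] = field(default_factory=dict)
    theoretical_mass: float = 0.0
    expected_slice: int = 0
    gene_name: str = ""


@dataclass(frozen=True)
class FilterParams:
    """Candidate-selection thresholds.

    min_slices
        Minimum number of quantified slices per profile (default 2).
    min_ratio_count
        Per-slice evidence threshold, interpreted per ``count_rule``
        (default 2).
    min_abs_log2
        At least one slice must have |normalized log2(H/L)| at or above this
        (default 0.5).
    count_rule
        "count" (default): every quantified slice needs >= min_ratio_count
        peptide ratio measurements.  "value": the literal reading — every
        quantified slice needs H/L ratio >= min_ratio_count — kept available
        because the source protocol wording is ambiguous, although it would
        discard all treated-enriched (H/L < 1) species.
    """

    min_slices: int = 2
    min_ratio_count: int = 2
    min_abs_log2: float = 0.5
    count_rule: str = "count"

    def __post_init__(self) -> None:
        if self.min_slices < 0 or self.min_ratio_count < 0 or self.min_abs_log2 < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.count_rule not in ("count", "value"):
            raise ValueError(f"count_rule must be 'count' or 'value', got {self.count_rule!r}")


# ---------------------------------------------------------------------------
# zero-median normalization
# ---------------------------------------------------------------------------

def _median(values: Sequence[float]) -> float:
    """Lower median (an order statistic, R quantile type 1).

    Using a data point instead of the even-count midpoint makes the
    zero-median property exact in floating point: the median element maps to
    exactly 0 under subtraction, and monotone transforms keep it the median.
    """
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def normalize_zero_median(
    records: Sequence[ProteinGroupRecord],
) -> list[ProteinGroupRecord]:
    """Zero-median normalize H/L ratios slice by slice.

    For every slice with at least one finite ratio, the median log2 ratio
    across proteins (lower-median convention, see :func:`_median`) is
    subtracted from each protein's log2 ratio in that slice, making the
    post-normalization median exactly 0.  The normalized log2 value is also
    recorded on each :class:`SliceQuant` so downstream stages avoid a
    lossy exp/log round trip.  Missing values are untouched; slices without
    any finite ratio are skipped with a log notice.  Must be applied to one
    dataset (one gel) at a time.
    """
    def log_value(q) -> float:
        return (
            q.log2_normalized
            if q.log2_normalized is not None
            else math.log2(q.ratio_hl)
        )

    by_slice: dict[int, list[float]] = {}
    for rec in records:
        for s, q in rec.per_slice.items():
            if q.ratio_hl is not None:
                by_slice.setdefault(s, []).append(log_value(q))

    all_slices = {s for rec in records for s in rec.per_slice}
    for s in sorted(all_slices - set(by_slice)):
        logger.info("slice %d has no finite ratios; normalization skipped", s)

    shifts = {s: _median(values) for s, values in by_slice.items()}

    out: list[ProteinGroupRecord] = []
    for rec in records:
        per_slice = {}
        for s, q in rec.per_slice.items():
            if q.ratio_hl is not None and s in shifts:
                normalized = log_value(q) - shifts[s]
                per_slice[s] = replace(
                    q,
                    ratio_hl=2.0 ** normalized,
                    log2_normalized=normalized,
                )
            else:
                per_slice[s] = q
        out.append(replace(rec, per_slice=per_slice))
    return out


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------

def assemble_profiles(
    records: Sequence[ProteinGroupRecord],
    calibration: Calibration,
    replicate_id: str,
    condition: str,
) -> list[SliceProfile]:
    """Build one :class:`SliceProfile` per protein group with finite ratios.

    The expected full-length slice is placed by inverting the replicate's own
    calibration at the protein's theoretical mass.  Records without any
    finite ratio yield no profile.
    """
    profiles: list[SliceProfile] = []
    for rec in records:
        log_ratio = {
            s: (
                q.log2_normalized
                if q.log2_normalized is not None
                else math.log2(q.ratio_hl)
            )
            for s, q in rec.per_slice.items()
            if q.ratio_hl is not None
        }
        if not log_ratio:
            continue
        profiles.append(
            SliceProfile(
                group_id=rec.group_id,
                replicate_id=replicate_id,
                condition=condition,
                log_ratio=log_ratio,
                ratio_count={s: rec.per_slice[s].ratio_count for s in log_ratio},
                theoretical_mass=rec.theoretical_mass,
                expected_slice=expected_slice(calibration, rec.theoretical_mass),
                gene_name=rec.gene_name,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# candidate filtering
# ---------------------------------------------------------------------------

def filter_candidates(
    profiles: Sequence[SliceProfile],
    params: FilterParams = FilterParams(),
) -> list[SliceProfile]:
    """Keep profiles that can carry a PTM call.

    A profile survives iff it (a) is quantified in at least ``min_slices``
    slices, (b) meets the per-slice evidence rule in *every* quantified slice
    (see :class:`FilterParams.count_rule`), and (c) has at least one slice
    with |normalized log2 ratio| >= ``min_abs_log2``.  Order is preserved and
    the filter is idempotent.
    """
    out: list[SliceProfile] = []
    for p in profiles:
        if len(p.log_ratio) < params.min_slices:
            continue
        if params.count_rule == "count":
            evidence_ok = all(
                p.ratio_count.get(s, 0) >= params.min_ratio_count for s in p.log_ratio
            )
        else:  # literal value threshold
            evidence_ok = all(
                2.0 ** lr >= params.min_ratio_count for lr in p.log_ratio.values()
            )
        if not evidence_ok:
            continue
        if not any(abs(lr) >= params.min_abs_log2 for lr in p.log_ratio.values()):
            continue
        out.append(p)
    return out
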