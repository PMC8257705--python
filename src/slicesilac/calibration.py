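"""Gel slice → molecular-weight calibration.

SDS-PAGE migration is approximately linear in log molecular mass, so each
dataset gets its own degree-3 polynomial fit of log10(theoretical mass, kDa)
against gel-slice index.  Anchor proteins are protein groups that migrate as
a single well-behaved band: smeared proteins (quantified in more than a
configurable fraction of the slices) and treatment-perturbed proteins (any
slice with a normalized H/L ratio outside a symmetric bound, default
[1/4, 4]) are excluded, since neither reflects the unmodified full-length
species the theoretical mass describes.

The fitted polynomial is inverted on the integer slice grid to place a
protein's expected full-length slice from its theoretical mass.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .maxquant_io import ProteinGroupRecord

__all__ = [
    "Anchor",
    "Calibration",
    "CalibrationError",
    "select_anchors",
    "fit_slice_mass",
    "predict_mass",
    "expected_slice",
]

logger = logging.getLogger(__name__)

MIN_ANCHORS = 6
MIN_DISTINCT_SLICES = 4  # below this the cubic design matrix is rank-deficient
RECOMMENDED_DISTINCT_SLICES = 8


class CalibrationError(ValueError):
    """Raised for unusable anchor sets or non-invertible calibrations."""


@dataclass(frozen=True)
class Anchor:
    """One calibration point: a protein anchored at its modal gel slice."""

    group_id: str
    modal_slice: int
    log_mass: float  # log10 of theoretical mass in kDa

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_mass):
            raise ValueError(f"{self.group_id}: log_mass must be finite")


@dataclass(frozen=True)
class Calibration:
    """Degree-3 polynomial slice → log10(kDa) with fit diagnostics."""

    coefficients: tuple[float, float, float, float]  # ascending powers
    fit_range: tuple[int, int]
    n_anchors: int
    rmse: float
    monotone: bool

    def evaluate(self, slice_index: float) -> float:
        """Polynomial value (log10 kDa) at a slice position."""
        c0, c1, c2, c3 = self.coefficients
        s = slice_index
        return c0 + c1 * s + c2 * s * s + c3 * s * s * s

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "coefficients": list(self.coefficients),
                "fit_range": list(self.fit_range),
                "n_anchors": self.n_anchors,
                "rmse": self.rmse,
                "monotone": self.monotone,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "Calibration":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            coefficients=tuple(d["coefficients"]),
            fit_range=tuple(d["fit_range"]),
            n_anchors=d["n_anchors"],
            rmse=d["rmse"],
            monotone=d["monotone"],
        )


# ---------------------------------------------------------------------------
# anchor selection
# ---------------------------------------------------------------------------

def _modal_slice(record: ProteinGroupRecord) -> int:
    """Slice where the protein's band peaks.

    Argmax of summed H+L intensity, falling back to argmax ratio count, then
    the smallest quantified slice index.  Ties always break toward the
    smaller slice.
    """
    slices = sorted(record.per_slice)
    best, best_int = None, -math.inf
    for s in slices:
        q = record.per_slice[s]
        total = (q.intensity_h or 0.0) + (q.intensity_l or 0.0)
        if total > best_int:
            best, best_int = s, total
    if best is not None and best_int > 0:
        return best
    best, best_count = None, -1
    for s in slices:
        if record.per_slice[s].ratio_count > best_count:
            best, best_count = s, record.per_slice[s].ratio_count
    return best if best_count > 0 else slices[0]


def select_anchors(
    records: Sequence[ProteinGroupRecord],
    n_slices: int,
    max_slice_occupancy: float = 0.30,
    ratio_exclusion_bound: float = 4.0,
) -> list[Anchor]:
    """Select the well-behaved proteins that anchor the slice→mass fit.

    Parameters
    ----------
    records
        Contaminant-filtered protein groups with *normalized* ratios.
    n_slices
        Total number of gel slices (occupancy denominator).
    max_slice_occupancy
        Proteins quantified in more than this fraction of the slices are
        treated as smeared and excluded (default 0.30).
    ratio_exclusion_bound
        A protein whose normalized H/L ratio leaves
        ``[1/bound, bound]`` in any slice is treatment-perturbed and
        excluded (default 4, i.e. |log2 ratio| >= 2).

    Raises
    ------
    CalibrationError
        If fewer than 6 anchors survive; the message advises relaxing
        the thresholds.
    """
    log_bound = math.log2(ratio_exclusion_bound)
    anchors: list[Anchor] = []
    for rec in records:
        quantified = [s for s, q in rec.per_slice.items() if q.has_quant]
        if not quantified:
            continue
        if len(quantified) > max_slice_occupancy * n_slices:
            continue
        perturbed = any(
            q.ratio_hl is not None and abs(math.log2(q.ratio_hl)) >= log_bound
            for q in rec.per_slice.values()
        )
        if perturbed:
            continue
        anchors.append(
            Anchor(
                group_id=rec.group_id,
                modal_slice=_modal_slice(rec),
                log_mass=math.log10(rec.theoretical_mass),
            )
        )
    if len(anchors) < MIN_ANCHORS:
        raise CalibrationError(
            f"only {len(anchors)} anchors survive selection (need >= {MIN_ANCHORS}); "
            "consider relaxing max_slice_occupancy or ratio_exclusion_bound"
        )
    return anchors


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_slice_mass(anchors: Sequence[Anchor]) -> Calibration:
    """Least-squares degree-3 fit of log10 mass on modal slice.

    The fit is independent of anchor ordering (anchors are sorted internally
    before the solve) and deterministic.

    Raises
    ------
    CalibrationError
        If fewer than 6 anchors are given or the anchors fall in fewer than
        4 distinct slices (rank-deficient cubic design).
    """
    if len(anchors) < MIN_ANCHORS:
        raise CalibrationError(f"need >= {MIN_ANCHORS} anchors, got {len(anchors)}")
    distinct = {a.modal_slice for a in anchors}
    if len(distinct) < MIN_DISTINCT_SLICES:
        raise CalibrationError(
            f"anchors span only {len(distinct)} distinct slices; a cubic fit "
            f"needs >= {MIN_DISTINCT_SLICES}"
        )
    if len(distinct) < RECOMMENDED_DISTINCT_SLICES:
        logger.warning(
            "anchors span only %d distinct slices (recommended >= %d); "
            "the calibration may be poorly constrained",
            len(distinct), RECOMMENDED_DISTINCT_SLICES,
        )

    ordered = sorted(anchors, key=lambda a: (a.modal_slice, a.log_mass, a.group_id))
    x = np.array([a.modal_slice for a in ordered], dtype=float)
    y = np.array([a.log_mass for a in ordered], dtype=float)
    # centred/scaled basis keeps the normal equations well-conditioned
    series = np.polynomial.Polynomial.fit(x, y, deg=3)
    poly = series.convert()
    coeffs = tuple(float(c) for c in np.pad(poly.coef, (0, 4 - len(poly.coef))))

    residuals = y - series(x)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    lo, hi = int(x.min()), int(x.max())
    cal = Calibration(
        coefficients=coeffs,
        fit_range=(lo, hi),
        n_anchors=len(anchors),
        rmse=rmse,
        monotone=_is_monotone(coeffs, lo, hi),
    )
    return cal


def _is_monotone(coeffs: Sequence[float], lo: int, hi: int) -> bool:
    """Strict monotonicity of the cubic over [lo, hi] via its derivative."""
    c0, c1, c2, c3 = coeffs
    s = np.linspace(lo, hi, max(2, (hi - lo) * 8 + 1))
    deriv = c1 + 2 * c2 * s + 3 * c3 * s * s
    return bool(np.all(deriv < 0) or np.all(deriv > 0))


# ---------------------------------------------------------------------------
# prediction / inversion
# ---------------------------------------------------------------------------

def predict_mass(calibration: Calibration, slice_index: float) -> float:
    """Apparent molecular mass (kDa) at a gel slice: ``10 ** p(slice)``.

    Slices outside the fit range are clamped to it with a warning;
    extrapolating a cubic is not meaningful.
    """
    lo, hi = calibration.fit_range
    s = slice_index
    if s < lo or s > hi:
        clamped = min(max(s, lo), hi)
        logger.warning(
            "slice %s outside calibration fit range [%d, %d]; clamping to %s",
            s, lo, hi, clamped,
        )
        s = clamped
    return 10.0 ** calibration.evaluate(s)


def expected_slice(calibration: Calibration, mass: float) -> int:
    """Integer slice whose predicted mass is closest to ``mass`` in log10 space.

    Ties break toward the smaller slice index (the gel top).

    Raises
    ------
    CalibrationError
        If the calibration is not monotone over its fit range (the inversion
        is then undefined) or ``mass`` is not positive.
    """
    if not calibration.monotone:
        raise CalibrationError(
            "calibration is not monotone over its fit range; slice inversion "
            "is undefined"
        )
    if not mass > 0:
        raise CalibrationError(f"mass must be positive, got {mass}")
    lo, hi = calibration.fit_range
    target = math.log10(mass)
    best_slice, best_err = lo, math.inf
    for s in range(lo, hi + 1):
        err = abs(target - calibration.evaluate(s))
        if err < best_err - 1e-15:
            best_slice, best_err = s, err
    return best_slice
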