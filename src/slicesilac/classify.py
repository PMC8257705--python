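"""PTM migration-pattern classification, replicate concordance and
caspase-dependency calls.

A protein whose treated (L) channel shows species in gel slices away from its
expected full-length slice has been post-translationally modified.  The
migration-pattern taxonomy:

discrete_fragmentation
    One to a few defined lower-mass species together with depletion of the
    full-length band — limited, site-specific proteolysis.
ubiquitination
    A ladder of species above the full-length band (poly-ubiquitin
    conjugates add ~8.6 kDa per rung).
tagging
    One or two discrete species above the full-length band (a covalent tag:
    phosphorylation, acylation, glycosylation, ...).
degradation
    Ladders on both sides of the full-length band (by default) —
    proteasome-mediated turnover.
other
    Any pattern that fits none of the above.

Sign convention (asserted in tests): the heavy channel is the untreated
reference, so treatment-induced species have NEGATIVE normalized log2(H/L)
and treatment-depleted bands POSITIVE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .calibration import Calibration, predict_mass
from .profiles import SliceProfile

__all__ = [
    "SpeciesCall",
    "PTMCall",
    "LadderParams",
    "FLAGS",
    "call_species",
    "classify_pattern",
    "classify_profile",
    "concordant_calls",
    "dependency_analysis",
]

logger = logging.getLogger(__name__)

#: The five pattern flags, in report order.
FLAGS = (
    "discrete_fragmentation",
    "ubiquitination",
    "tagging",
    "degradation",
    "other",
)

#: Band tolerance (slices) around the expected full-length slice; species
#: within it are `at_fl`.  One slice matches the typical calibration rmse.
FL_BAND_TOLERANCE = 1


@dataclass(frozen=True)
class SpeciesCall:
    """A treated-specific species in one gel slice.

    ``direction`` is relative to the expected full-length slice: slice
    indices increase down the gel, so a species in a *smaller* slice index
    than expected migrates above the full-length band (higher apparent
    mass) and is ``above_fl``.
    """

    slice: int
    direction: str  # "above_fl" | "below_fl" | "at_fl"
    log_ratio: float
    apparent_mass: float  # kDa


@dataclass
class PTMCall:
    """Multi-label PTM pattern call for one protein in one condition."""

    group_id: str
    condition: str
    flags: frozenset[str]
    full_length_depleted: bool
    species: tuple[SpeciesCall, ...]
    replicate_support: int = 1
    replicate_id: str = ""  # producing replicate; empty once merged over replicates
    dependency: str = "undetermined"  # caspase_dependent | caspase_independent | undetermined
    expected_slice: int = 0
    theoretical_mass: float = 0.0
    gene_name: str = ""
    annotations: list = field(default_factory=list)  # filled by cleavage annotation


@dataclass(frozen=True)
class LadderParams:
    """Ladder geometry.

    max_gap
        Largest inter-slice gap between consecutive rungs of a ladder
        (default 1: rungs in adjacent slices).
    min_rungs
        Species needed on one side to count as a ladder (default 3).
    degradation_mode
        "both" (default): degradation needs ladders above AND below the
        full-length band.  "below_only": a ladder below suffices.
    ubiquitin_spacing_kda / ubiquitin_spacing_tol
        Optional check that consecutive above-ladder rungs are spaced by one
        ubiquitin (~8.6 +/- 2 kDa apparent mass); off by default because the
        original classification is by band shape only.
    """

    max_gap: int = 1
    min_rungs: int = 3
    degradation_mode: str = "both"
    check_ubiquitin_spacing: bool = False
    ubiquitin_spacing_kda: float = 8.6
    ubiquitin_spacing_tol: float = 2.0

    def __post_init__(self) -> None:
        if self.degradation_mode not in ("both", "below_only"):
            raise ValueError("degradation_mode must be 'both' or 'below_only'")


# ---------------------------------------------------------------------------
# species calling
# ---------------------------------------------------------------------------

def call_species(
    profile: SliceProfile,
    calibration: Calibration,
    delta: float = 0.5,
) -> tuple[list[SpeciesCall], bool]:
    """Detect treated-specific species and full-length depletion.

    Slices with normalized log2(H/L) <= -delta carry treated-specific
    (L-enriched) species; their direction follows from the slice index
    relative to the expected full-length slice with a +/-1-slice band
    tolerance.  Full-length depletion is a log2 ratio >= +delta anywhere in
    the expected-slice band.

    Returns
    -------
    (species, full_length_depleted)
    """
    exp = profile.expected_slice
    species: list[SpeciesCall] = []
    depleted = False
    for s in sorted(profile.log_ratio):
        lr = profile.log_ratio[s]
        if abs(s - exp) <= FL_BAND_TOLERANCE and lr >= delta:
            depleted = True
        if lr <= -delta:
            if s < exp - FL_BAND_TOLERANCE:
                direction = "above_fl"
            elif s > exp + FL_BAND_TOLERANCE:
                direction = "below_fl"
            else:
                direction = "at_fl"
            species.append(
                SpeciesCall(
                    slice=s,
                    direction=direction,
                    log_ratio=lr,
                    apparent_mass=predict_mass(calibration, s),
                )
            )
    return species, depleted


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

def _has_ladder(slices: Sequence[int], params: LadderParams,
                masses: Sequence[float] = ()) -> bool:
    """True if the sorted slice list contains a run of >= min_rungs species
    with consecutive gaps <= max_gap (optionally with ubiquitin spacing)."""
    if len(slices) < params.min_rungs:
        return False
    ordered = sorted(slices)
    run = [ordered[0]]
    runs = []
    for s in ordered[1:]:
        if s - run[-1] <= params.max_gap:
            run.append(s)
        else:
            runs.append(run)
            run = [s]
    runs.append(run)
    ladder_runs = [r for r in runs if len(r) >= params.min_rungs]
    if not ladder_runs:
        return False
    if params.check_ubiquitin_spacing and masses:
        mass_of = dict(zip(slices, masses))
        for r in ladder_runs:
            gaps = [abs(mass_of[a] - mass_of[b]) for a, b in zip(r, r[1:])]
            if all(
                abs(g - params.ubiquitin_spacing_kda) <= params.ubiquitin_spacing_tol
                for g in gaps
            ):
                return True
        return False
    return True


def classify_pattern(
    species: Sequence[SpeciesCall],
    full_length_depleted: bool,
    ladder_params: LadderParams = LadderParams(),
) -> frozenset[str]:
    """Map a species configuration to its (multi-label) pattern flags.

    Rules, applied independently (a protein can carry several PTMs):

    - ladder above the full-length band        -> ubiquitination
    - ladder above AND below ("both" mode),
      or ladder below ("below_only" mode)      -> degradation
    - 1-2 above-band species, no above ladder  -> tagging
    - 1-3 isolated below-band species (no
      below ladder) with full-length depletion -> discrete_fragmentation
    - any remaining nonempty evidence          -> other
    """
    above = [sp for sp in species if sp.direction == "above_fl"]
    below = [sp for sp in species if sp.direction == "below_fl"]
    ladder_above = _has_ladder(
        [sp.slice for sp in above], ladder_params, [sp.apparent_mass for sp in above]
    )
    ladder_below = _has_ladder([sp.slice for sp in below], ladder_params)

    flags: set[str] = set()
    if ladder_above:
        flags.add("ubiquitination")
    if ladder_params.degradation_mode == "both":
        if ladder_above and ladder_below:
            flags.add("degradation")
    elif ladder_below:
        flags.add("degradation")
    if above and not ladder_above and len(above) <= 2:
        flags.add("tagging")
    if below and not ladder_below and len(below) <= 3 and full_length_depleted:
        flags.add("discrete_fragmentation")

    # evidence the specific rules leave unexplained (scattered above species,
    # fragments without full-length depletion, a lone below ladder in "both"
    # mode, depletion with no species, ...) is still a modified migration
    # pattern: flag it "other"
    above_covered = not above or flags.intersection({"ubiquitination", "tagging"})
    below_covered = not below or flags.intersection(
        {"discrete_fragmentation", "degradation"}
    )
    if not above_covered or not below_covered:
        flags.add("other")
    if not flags and (species or full_length_depleted):
        flags.add("other")
    return frozenset(flags)


def classify_profile(
    profile: SliceProfile,
    calibration: Calibration,
    delta: float = 0.5,
    ladder_params: LadderParams = LadderParams(),
) -> PTMCall:
    """Species calling + pattern classification for one candidate profile.

    A candidate that passed the filters but yields no specific pattern falls
    back to the ``other`` flag, so every candidate carries at least one flag.
    """
    species, depleted = call_species(profile, calibration, delta)
    flags = classify_pattern(species, depleted, ladder_params)
    if not flags:
        flags = frozenset({"other"})
    return PTMCall(
        group_id=profile.group_id,
        condition=profile.condition,
        flags=flags,
        full_length_depleted=depleted,
        species=tuple(species),
        replicate_support=1,
        replicate_id=profile.replicate_id,
        expected_slice=profile.expected_slice,
        theoretical_mass=profile.theoretical_mass,
        gene_name=profile.gene_name,
    )


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

#: Species direction that carries the evidence for each flag.
_FLAG_DIRECTION = {
    "discrete_fragmentation": "below_fl",
    "degradation": None,  # evidence on both sides
    "ubiquitination": "above_fl",
    "tagging": "above_fl",
    "other": None,
}


def _flag_slices(call: PTMCall, flag: str) -> list[int]:
    direction = _FLAG_DIRECTION[flag]
    return sorted(
        sp.slice for sp in call.species if direction is None or sp.direction == direction
    )


def _patterns_overlap(a: list[int], b: list[int], tol: int = 1) -> bool:
    """Replicates agree when some species slices coincide within ``tol``."""
    if not a and not b:
        return True  # flag carried by depletion only
    return any(abs(x - y) <= tol for x in a for y in b)


def concordant_calls(
    calls: Sequence[PTMCall],
    min_replicates: int = 2,
    slice_tolerance: int = 1,
) -> list[PTMCall]:
    """Keep only flags reproduced in at least ``min_replicates`` experiments.

    ``calls`` are per-replicate calls for one condition (any number of
    proteins).  A flag is reported for a protein iff >= min_replicates
    replicate calls assign the same flag with species slices overlapping
    within ``slice_tolerance``.  The reported call takes its species from the
    best-supported replicate and records the replicate support.

    With fewer than ``min_replicates`` distinct replicates available in the
    input, nothing can be concordant: the result is empty and a warning is
    emitted.
    """
    by_protein: dict[str, list[PTMCall]] = {}
    replicates = set()
    for c in calls:
        by_protein.setdefault(c.group_id, []).append(c)
        replicates.add(c.replicate_id)
    if len(replicates) < min_replicates:
        if calls:
            logger.warning(
                "only %d replicate experiment(s) present; concordance needs >= %d "
                "— no calls reported",
                len(replicates), min_replicates,
            )
        return []

    out: list[PTMCall] = []
    for group_id in sorted(by_protein):
        reps = by_protein[group_id]
        supported_flags: dict[str, tuple[int, PTMCall]] = {}
        for flag in FLAGS:
            holders = [c for c in reps if flag in c.flags]
            if len(holders) < min_replicates:
                continue
            best_support, best_call = 0, None
            for c in holders:
                concordant = [
                    o
                    for o in holders
                    if o is not c
                    and _patterns_overlap(
                        _flag_slices(c, flag), _flag_slices(o, flag), slice_tolerance
                    )
                ]
                support = 1 + len(concordant)
                if support > best_support or (
                    support == best_support
                    and best_call is not None
                    and len(c.species) > len(best_call.species)
                ):
                    best_support, best_call = support, c
            if best_support >= min_replicates and best_call is not None:
                supported_flags[flag] = (best_support, best_call)
        if not supported_flags:
            continue
        # merge: one call per protein x condition carrying all supported flags
        support = max(s for s, _ in supported_flags.values())
        reference = max(
            (c for _, c in supported_flags.values()),
            key=lambda c: len(c.species),
        )
        out.append(
            PTMCall(
                group_id=group_id,
                condition=reference.condition,
                flags=frozenset(supported_flags),
                full_length_depleted=any(c.full_length_depleted for c in reps),
                species=reference.species,
                replicate_support=support,
                expected_slice=reference.expected_slice,
                theoretical_mass=reference.theoretical_mass,
                gene_name=reference.gene_name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# caspase dependency
# ---------------------------------------------------------------------------

def dependency_analysis(
    wt_calls: Sequence[PTMCall],
    dko_calls: Sequence[PTMCall],
    dko_proteins: Iterable[str] | None = None,
) -> list[PTMCall]:
    """Label WT cleavage events by their dependence on executioner caspases.

    Both call sets must come from the same stress condition and be
    concordance-filtered.  A WT ``discrete_fragmentation`` call is

    - ``caspase_dependent`` if the DKO (caspase-3/-7 double knock-out)
      dataset contains the protein but shows no discrete fragmentation;
    - ``caspase_independent`` if the DKO dataset shows discrete
      fragmentation of the same protein;
    - ``undetermined`` if the protein is absent from the DKO dataset
      (``dko_proteins`` = accessions detected in DKO; when None, every
      protein is assumed covered by the DKO experiment).
    """
    dko_cleaved = {
        c.group_id for c in dko_calls if "discrete_fragmentation" in c.flags
    }
    covered = None if dko_proteins is None else set(dko_proteins)
    out: list[PTMCall] = []
    for c in wt_calls:
        if "discrete_fragmentation" not in c.flags:
            out.append(c)
            continue
        if c.group_id in dko_cleaved:
            label = "caspase_independent"
        elif covered is not None and c.group_id not in covered:
            label = "undetermined"
        else:
            label = "caspase_dependent"
        out.append(
            PTMCall(
                group_id=c.group_id,
                condition=c.condition,
                flags=c.flags,
                full_length_depleted=c.full_length_depleted,
                species=c.species,
                replicate_support=c.replicate_support,
                dependency=label,
                expected_slice=c.expected_slice,
                theoretical_mass=c.theoretical_mass,
                gene_name=c.gene_name,
                annotations=list(c.annotations),
            )
        )
    return out
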