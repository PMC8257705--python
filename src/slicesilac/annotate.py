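"""Theoretical fragment masses and cleavage-site matching.

For a candidate cleavage after the P1 residue of a protein sequence, the two
hydrolysis products have average masses

    n_mass = sum(residue masses of 1..P1)   + H2O
    c_mass = sum(residue masses of P1+1..n) + H2O

so that n_mass + c_mass = full_mass + one water.  Average (not monoisotopic)
masses are used throughout: gel mobility reflects the average isotopic
composition.  Observed fragment species (apparent mass from the slice
calibration) are matched against known cleavage-site tables and, as a
fallback, against canonical executioner-caspase D-x-x-D motifs (Asp at P4
and P1), within a relative mass tolerance that reflects the +/-1-slice
uncertainty of the calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .classify import PTMCall
from .maxquant_io import CleavageSiteRecord

__all__ = [
    "AVERAGE_RESIDUE_MASS_DA",
    "WATER_MASS_DA",
    "FragmentPair",
    "SiteMatch",
    "theoretical_fragment_masses",
    "scan_caspase_motifs",
    "match_fragments",
]

logger = logging.getLogger(__name__)

#: Average residue (amino acid minus water) masses in Da, 20 standard
#: residues.  Table version: IUPAC 2021 atomic weights.
AVERAGE_RESIDUE_MASS_DA: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS_DA = 18.01528


@dataclass(frozen=True)
class FragmentPair:
    """The two products of hydrolysis after the P1 residue (masses in kDa)."""

    p1_position: int
    n_mass: float
    c_mass: float
    motif_context: str  # P4..P4' residues around the scissile bond


@dataclass(frozen=True)
class SiteMatch:
    """A cleavage site compatible with an observed fragment species."""

    p1_position: int
    fragment: str  # "n" or "c" — which product matches the species
    predicted_mass: float  # kDa
    apparent_mass: float  # kDa
    relative_error: float
    known: bool  # from the site table (True) or motif fallback (False)
    motif_context: str
    source: str = ""


def _sequence_mass_da(sequence: str, offset: int = 0) -> float:
    total = 0.0
    for i, aa in enumerate(sequence):
        try:
            total += AVERAGE_RESIDUE_MASS_DA[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {offset + i + 1}"
            ) from None
    return total


def theoretical_fragment_masses(sequence: str, p1_position: int) -> FragmentPair:
    """Average masses of the N- and C-terminal products of one cleavage.

    Parameters
    ----------
    sequence
        Protein sequence over the 20 standard one-letter residue codes.
    p1_position
        1-based index of the P1 residue; the bond after it is hydrolysed.

    Raises
    ------
    ValueError
        For an out-of-range position or a non-standard residue code (the
        message names the offending position).
    """
    sequence = sequence.upper()
    n = len(sequence)
    if not 1 <= p1_position < n:
        raise ValueError(
            f"p1_position must be in [1, {n - 1}] for a {n}-residue sequence, "
            f"got {p1_position}"
        )
    n_mass = (_sequence_mass_da(sequence[:p1_position]) + WATER_MASS_DA) / 1000.0
    c_mass = (
        _sequence_mass_da(sequence[p1_position:], offset=p1_position) + WATER_MASS_DA
    ) / 1000.0
    context = sequence[max(0, p1_position - 4): p1_position + 4]
    return FragmentPair(
        p1_position=p1_position, n_mass=n_mass, c_mass=c_mass, motif_context=context
    )


def scan_caspase_motifs(sequence: str) -> list[int]:
    """P1 positions of canonical executioner-caspase D-x-x-D motifs.

    Returns every 1-based position ``i >= 4`` with Asp at both P4 (``i-3``)
    and P1 (``i``); cleavage occurs after position ``i``.  Overlapping
    matches are all reported.  The last residue cannot be P1 (no bond to
    cleave after it).
    """
    sequence = sequence.upper()
    return [
        i
        for i in range(4, len(sequence))
        if sequence[i - 1] == "D" and sequence[i - 4] == "D"
    ]


def match_fragments(
    call: PTMCall,
    sequence: str | None,
    sites: Sequence[CleavageSiteRecord] = (),
    tol_fraction: float = 0.10,
    use_motif_fallback: bool = True,
) -> PTMCall:
    """Annotate a call's below-band species with compatible cleavage sites.

    For every below-full-length species, all sites (table entries for the
    call's accession plus, optionally, D-x-x-D motif positions) whose N- or
    C-terminal product mass lies within ``tol_fraction`` of the species'
    apparent mass are attached.  Known-table sites rank before motif-only
    sites; within each tier, smaller relative mass error first.

    The call's flags, species and dependency label are never altered; if no
    sequence is available the call is returned unchanged with a warning.
    """
    if sequence is None:
        logger.warning(
            "%s: no sequence available; cleavage annotation skipped", call.group_id
        )
        return call

    known_positions = {
        s.p1_position: s for s in sites if s.accession in (call.group_id, *_aliases(call))
    }
    candidate_positions: dict[int, CleavageSiteRecord | None] = dict(known_positions)
    if use_motif_fallback:
        for p1 in scan_caspase_motifs(sequence):
            candidate_positions.setdefault(p1, None)

    matches: list[SiteMatch] = []
    for sp in call.species:
        if sp.direction != "below_fl":
            continue
        for p1 in sorted(candidate_positions):
            if not 1 <= p1 < len(sequence):
                continue
            pair = theoretical_fragment_masses(sequence, p1)
            site = candidate_positions[p1]
            for frag_name, mass in (("n", pair.n_mass), ("c", pair.c_mass)):
                rel = abs(mass - sp.apparent_mass) / sp.apparent_mass
                if rel <= tol_fraction:
                    matches.append(
                        SiteMatch(
                            p1_position=p1,
                            fragment=frag_name,
                            predicted_mass=mass,
                            apparent_mass=sp.apparent_mass,
                            relative_error=rel,
                            known=site is not None,
                            motif_context=site.motif if site else pair.motif_context,
                            source=site.source if site else "DxxD motif scan",
                        )
                    )
    matches.sort(key=lambda m: (not m.known, m.relative_error, m.p1_position))
    return PTMCall(
        group_id=call.group_id,
        condition=call.condition,
        flags=call.flags,
        full_length_depleted=call.full_length_depleted,
        species=call.species,
        replicate_support=call.replicate_support,
        replicate_id=call.replicate_id,
        dependency=call.dependency,
        expected_slice=call.expected_slice,
        theoretical_mass=call.theoretical_mass,
        gene_name=call.gene_name,
        annotations=matches,
    )


def _aliases(call: PTMCall) -> tuple[str, ...]:
    return tuple(getattr(call, "all_ids", ()) or ())
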