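"""Readers for MaxQuant-style slice-indexed result tables and auxiliary inputs.

SLICE-SILAC quantifies each gel slice as a distinct MaxQuant "experiment"
numbered after the slice it came from, so a ``proteinGroups.txt`` row carries
one H/L ratio (plus ratio count and per-channel intensities) per slice.  This
module parses those tables into :class:`ProteinGroupRecord` objects, applies
the contaminant/reverse pre-filters, and loads the auxiliary inputs the
downstream annotation stage needs (extra contaminant ID lists, protein
sequences in FASTA, protease cleavage-site tables).

Nothing here touches ratio values: parsing is lossless for quantified cells
and filtering only drops whole records.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SliceQuant",
    "ProteinGroupRecord",
    "CleavageSiteRecord",
    "MaxQuantFormatError",
    "read_protein_groups",
    "write_protein_groups",
    "remove_flagged",
    "read_contaminant_list",
    "read_cleavage_sites",
    "read_fasta",
    "read_peptides",
]

#: Column-name templates of the per-experiment quantification columns.
#: ``{slice}`` is the gel-slice number embedded in the experiment label.
RATIO_TEMPLATE = "Ratio H/L {slice}"
RATIO_COUNT_TEMPLATE = "Ratio H/L count {slice}"
INTENSITY_H_TEMPLATE = "Intensity H {slice}"
INTENSITY_L_TEMPLATE = "Intensity L {slice}"

MANDATORY_COLUMNS = ("Majority protein IDs", "Mol. weight [kDa]")


class MaxQuantFormatError(ValueError):
    """Raised when an input table violates the expected MaxQuant dialect."""


@dataclass(frozen=True)
class SliceQuant:
    """Quantification of one protein group in one gel slice.

    A missing ratio means the species was not quantified in that slice —
    never that its ratio is zero.
    """

    ratio_hl: float | None = None
    ratio_count: int = 0
    intensity_h: float | None = None
    intensity_l: float | None = None
    #: normalized log2(H/L), set by zero-median normalization; carried
    #: explicitly so the per-slice zero median holds exactly downstream
    log2_normalized: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_hl is not None and not self.ratio_hl > 0:
            raise ValueError(f"H/L ratio must be positive, got {self.ratio_hl}")
        if self.ratio_count < 0:
            raise ValueError("ratio_count must be >= 0")

    @property
    def has_quant(self) -> bool:
        return any(
            v is not None and not (isinstance(v, float) and math.isnan(v))
            for v in (self.ratio_hl, self.intensity_h, self.intensity_l)
        ) or self.ratio_count > 0


@dataclass
class ProteinGroupRecord:
    """One proteinGroups.txt row: a protein group with per-slice quantities."""

    group_id: str
    all_ids: list[str]
    gene_name: str
    theoretical_mass: float  # kDa, MaxQuant "Mol. weight [kDa]"
    per_slice: dict[int, SliceQuant] = field(default_factory=dict)
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if not self.theoretical_mass > 0:
            raise ValueError(
                f"{self.group_id}: theoretical mass must be > 0, "
                f"got {self.theoretical_mass}"
            )

    @property
    def quantified_slices(self) -> list[int]:
        """Slices with a finite H/L ratio, ascending."""
        return sorted(s for s, q in self.per_slice.items() if q.ratio_hl is not None)


@dataclass(frozen=True)
class CleavageSiteRecord:
    """A known protease cleavage site: cleavage occurs after the P1 residue."""

    accession: str
    p1_position: int  # 1-based index of the P1 residue
    motif: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise ValueError(f"p1_position must be >= 1, got {self.p1_position}")


# ---------------------------------------------------------------------------
# proteinGroups.txt
# ---------------------------------------------------------------------------

def _slice_columns(columns: Sequence[str], template: str) -> dict[int, str]:
    """Map slice number -> column name for one per-experiment template.

    The experiment label is assumed to embed the slice number as the trailing
    integer of the column name (MaxQuant experiment naming in SLICE-SILAC).
    """
    prefix = template.split("{slice}")[0]
    pattern = re.compile(re.escape(prefix) + r"(\d+)$")
    out: dict[int, str] = {}
    for col in columns:
        m = pattern.fullmatch(col)
        if m:
            out[int(m.group(1))] = col
    return out


def _parse_float(cell: object) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str):
        cell = cell.strip()
        if cell == "" or cell.lower() == "nan":
            return None
        cell = float(cell)
    return float(cell)


def read_protein_groups(
    path: str | Path,
    experiment_pattern: str = RATIO_TEMPLATE,
) -> list[ProteinGroupRecord]:
    """Read a MaxQuant ``proteinGroups.txt`` into :class:`ProteinGroupRecord` s.

    Parameters
    ----------
    path
        Tab-separated table with a header row.  Must contain
        "Majority protein IDs", "Mol. weight [kDa]", and per-experiment ratio
        columns whose labels end in the gel-slice number.
    experiment_pattern
        Template of the ratio column names; ``{slice}`` marks where the slice
        number sits (default: MaxQuant's ``"Ratio H/L {slice}"``).

    Returns
    -------
    One record per row, in file order.  Empty/"NaN" cells become missing
    values; a slice appears in ``per_slice`` only if at least one of its
    quantities is present.

    Raises
    ------
    MaxQuantFormatError
        If a mandatory column is absent, no slice-labelled ratio column can
        be parsed, or a ratio value is non-positive.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MaxQuantFormatError(
                f"{path.name}: mandatory column {col!r} is missing"
            )

    ratio_cols = _slice_columns(df.columns, experiment_pattern)
    if not ratio_cols:
        prefix = experiment_pattern.split("{slice}")[0]
        offenders = [c for c in df.columns if c.startswith(prefix)]
        raise MaxQuantFormatError(
            f"{path.name}: no ratio columns matching {experiment_pattern!r} with a "
            f"trailing slice number; offending labels: {offenders or 'none found'}"
        )
    count_cols = _slice_columns(df.columns, RATIO_COUNT_TEMPLATE)
    ih_cols = _slice_columns(df.columns, INTENSITY_H_TEMPLATE)
    il_cols = _slice_columns(df.columns, INTENSITY_L_TEMPLATE)

    records: list[ProteinGroupRecord] = []
    for idx, row in df.iterrows():
        majority = [a for a in str(row["Majority protein IDs"]).split(";") if a]
        if not majority:
            raise MaxQuantFormatError(
                f"{path.name} row {idx}: empty 'Majority protein IDs'"
            )
        mass = _parse_float(row["Mol. weight [kDa]"])
        if mass is None or not mass > 0:
            raise MaxQuantFormatError(
                f"{path.name} row {idx} ({majority[0]}): "
                f"invalid 'Mol. weight [kDa]' value {row['Mol. weight [kDa]']!r}"
            )

        per_slice: dict[int, SliceQuant] = {}
        for s, col in ratio_cols.items():
            ratio = _parse_float(row[col])
            if ratio is not None and ratio <= 0:
                raise MaxQuantFormatError(
                    f"{path.name} row {idx} ({majority[0]}): non-positive ratio "
                    f"{ratio} in column {col!r}"
                )
            count_cell = row[count_cols[s]] if s in count_cols else None
            count = _parse_float(count_cell)
            quant = SliceQuant(
                ratio_hl=ratio,
                ratio_count=int(count) if count is not None else 0,
                intensity_h=_parse_float(row[ih_cols[s]]) if s in ih_cols else None,
                intensity_l=_parse_float(row[il_cols[s]]) if s in il_cols else None,
            )
            if quant.has_quant:
                per_slice[s] = quant

        records.append(
            ProteinGroupRecord(
                group_id=majority[0],
                all_ids=majority,
                gene_name=str(row.get("Gene names", "")),
                theoretical_mass=mass,
                per_slice=per_slice,
                is_contaminant=str(row.get("Potential contaminant", "")).strip() == "+",
                is_reverse=str(row.get("Reverse", "")).strip() == "+",
            )
        )
    return records


def write_protein_groups(
    records: Iterable[ProteinGroupRecord],
    path: str | Path,
    n_slices: int,
) -> None:
    """Write records back to the MaxQuant tab-separated dialect.

    Float cells use ``repr`` so that a read/write round trip reproduces every
    finite ratio bit-exactly.
    """
    def fmt(v: float | None) -> str:
        return "" if v is None else repr(float(v))

    cols = ["Protein IDs", "Majority protein IDs", "Gene names",
            "Mol. weight [kDa]", "Potential contaminant", "Reverse"]
    for s in range(1, n_slices + 1):
        cols += [
            RATIO_TEMPLATE.format(slice=s),
            RATIO_COUNT_TEMPLATE.format(slice=s),
            INTENSITY_H_TEMPLATE.format(slice=s),
            INTENSITY_L_TEMPLATE.format(slice=s),
        ]
    rows = []
    for rec in records:
        row = {
            "Protein IDs": ";".join(rec.all_ids),
            "Majority protein IDs": ";".join(rec.all_ids),
            "Gene names": rec.gene_name,
            "Mol. weight [kDa]": repr(float(rec.theoretical_mass)),
            "Potential contaminant": "+" if rec.is_contaminant else "",
            "Reverse": "+" if rec.is_reverse else "",
        }
        for s in range(1, n_slices + 1):
            q = rec.per_slice.get(s)
            row[RATIO_TEMPLATE.format(slice=s)] = fmt(q.ratio_hl if q else None)
            row[RATIO_COUNT_TEMPLATE.format(slice=s)] = (
                str(q.ratio_count) if q else "0"
            )
            row[INTENSITY_H_TEMPLATE.format(slice=s)] = fmt(q.intensity_h if q else None)
            row[INTENSITY_L_TEMPLATE.format(slice=s)] = fmt(q.intensity_l if q else None)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contaminant / reverse filtering
# ---------------------------------------------------------------------------

def remove_flagged(
    records: Sequence[ProteinGroupRecord],
    extra_contaminants: Iterable[str] = (),
) -> list[ProteinGroupRecord]:
    """Drop contaminant-flagged, reverse-hit and extra-listed protein groups.

    A record is removed if it carries the "Potential contaminant" or reverse
    flag, or if *any* of its majority-protein accessions appears in
    ``extra_contaminants``.  Relative order of survivors is preserved; the
    operation is idempotent.
    """
    extra = set(extra_contaminants)
    return [
        rec
        for rec in records
        if not (rec.is_contaminant or rec.is_reverse or extra.intersection(rec.all_ids))
    ]


def read_contaminant_list(path: str | Path) -> list[str]:
    """Read a plain-text contaminant accession list (one per line, # comments)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# auxiliary annotation inputs
# ---------------------------------------------------------------------------

def read_cleavage_sites(path: str | Path) -> list[CleavageSiteRecord]:
    """Read a 4-column cleavage-site TSV (accession, p1_position, motif, source).

    Duplicate (accession, p1_position) pairs collapse to the first record.
    Non-integer or non-positive positions are hard errors naming the line.
    """
    path = Path(path)
    records: dict[tuple[str, int], CleavageSiteRecord] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = re.split(r"\t|\s+", line.strip())
            if lineno == 1 and fields[0].lower() == "accession":
                continue  # optional header
            if len(fields) < 2:
                raise MaxQuantFormatError(
                    f"{path.name} line {lineno}: expected at least accession and "
                    f"position, got {line!r}"
                )
            accession = fields[0]
            try:
                p1 = int(fields[1])
            except ValueError:
                raise MaxQuantFormatError(
                    f"{path.name} line {lineno}: non-integer P1 position {fields[1]!r}"
                ) from None
            if p1 < 1:
                raise MaxQuantFormatError(
                    f"{path.name} line {lineno}: non-positive P1 position {p1}"
                )
            motif = fields[2] if len(fields) > 2 else ""
            source = fields[3] if len(fields) > 3 else ""
            key = (accession, p1)
            if key not in records:
                records[key] = CleavageSiteRecord(accession, p1, motif, source)
    return list(records.values())


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by accession.

    FASTA headers in the UniProt style (``sp|P09874|PARP1_HUMAN``) are keyed
    by the central accession; plain headers by their first word.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "|" in name:
            parts = name.split("|")
            name = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
        seqs[name] = str(rec.seq).upper()
    return seqs


def read_peptides(
    path: str | Path,
    experiment_pattern: str = RATIO_TEMPLATE,
) -> pd.DataFrame:
    """Read the subset of ``peptides.txt`` the per-protein export consumes.

    Returns a DataFrame with peptide sequence, protein assignment, start/end
    positions when present, and the per-slice H/L ratio columns renamed to
    ``ratio_<slice>``.  Anything beyond these columns is ignored.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "Sequence" not in df.columns:
        raise MaxQuantFormatError("peptides table: mandatory column 'Sequence' is missing")
    keep = {"Sequence": "sequence"}
    for src, dst in [
        ("Proteins", "proteins"),
        ("Leading razor protein", "leading_protein"),
        ("Start position", "start_position"),
        ("End position", "end_position"),
    ]:
        if src in df.columns:
            keep[src] = dst
    out = df[list(keep)].rename(columns=keep)
    for s, col in sorted(_slice_columns(df.columns, experiment_pattern).items()):
        out[f"ratio_{s}"] = pd.to_numeric(df[col], errors="coerce")
    for col in ("start_position", "end_position"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
    return out
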