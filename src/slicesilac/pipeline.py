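"""End-to-end orchestration, JSON/TSV export and truth-based evaluation.

Stage order per dataset (one gel = one condition x replicate):

    read -> contaminant/reverse removal -> zero-median normalization ->
    slice-to-mass calibration -> profile assembly -> candidate filtering ->
    per-replicate pattern classification

then per condition: replicate concordance; then WT-vs-DKO caspase-dependency
labelling; then cleavage-site annotation; then export.  Every stage logs its
record counts in/out so the processing funnel of a run can be read from the
manifest.  All stages are deterministic, and the manifest records a checksum
of every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel

from . import calibration as calib
from . import maxquant_io as mio
from .annotate import SiteMatch, match_fragments
from .classify import (
    FLAGS,
    LadderParams,
    PTMCall,
    classify_profile,
    concordant_calls,
    dependency_analysis,
)
from .maxquant_io import CleavageSiteRecord, ProteinGroupRecord
from .profiles import (
    FilterParams,
    SliceProfile,
    assemble_profiles,
    filter_candidates,
    normalize_zero_median,
)

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "RunManifest",
    "EvaluationReport",
    "run_pipeline",
    "export_json",
    "export_calls_tsv",
    "evaluate_against_truth",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the processing chain, with the protocol defaults:
    46 slices, candidates in >= 2 slices, 0.5 log2 species threshold, 30%
    anchor slice occupancy, ratio exclusion bound 4, >= 2 concordant
    replicates."""

    n_slices: int = 46
    filter: FilterParams = field(default_factory=FilterParams)
    delta: float = 0.5
    ladder: LadderParams = field(default_factory=LadderParams)
    max_slice_occupancy: float = 0.30
    ratio_exclusion_bound: float = 4.0
    min_replicates: int = 2
    slice_tolerance: int = 1
    annotation_tol: float = 0.10

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineParams":
        p = Path(str(source))
        d = yaml.safe_load(p.read_text() if p.exists() else str(source))
        if "filter" in d:
            d["filter"] = FilterParams(**d["filter"])
        if "ladder" in d:
            d["ladder"] = LadderParams(**d["ladder"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, config hash, per-stage record
    counts, warnings, and a checksum for every output file."""

    inputs: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)

    def record_output(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    calls: dict[str, list[PTMCall]]            # condition -> concordant calls
    calibrations: dict[tuple[str, str], calib.Calibration]
    profiles: dict[tuple[str, str], list[SliceProfile]]   # post-filter candidates
    detected: dict[str, set[str]]              # condition -> accessions seen
    manifest: RunManifest = field(default_factory=RunManifest)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _load_dataset(
    source: Sequence[ProteinGroupRecord] | str | Path,
) -> list[ProteinGroupRecord]:
    if isinstance(source, (str, Path)):
        return mio.read_protein_groups(source)
    return list(source)


def _dko_counterpart(condition: str) -> str | None:
    return condition.replace("WT", "DKO", 1) if condition.startswith("WT") else None


def run_pipeline(
    datasets: Mapping[tuple[str, str], Sequence[ProteinGroupRecord] | str | Path],
    params: PipelineParams = PipelineParams(),
    extra_contaminants: Sequence[str] = (),
    sequences: Mapping[str, str] | None = None,
    sites: Sequence[CleavageSiteRecord] = (),
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full processing chain on one or more conditions.

    Parameters
    ----------
    datasets
        ``(condition, replicate_id) -> proteinGroups.txt path or parsed
        records``.  Conditions named ``WT_*`` are paired with ``DKO_*``
        counterparts for the caspase-dependency stage.
    params
        All thresholds; defaults are the protocol constants.
    extra_contaminants, sequences, sites
        Optional auxiliary inputs (extra contaminant accessions, FASTA
        sequences keyed by accession, cleavage-site records).
    out_dir
        If set, writes ``calls.tsv``, per-protein JSON documents
        (``proteins.json``), ``params.yaml`` and ``manifest.json``.

    Raises
    ------
    RuntimeError
        Wrapping any stage hard error with the stage name and dataset.
    """
    manifest = RunManifest(config_hash=params.config_hash())
    for key, src in sorted(datasets.items()):
        manifest.inputs["/".join(key)] = (
            str(src) if isinstance(src, (str, Path)) else "<memory>"
        )

    calibrations: dict[tuple[str, str], calib.Calibration] = {}
    candidates: dict[tuple[str, str], list[SliceProfile]] = {}
    per_replicate_calls: dict[str, list[PTMCall]] = {}
    detected: dict[str, set[str]] = {}

    for (condition, rep_id), source in sorted(datasets.items()):
        key = f"{condition}/{rep_id}"
        counts: dict[str, int] = {}
        try:
            records = _load_dataset(source)
            counts["read"] = len(records)
            records = mio.remove_flagged(records, extra_contaminants)
            counts["after_contaminant_removal"] = len(records)
            detected.setdefault(condition, set()).update(r.group_id for r in records)
            records = normalize_zero_median(records)
            anchors = calib.select_anchors(
                records,
                n_slices=params.n_slices,
                max_slice_occupancy=params.max_slice_occupancy,
                ratio_exclusion_bound=params.ratio_exclusion_bound,
            )
            counts["anchors"] = len(anchors)
            calibration = calib.fit_slice_mass(anchors)
            calibrations[(condition, rep_id)] = calibration
            profiles = assemble_profiles(records, calibration, rep_id, condition)
            counts["profiles"] = len(profiles)
            kept = filter_candidates(profiles, params.filter)
            counts["candidates"] = len(kept)
            candidates[(condition, rep_id)] = kept
            calls = [
                classify_profile(p, calibration, params.delta, params.ladder)
                for p in kept
            ]
            counts["calls"] = len(calls)
            per_replicate_calls.setdefault(condition, []).extend(calls)
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise RuntimeError(f"pipeline failed in dataset {key}: {exc}") from exc
        manifest.stage_counts[key] = counts

    concordant: dict[str, list[PTMCall]] = {}
    for condition, calls in sorted(per_replicate_calls.items()):
        kept = concordant_calls(
            calls,
            min_replicates=params.min_replicates,
            slice_tolerance=params.slice_tolerance,
        )
        if not kept and calls:
            manifest.warnings.append(
                f"{condition}: no concordant calls "
                f"(needs >= {params.min_replicates} agreeing replicates)"
            )
        concordant[condition] = kept
        manifest.stage_counts.setdefault(condition, {})["concordant"] = len(kept)

    for condition in sorted(concordant):
        dko = _dko_counterpart(condition)
        if dko and dko in concordant:
            concordant[condition] = dependency_analysis(
                concordant[condition],
                concordant[dko],
                dko_proteins=detected.get(dko),
            )

    if sequences is not None:
        for condition, calls in concordant.items():
            concordant[condition] = [
                match_fragments(
                    c, sequences.get(c.group_id), sites, params.annotation_tol
                )
                if any(sp.direction == "below_fl" for sp in c.species)
                else c
                for c in calls
            ]

    result = PipelineResult(
        calls=concordant,
        calibrations=calibrations,
        profiles=candidates,
        detected=detected,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls_path = out / "calls.tsv"
        export_calls_tsv(result, calls_path)
        json_path = out / "proteins.json"
        docs = export_json(result)
        json_path.write_text(
            json.dumps([d.model_dump() for d in docs], indent=1) + "\n"
        )
        params_path = out / "params.yaml"
        params.to_yaml(params_path)
        for p in (calls_path, json_path, params_path):
            manifest.record_output(p)
        manifest.to_json(out / "manifest.json")
    return result


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_calls_tsv(result: PipelineResult, path: str | Path) -> pd.DataFrame:
    """One row per protein x condition x flag (multi-label accounting)."""
    rows = []
    for condition in sorted(result.calls):
        for call in result.calls[condition]:
            for flag in FLAGS:
                if flag not in call.flags:
                    continue
                rows.append(
                    {
                        "protein": call.group_id,
                        "gene": call.gene_name,
                        "condition": condition,
                        "flag": flag,
                        "species_slices": ";".join(
                            str(sp.slice) for sp in call.species
                        ),
                        "expected_slice": call.expected_slice,
                        "full_length_depleted": call.full_length_depleted,
                        "replicate_support": call.replicate_support,
                        "dependency": call.dependency,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "protein", "gene", "condition", "flag", "species_slices",
            "expected_slice", "full_length_depleted", "replicate_support",
            "dependency",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df


class SpeciesDoc(BaseModel):
    slice: int
    direction: str
    log_ratio: float
    apparent_mass_kda: float


class CleavageCandidateDoc(BaseModel):
    p1_position: int
    fragment: str
    predicted_mass_kda: float
    apparent_mass_kda: float
    relative_error: float
    known: bool
    motif_context: str
    source: str


class ConditionDoc(BaseModel):
    condition: str
    flags: list[str]
    full_length_depleted: bool
    replicate_support: int
    dependency: str
    expected_slice: int
    species: list[SpeciesDoc]
    cleavage_candidates: list[CleavageCandidateDoc]
    profile_log2: dict[int, float]  # normalized log2(H/L) per slice


class ProteinDoc(BaseModel):
    """Per-protein-group JSON payload (the viewer-facing data object)."""

    majority_protein_ids: list[str]
    gene_name: str
    theoretical_mass_kda: float
    conditions: list[ConditionDoc]


def export_json(result: PipelineResult) -> list[ProteinDoc]:
    """Schema-validated per-protein documents for all concordant calls.

    One document per protein group that survived the filters in at least one
    condition; numeric fields round-trip bit-exactly through JSON.
    """
    profile_of: dict[tuple[str, str], SliceProfile] = {}
    for (condition, _rep), profs in sorted(result.profiles.items()):
        for p in profs:
            profile_of.setdefault((condition, p.group_id), p)

    by_protein: dict[str, list[tuple[str, PTMCall]]] = {}
    for condition in sorted(result.calls):
        for call in result.calls[condition]:
            by_protein.setdefault(call.group_id, []).append((condition, call))

    docs: list[ProteinDoc] = []
    for group_id in sorted(by_protein):
        entries = by_protein[group_id]
        first = entries[0][1]
        cond_docs = []
        for condition, call in entries:
            prof = profile_of.get((condition, group_id))
            cond_docs.append(
                ConditionDoc(
                    condition=condition,
                    flags=[f for f in FLAGS if f in call.flags],
                    full_length_depleted=call.full_length_depleted,
                    replicate_support=call.replicate_support,
                    dependency=call.dependency,
                    expected_slice=call.expected_slice,
                    species=[
                        SpeciesDoc(
                            slice=sp.slice,
                            direction=sp.direction,
                            log_ratio=sp.log_ratio,
                            apparent_mass_kda=sp.apparent_mass,
                        )
                        for sp in call.species
                    ],
                    cleavage_candidates=[
                        CleavageCandidateDoc(
                            p1_position=m.p1_position,
                            fragment=m.fragment,
                            predicted_mass_kda=m.predicted_mass,
                            apparent_mass_kda=m.apparent_mass,
                            relative_error=m.relative_error,
                            known=m.known,
                            motif_context=m.motif_context,
                            source=m.source,
                        )
                        for m in call.annotations
                        if isinstance(m, SiteMatch)
                    ],
                    profile_log2=dict(sorted(prof.log_ratio.items())) if prof else {},
                )
            )
        docs.append(
            ProteinDoc(
                majority_protein_ids=[group_id],
                gene_name=first.gene_name,
                theoretical_mass_kda=first.theoretical_mass,
                conditions=cond_docs,
            )
        )
    return docs


# ---------------------------------------------------------------------------
# evaluation against simulation truth
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class detection quality against a ground-truth event table.

    ``precision``/``recall``/``f1`` map flag -> value, with None where the
    quantity is undefined (no calls / no truth events of that class).  The
    confusion matrix rows are truth classes plus "none" (false calls);
    columns are called flags plus "missed".
    """

    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f1: dict[str, float | None]
    confusion: dict[str, dict[str, int]]
    dependency_accuracy: dict[str, float | None]
    n_truth: int
    n_calls: int


def evaluate_against_truth(
    calls: Mapping[str, Sequence[PTMCall]],
    truth: pd.DataFrame,
    slice_tolerance: int = 1,
) -> EvaluationReport:
    """Score concordant calls against the generator's truth table.

    A truth row (protein, condition, flag, species slices) is recovered iff
    some call for that protein and condition carries the flag with at least
    one species slice within ``slice_tolerance`` of a truth slice (rows
    without species slices match on the flag alone).  Only reproducible
    truth rows count: non-reproducible events are, by design, removed by the
    concordance stage.  Precision with zero calls (or recall with zero truth
    rows) is reported as None, never as 0 or 1.

    Raises
    ------
    ValueError
        If truth and calls share no protein identifiers at all (id scheme
        mismatch).
    """
    truth_rep = truth[truth["reproducible"].astype(bool)] if len(truth) else truth
    call_index: dict[tuple[str, str], list[PTMCall]] = {}
    for condition, call_list in calls.items():
        for c in call_list:
            call_index.setdefault((c.group_id, condition), []).append(c)

    if len(truth_rep) and call_index:
        truth_ids = set(truth_rep["protein_id"])
        call_ids = {pid for pid, _ in call_index}
        if not truth_ids & call_ids and truth_ids:
            raise ValueError(
                "no protein id overlap between calls and truth — mismatched inputs"
            )

    matched_calls: set[tuple[str, str, str]] = set()
    tp: dict[str, int] = {f: 0 for f in FLAGS}
    fn: dict[str, int] = {f: 0 for f in FLAGS}
    confusion: dict[str, dict[str, int]] = {}

    def bump(row_label: str, col_label: str) -> None:
        confusion.setdefault(row_label, {})
        confusion[row_label][col_label] = confusion[row_label].get(col_label, 0) + 1

    for _, row in truth_rep.iterrows():
        pid, condition, flag = row["protein_id"], row["condition"], row["flag"]
        truth_slices = [
            int(s) for s in str(row["species_slices"]).split(";") if s.strip()
        ]
        candidates = call_index.get((pid, condition), [])
        hit = None
        for c in candidates:
            if flag not in c.flags:
                continue
            if truth_slices:
                call_slices = [sp.slice for sp in c.species]
                if not any(
                    abs(a - b) <= slice_tolerance
                    for a in call_slices
                    for b in truth_slices
                ):
                    continue
            hit = c
            break
        if hit is not None:
            tp[flag] += 1
            matched_calls.add((pid, condition, flag))
            bump(flag, flag)
        else:
            fn[flag] += 1
            # mislabelled if the protein was called with some other flag
            other_flags = [
                f
                for c in candidates
                for f in FLAGS
                if f in c.flags and f != flag
                and (pid, condition, f) not in matched_calls
            ]
            if other_flags:
                bump(flag, other_flags[0])
                matched_calls.add((pid, condition, other_flags[0]))
            else:
                bump(flag, "missed")

    fp: dict[str, int] = {f: 0 for f in FLAGS}
    n_calls = 0
    for (pid, condition), call_list in sorted(call_index.items()):
        for c in call_list:
            for flag in FLAGS:
                if flag not in c.flags:
                    continue
                n_calls += 1
                if (pid, condition, flag) not in matched_calls:
                    fp[flag] += 1
                    bump("none", flag)

    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    f1: dict[str, float | None] = {}
    for flag in FLAGS:
        n_called = tp[flag] + fp[flag]
        n_truth = tp[flag] + fn[flag]
        precision[flag] = tp[flag] / n_called if n_called else None
        recall[flag] = tp[flag] / n_truth if n_truth else None
        if precision[flag] and recall[flag]:
            f1[flag] = 2 * precision[flag] * recall[flag] / (
                precision[flag] + recall[flag]
            )
        else:
            f1[flag] = None

    dependency_accuracy = _dependency_accuracy(calls, truth_rep)

    return EvaluationReport(
        precision=precision,
        recall=recall,
        f1=f1,
        confusion=confusion,
        dependency_accuracy=dependency_accuracy,
        n_truth=int(len(truth_rep)),
        n_calls=n_calls,
    )


def _dependency_accuracy(
    calls: Mapping[str, Sequence[PTMCall]],
    truth: pd.DataFrame,
) -> dict[str, float | None]:
    """Fraction of WT discrete-fragmentation calls whose dependency label
    matches the generator truth (event present in the DKO counterpart ->
    caspase_independent, else caspase_dependent)."""
    out: dict[str, float | None] = {}
    if not len(truth):
        return out
    frag = truth[truth["flag"] == "discrete_fragmentation"]
    by_protein_conditions: dict[str, set[str]] = {}
    for _, row in frag.iterrows():
        by_protein_conditions.setdefault(row["protein_id"], set()).add(row["condition"])
    for condition in sorted(calls):
        if not condition.startswith("WT"):
            continue
        dko = condition.replace("WT", "DKO", 1)
        scored = correct = 0
        for c in calls[condition]:
            if "discrete_fragmentation" not in c.flags or c.dependency == "undetermined":
                continue
            conds = by_protein_conditions.get(c.group_id)
            if conds is None:
                continue
            expected = (
                "caspase_independent" if dko in conds else "caspase_dependent"
            )
            scored += 1
            correct += int(c.dependency == expected)
        out[condition] = correct / scored if scored else None
    return out
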