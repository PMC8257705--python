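"""Forward simulation of SLICE-SILAC datasets with known ground truth.

The generator emulates the study design end to end: a proteome of 10-300 kDa
proteins run on a 46-slice gel whose migration law is a monotone cubic in
log10 mass; a heavy (H) reference channel carrying only unmodified
full-length protein; a light (L) treated channel carrying, for selected
proteins, injected PTM events of each migration-pattern class; per-slice
systematic ratio bias; lognormal ratio noise; intensity-dependent dropout;
and replicate / WT-vs-DKO condition structure.  Output is written in the
exact MaxQuant dialect the readers consume, alongside a ground-truth event
table, so every pipeline stage can be tested closed-loop.

Two deliberate simplifications (see docs/methods.md):

- each species band is rendered sharply into its nearest slice (Gaussian
  band SD 0.25 slices with a 1% intensity floor), because consecutive-slice
  species are by definition ladder rungs in the classifier;
- protein theoretical masses are drawn log-uniform over the gel range and
  then quantized to slice-center masses, so that in the noiseless limit the
  calibration anchors lie exactly on the generating polynomial.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .maxquant_io import ProteinGroupRecord, SliceQuant, write_protein_groups

__all__ = [
    "SimConfig",
    "EventSpec",
    "SimResult",
    "simulate_dataset",
    "labeling_fraction",
    "EVENT_CLASSES",
]

EVENT_CLASSES = (
    "discrete_fragmentation",
    "ubiquitination",
    "tagging",
    "degradation",
    "other",
)

#: Converted fraction used for events that must NOT deplete the full-length
#: band past the 0.5-log2 threshold (ubiquitination / tagging / other):
#: log2(1 / (1 - 0.1)) = 0.15.
SUBSTOICHIOMETRIC_FRACTION = 0.1


@dataclass(frozen=True)
class EventSpec:
    """One injected PTM event and where it appears.

    fragment_masses are kDa; below-band species have masses smaller than the
    host's full-length mass, above-band species larger.  ``conditions`` is
    the subset of simulated conditions showing the event; ``reproducible``
    events appear in every replicate, others in the first replicate only.
    """

    protein_id: str
    event_class: str
    fragment_masses: tuple[float, ...]
    effect_log2: float
    conditions: tuple[str, ...]
    reproducible: bool = True

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults mirror the experimental design the pipeline targets: a 46-slice
    gel spanning roughly 20-370 kDa, lognormal ratio noise of 0.2 log2
    units, mild per-slice ratio bias, treated-vs-reference effect sizes of
    2 log2 units, and two replicate experiments per condition.
    """

    n_proteins: int = 300
    n_slices: int = 46
    #: ascending-power cubic slice -> log10 kDa; strictly decreasing
    gel_poly: tuple[float, float, float, float] = (2.60, -0.030, 1.0e-4, -1.0e-6)
    band_sd: float = 0.25          # slices; Gaussian spread of one band
    band_floor: float = 0.01       # relative intensity for slice occupancy
    noise_sd: float = 0.2          # log2 units, lognormal ratio noise
    slice_bias_sd: float = 0.1     # log2 units, per-slice systematic bias
    dropout_midpoint: float | None = 4.5   # log10 intensity; None = no dropout
    dropout_steepness: float = 2.0
    ratio_cap_log2: float = 6.0    # |log2| cap where one channel is absent
    h_leak: float = 0.0            # reference-channel leak into species bands
    effect_log2: float = 2.0       # default event effect magnitude
    conditions: tuple[str, ...] = ("WT_mild",)
    n_replicates: int = 2
    events: tuple[EventSpec, ...] | None = None  # explicit events, or None
    events_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 4 for c in EVENT_CLASSES}
    )
    dko_event_fraction: float = 0.0   # share of auto events also present in DKO
    reproducible_fraction: float = 1.0
    n_smeared: int = 10            # wide-band proteins (anchor-exclusion food)
    n_contaminants: int = 2
    n_reverse: int = 1
    abundance_log10_mean: float = 7.0
    abundance_log10_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in (self.band_sd, self.noise_sd, self.slice_bias_sd)):
            raise ValueError("standard deviations must be >= 0")
        if not self._gel_poly_monotone():
            raise ValueError(
                "gel_poly must be strictly decreasing over [1, n_slices]"
            )

    def _gel_poly_monotone(self) -> bool:
        c0, c1, c2, c3 = self.gel_poly
        s = np.linspace(1, self.n_slices, self.n_slices * 8)
        return bool(np.all(c1 + 2 * c2 * s + 3 * c3 * s * s < 0))

    def log_mass_at(self, slice_index: float) -> float:
        c0, c1, c2, c3 = self.gel_poly
        s = slice_index
        return c0 + c1 * s + c2 * s * s + c3 * s * s * s

    def mass_at(self, slice_index: float) -> float:
        return 10.0 ** self.log_mass_at(slice_index)

    def slice_of_mass(self, mass: float) -> int:
        """Nearest slice center to a mass, in log10 space (gel-truth inverse)."""
        target = math.log10(mass)
        errs = [
            (abs(target - self.log_mass_at(s)), s)
            for s in range(1, self.n_slices + 1)
        ]
        return min(errs)[1]

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["gel_poly"] = list(self.gel_poly)
        d["conditions"] = list(self.conditions)
        if self.events is not None:
            d["events"] = [
                {**dataclasses.asdict(e),
                 "fragment_masses": list(e.fragment_masses),
                 "conditions": list(e.conditions)}
                for e in self.events
            ]
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        d["gel_poly"] = tuple(d["gel_poly"])
        d["conditions"] = tuple(d["conditions"])
        if d.get("events") is not None:
            d["events"] = tuple(
                EventSpec(
                    protein_id=e["protein_id"],
                    event_class=e["event_class"],
                    fragment_masses=tuple(e["fragment_masses"]),
                    effect_log2=e["effect_log2"],
                    conditions=tuple(e["conditions"]),
                    reproducible=e.get("reproducible", True),
                )
                for e in d["events"]
            )
        return cls(**d)


@dataclass
class SimResult:
    """In-memory simulation output: one record list per condition/replicate."""

    datasets: dict[tuple[str, str], list[ProteinGroupRecord]]
    truth: pd.DataFrame
    config: SimConfig
    events: tuple[EventSpec, ...]
    protein_masses: dict[str, float]

    def replicate_ids(self) -> list[str]:
        return sorted({rep for _, rep in self.datasets})


# ---------------------------------------------------------------------------
# event construction
# ---------------------------------------------------------------------------

def _event_slices(cls: str, fl_slice: int) -> tuple[list[int], list[int]]:
    """(above_slices, below_slices) of one injected event, in slice units.

    Species must sit at least 2 slices from the full-length band to clear
    the +/-1-slice band tolerance; ladders are runs of 3 adjacent slices.
    """
    if cls == "discrete_fragmentation":
        return [], [fl_slice + 3]
    if cls == "ubiquitination":
        return [fl_slice - 2, fl_slice - 3, fl_slice - 4], []
    if cls == "tagging":
        return [fl_slice - 2], []
    if cls == "degradation":
        return (
            [fl_slice - 2, fl_slice - 3, fl_slice - 4],
            [fl_slice + 2, fl_slice + 3, fl_slice + 4],
        )
    if cls == "other":
        # fragment without full-length depletion: unexplained by the
        # specific patterns, lands in the catch-all class
        return [], [fl_slice + 3]
    raise ValueError(cls)


def _depletes_full_length(cls: str) -> bool:
    return cls in ("discrete_fragmentation", "degradation")


def _expected_flags(cls: str, degradation_mode: str = "both") -> tuple[str, ...]:
    """Flags the classifier assigns to a cleanly recovered event."""
    if cls == "degradation" and degradation_mode == "both":
        return ("degradation", "ubiquitination")
    return (cls,)


def build_events(
    config: SimConfig,
    rng: np.random.Generator,
    host_ids: Sequence[str],
    fl_slices: dict[str, int],
) -> tuple[EventSpec, ...]:
    """Auto-inject events_per_class events on distinct interior host proteins."""
    wt_conditions = tuple(c for c in config.conditions if not c.startswith("DKO"))
    dko_of = {
        c: c.replace("WT", "DKO", 1)
        for c in wt_conditions
        if c.replace("WT", "DKO", 1) in config.conditions
    }
    eligible = [
        pid
        for pid in host_ids
        if 8 <= fl_slices[pid] <= config.n_slices - 8
    ]
    total = sum(config.events_per_class.get(c, 0) for c in EVENT_CLASSES)
    if total > len(eligible):
        raise ValueError(
            f"need {total} interior host proteins for events, have {len(eligible)}"
        )
    hosts = [str(h) for h in rng.choice(eligible, size=total, replace=False)]
    events = []
    for cls in EVENT_CLASSES:
        for _ in range(config.events_per_class.get(cls, 0)):
            pid = hosts.pop()
            fl = fl_slices[pid]
            above, below = _event_slices(cls, fl)
            masses = tuple(config.mass_at(s) for s in above + below)
            conditions = list(wt_conditions)
            if (
                cls == "discrete_fragmentation"
                and dko_of
                and rng.random() < config.dko_event_fraction
            ):
                conditions += [dko_of[c] for c in wt_conditions if c in dko_of]
            reproducible = bool(rng.random() < config.reproducible_fraction)
            events.append(
                EventSpec(
                    protein_id=pid,
                    event_class=cls,
                    fragment_masses=masses,
                    effect_log2=config.effect_log2,
                    conditions=tuple(conditions),
                    reproducible=reproducible,
                )
            )
    return tuple(events)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _band_weights(
    center: float, sd: float, floor: float, n_slices: int
) -> dict[int, float]:
    """Per-slice relative intensity of one Gaussian band, floored."""
    if sd == 0:
        s = int(round(center))
        return {s: 1.0} if 1 <= s <= n_slices else {}
    out = {}
    reach = int(math.ceil(sd * math.sqrt(-2.0 * math.log(floor)))) + 1
    for s in range(max(1, int(center) - reach), min(n_slices, int(center) + reach) + 1):
        w = math.exp(-((s - center) ** 2) / (2.0 * sd * sd))
        if w >= floor:
            out[s] = w
    return out


def _render_dataset(
    config: SimConfig,
    condition: str,
    replicate_idx: int,
    proteins: list[dict],
    events: Sequence[EventSpec],
    cond_idx: int,
) -> list[ProteinGroupRecord]:
    """Render one condition x replicate into ProteinGroupRecords."""
    seed = config.seed
    rng_noise = np.random.default_rng([seed, 11, cond_idx, replicate_idx])
    rng_bias = np.random.default_rng([seed, 17, cond_idx, replicate_idx])
    rng_drop = np.random.default_rng([seed, 13, cond_idx, replicate_idx])
    bias = rng_bias.normal(0.0, config.slice_bias_sd, size=config.n_slices + 1)

    by_protein: dict[str, list[EventSpec]] = {}
    for ev in events:
        if condition not in ev.conditions:
            continue
        if not ev.reproducible and replicate_idx != 0:
            continue
        by_protein.setdefault(ev.protein_id, []).append(ev)

    cap = config.ratio_cap_log2
    records: list[ProteinGroupRecord] = []
    for prot in proteins:
        pid = prot["id"]
        A = prot["abundance"]
        floor_abs = config.band_floor * A
        fl_w = _band_weights(
            prot["fl_slice"], prot["band_sd"], config.band_floor, config.n_slices
        )

        f_total = 0.0
        species_bands: list[tuple[dict[int, float], float]] = []  # weights, fraction
        for ev in by_protein.get(pid, ()):
            if _depletes_full_length(ev.event_class):
                f_event = 1.0 - 2.0 ** (-ev.effect_log2)
            else:
                f_event = SUBSTOICHIOMETRIC_FRACTION
            f_total += f_event
            per_species = f_event / max(1, len(ev.fragment_masses))
            for mass in ev.fragment_masses:
                mu = config.slice_of_mass(mass)
                species_bands.append(
                    (
                        _band_weights(mu, config.band_sd, config.band_floor,
                                      config.n_slices),
                        per_species,
                    )
                )
        f_total = min(f_total, 0.95)

        h_int = {s: A * w for s, w in fl_w.items()}
        l_int = {s: A * (1.0 - f_total) * w for s, w in fl_w.items()}
        # band-shape weight per slice: drives the peptide ratio count (how
        # sharply the band sits in the slice), independent of stoichiometry
        shape_w = dict(fl_w)
        for weights, frac in species_bands:
            for s, w in weights.items():
                contribution = A * frac * w
                l_int[s] = l_int.get(s, 0.0) + contribution
                shape_w[s] = max(shape_w.get(s, 0.0), w)
                if config.h_leak > 0:
                    h_int[s] = h_int.get(s, 0.0) + config.h_leak * contribution

        # noise / dropout draws happen in fixed slice order for determinism
        per_slice: dict[int, SliceQuant] = {}
        for s in range(1, config.n_slices + 1):
            h = h_int.get(s, 0.0)
            l = l_int.get(s, 0.0)
            h_ok, l_ok = h >= floor_abs, l >= floor_abs
            if not (h_ok or l_ok):
                continue
            u = rng_drop.random()
            eps = rng_noise.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
            if config.dropout_midpoint is not None:
                x = config.dropout_steepness * (
                    math.log10(h + l) - config.dropout_midpoint
                )
                p_keep = 1.0 / (1.0 + math.exp(-x))
                if u >= p_keep:
                    continue
            if h_ok and l_ok:
                log_ratio = math.log2(h / l)
            elif l_ok:
                log_ratio = -cap
            else:
                log_ratio = cap
            log_ratio = min(max(log_ratio + eps + bias[s], -cap), cap)
            count = max(1, int(round(prot["peptides"] * shape_w.get(s, 0.0))))
            per_slice[s] = SliceQuant(
                ratio_hl=2.0 ** log_ratio,
                ratio_count=count,
                intensity_h=round(h, 4),
                intensity_l=round(l, 4),
            )

        records.append(
            ProteinGroupRecord(
                group_id=pid,
                all_ids=[pid],
                gene_name=prot["gene"],
                theoretical_mass=prot["mass"],
                per_slice=per_slice,
                is_contaminant=prot["contaminant"],
                is_reverse=prot["reverse"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# top-level simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimConfig,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Simulate every condition x replicate and the ground-truth table.

    Protein masses are drawn log-uniform over the gel's mass range and
    quantized to slice centers; events are taken from ``config.events`` or
    auto-built per ``config.events_per_class``.  With ``out_dir`` set, one
    MaxQuant-dialect ``proteinGroups.txt`` is written per
    ``<condition>_<replicate>`` directory, plus ``truth.tsv`` and
    ``config.yaml`` at the top level.  Output is byte-deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng([config.seed, 7])

    lo_mass = config.mass_at(config.n_slices)
    hi_mass = config.mass_at(1)
    proteins: list[dict] = []
    fl_slices: dict[str, int] = {}
    for i in range(config.n_proteins):
        pid = f"SIM{i + 1:04d}"
        raw_mass = 10.0 ** rng.uniform(math.log10(lo_mass), math.log10(hi_mass))
        fl = config.slice_of_mass(raw_mass)
        mass = config.mass_at(fl)  # quantized to the slice center
        proteins.append(
            {
                "id": pid, "gene": f"G{i + 1:04d}", "mass": mass, "fl_slice": fl,
                "abundance": 10.0 ** rng.normal(config.abundance_log10_mean,
                                                config.abundance_log10_sd),
                "peptides": int(rng.integers(4, 13)),
                "band_sd": config.band_sd,
                "contaminant": False, "reverse": False,
            }
        )
        fl_slices[pid] = fl
    for i in range(config.n_smeared):
        fl = int(rng.integers(10, config.n_slices - 9))
        proteins.append(
            {
                "id": f"SMR{i + 1:03d}", "gene": f"SMR{i + 1:03d}",
                "mass": config.mass_at(fl), "fl_slice": fl,
                "abundance": 10.0 ** rng.normal(config.abundance_log10_mean,
                                                config.abundance_log10_sd),
                "peptides": int(rng.integers(4, 13)),
                "band_sd": 8.0,  # smeared across a large share of the gel
                "contaminant": False, "reverse": False,
            }
        )
    for i in range(config.n_contaminants):
        fl = int(rng.integers(5, config.n_slices - 4))
        proteins.append(
            {
                "id": f"CON__P{i + 1:05d}", "gene": "",
                "mass": config.mass_at(fl), "fl_slice": fl,
                "abundance": 10.0 ** rng.normal(config.abundance_log10_mean,
                                                config.abundance_log10_sd),
                "peptides": int(rng.integers(4, 13)),
                "band_sd": config.band_sd,
                "contaminant": True, "reverse": False,
            }
        )
    for i in range(config.n_reverse):
        fl = int(rng.integers(5, config.n_slices - 4))
        proteins.append(
            {
                "id": f"REV__SIM{i + 1:04d}", "gene": "",
                "mass": config.mass_at(fl), "fl_slice": fl,
                "abundance": 10.0 ** rng.normal(config.abundance_log10_mean,
                                                config.abundance_log10_sd),
                "peptides": int(rng.integers(4, 13)),
                "band_sd": config.band_sd,
                "contaminant": False, "reverse": True,
            }
        )

    if config.events is not None:
        events = tuple(config.events)
    else:
        events = build_events(
            config, rng, [p["id"] for p in proteins[: config.n_proteins]], fl_slices
        )

    datasets: dict[tuple[str, str], list[ProteinGroupRecord]] = {}
    for ci, condition in enumerate(config.conditions):
        for ri in range(config.n_replicates):
            rep_id = f"rep{ri + 1}"
            datasets[(condition, rep_id)] = _render_dataset(
                config, condition, ri, proteins, events, ci
            )

    truth = _truth_table(config, events, fl_slices)

    result = SimResult(
        datasets=datasets,
        truth=truth,
        config=config,
        events=events,
        protein_masses={p["id"]: p["mass"] for p in proteins},
    )
    if out_dir is not None:
        _write_output(result, Path(out_dir))
    return result


def _truth_table(
    config: SimConfig,
    events: Sequence[EventSpec],
    fl_slices: dict[str, int],
) -> pd.DataFrame:
    """One row per (event, condition, expected flag) with its species slices."""
    rows = []
    for ev in events:
        fl = fl_slices[ev.protein_id]
        above, below = _event_slices(ev.event_class, fl)
        for condition in ev.conditions:
            for flag in _expected_flags(ev.event_class):
                if flag == "ubiquitination":
                    slices = above
                elif flag in ("discrete_fragmentation", "other"):
                    slices = below
                else:
                    slices = above + below
                rows.append(
                    {
                        "protein_id": ev.protein_id,
                        "condition": condition,
                        "flag": flag,
                        "event_class": ev.event_class,
                        "species_slices": ";".join(str(s) for s in sorted(slices)),
                        "fragment_masses": ";".join(
                            f"{m:.4f}" for m in ev.fragment_masses
                        ),
                        "effect_log2": ev.effect_log2,
                        "reproducible": ev.reproducible,
                        "full_length_slice": fl,
                    }
                )
    columns = [
        "protein_id", "condition", "flag", "event_class", "species_slices",
        "fragment_masses", "effect_log2", "reproducible", "full_length_slice",
    ]
    return pd.DataFrame(rows, columns=columns)


def _write_output(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for (condition, rep_id), records in sorted(result.datasets.items()):
        ds_dir = out_dir / f"{condition}_{rep_id}"
        ds_dir.mkdir(parents=True, exist_ok=True)
        write_protein_groups(
            records, ds_dir / "proteinGroups.txt", result.config.n_slices
        )
    result.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    result.config.to_yaml(out_dir / "config.yaml")


# ---------------------------------------------------------------------------
# SILAC labeling model
# ---------------------------------------------------------------------------

def labeling_fraction(doublings: float) -> float:
    """Heavy-label incorporation after a number of population doublings.

    Under pure division-dilution of pre-existing light protein, the labeled
    fraction is ``1 - 2**(-doublings)``; six doublings already exceed the
    95% incorporation customarily required before a SILAC experiment.
    """
    if doublings < 0:
        raise ValueError("doublings must be >= 0")
    return 1.0 - 2.0 ** (-doublings)
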