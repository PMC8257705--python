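"""Shared fixtures: hand-written MaxQuant fixture tables, oracle calibration,
and small simulation configurations."""

from __future__ import annotations

from pathlib import Path

import pytest

from slicesilac import Calibration, SimConfig
from slicesilac.simulate import EVENT_CLASSES

#: The calibration oracle polynomial used across the calibration tests,
#: log10 kDa as a cubic in slice index (ascending powers).
ORACLE_POLY = (2.60, -0.030, 1.0e-4, -1.0e-6)


def oracle_value(s: float) -> float:
    c0, c1, c2, c3 = ORACLE_POLY
    return c0 + c1 * s + c2 * s * s + c3 * s * s * s


@pytest.fixture()
def oracle_calibration() -> Calibration:
    """A calibration whose coefficients are the oracle polynomial exactly."""
    return Calibration(
        coefficients=ORACLE_POLY,
        fit_range=(1, 46),
        n_anchors=40,
        rmse=0.0,
        monotone=True,
    )


def write_protein_groups_text(path: Path, rows: list[dict], n_slices: int = 3) -> Path:
    """Write a minimal hand-controlled proteinGroups.txt.

    ``rows`` entries map column suffixes to cell strings, e.g.
    ``{"ids": "P1", "mass": "100", "ratio": {1: "2.0"}, "count": {1: "3"}}``.
    """
    header = ["Majority protein IDs", "Gene names", "Mol. weight [kDa]",
              "Potential contaminant", "Reverse"]
    for s in range(1, n_slices + 1):
        header += [f"Ratio H/L {s}", f"Ratio H/L count {s}",
                   f"Intensity H {s}", f"Intensity L {s}"]
    lines = ["\t".join(header)]
    for row in rows:
        cells = [row.get("ids", "P1"), row.get("gene", ""),
                 row.get("mass", "100"), row.get("contaminant", ""),
                 row.get("reverse", "")]
        for s in range(1, n_slices + 1):
            cells += [
                row.get("ratio", {}).get(s, ""),
                row.get("count", {}).get(s, "0"),
                row.get("ih", {}).get(s, ""),
                row.get("il", {}).get(s, ""),
            ]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def noiseless_config() -> SimConfig:
    """Small noiseless simulation: two events per class, two replicates."""
    return SimConfig(
        n_proteins=150,
        noise_sd=0.0,
        slice_bias_sd=0.0,
        dropout_midpoint=None,
        conditions=("WT_apoptosis",),
        n_replicates=2,
        events_per_class={c: 2 for c in EVENT_CLASSES},
        seed=42,
    )


@pytest.fixture()
def parp1_sequence() -> str:
    from importlib.resources import files

    from slicesilac.maxquant_io import read_fasta

    data = files("slicesilac") / "data" / "parp1_p09874_synthetic.fasta"
    return read_fasta(str(data))["P09874"]
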