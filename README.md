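# slicesilac

Post-processing for **SLICE-SILAC** experiments: quantitative proteomics in
which a heavy-labeled untreated reference and a light-labeled treated sample
are mixed, run on SDS-PAGE, and the whole lane is cut into ~46 gel slices,
each quantified separately by LC–MS/MS.  A protein's slice-resolved
log2(H/L) profile then reveals post-translational modifications: species
appearing away from the expected molecular weight are treatment-induced
proteoforms — proteolytic fragments below the full-length band,
ubiquitin-conjugate ladders or covalent tags above it.

The package is aimed at proteomics analysts who have MaxQuant
`proteinGroups.txt` output from such a slice-per-experiment design and want
reproducible, scriptable calls of cleavage and other migration-pattern
changes, including caspase-dependency assignment from wild-type versus
caspase-3/-7 double knock-out (DKO) comparisons.

## What it computes

For each dataset (one gel = one condition × replicate):

1. **Contaminant removal** — "Potential contaminant"/reverse rows and an
   optional extra accession list are dropped.
2. **Zero-median normalization** — per slice *s*, the median of
   log2(H/L) across proteins is subtracted, removing slice-level
   systematic bias: `x̃_ps = log2(H/L)_ps − median_p log2(H/L)_ps`.
3. **Slice → mass calibration** — a degree-3 polynomial
   `log10 M = c₀ + c₁s + c₂s² + c₃s³` is fitted to theoretical masses of
   well-behaved anchor proteins (single-band, unperturbed), then inverted
   on the slice grid to place each protein's expected full-length slice.
4. **Candidate filtering** — keep proteins quantified in ≥ 2 slices, with
   ≥ 2 peptide ratio measurements per slice, and ≥ 1 slice with
   |normalized log2(H/L)| ≥ 0.5.
5. **Pattern classification** — treated-specific species (log2(H/L) ≤ −0.5;
   H is the reference, so treatment-induced species are L-enriched) are
   classified by geometry relative to the expected slice:
   *discrete fragmentation* (≤ 3 isolated below-band species plus
   full-length depletion), *ubiquitination* (ladder of ≥ 3 adjacent-slice
   species above), *tagging* (1–2 above-band species), *degradation*
   (ladders on both sides), *other*.  Calls are multi-label.
6. **Replicate concordance** — a flag is reported only when ≥ 2 replicates
   agree with species slices overlapping within ± 1 slice.
7. **Caspase dependency** — a WT cleavage call is `caspase_dependent` iff
   the matching DKO condition shows no discrete fragmentation of that
   protein (`undetermined` when the protein is absent from the DKO data).
8. **Cleavage annotation** — below-band species are matched against known
   cleavage-site tables and canonical executioner-caspase D-x-x-D motifs
   via average fragment masses, within a relative tolerance reflecting the
   ± 1-slice calibration uncertainty.

A forward simulator (`slicesilac.simulate`) generates complete synthetic
experiments — gel migration law, reference/treated channel structure,
per-slice bias, lognormal ratio noise, intensity-dependent dropout,
injected events of every class, replicates and WT/DKO conditions — in the
exact MaxQuant dialect the readers consume, with a ground-truth table, so
the whole chain is testable closed-loop.

## Worked example

```python
from slicesilac import SimConfig, simulate_dataset, run_pipeline, evaluate_against_truth

config = SimConfig(
    n_proteins=300,
    conditions=("WT_mild", "DKO_mild"),
    n_replicates=3,
    events_per_class={"discrete_fragmentation": 6, "ubiquitination": 3, "tagging": 3},
    seed=12,
)
sim = simulate_dataset(config)                    # MaxQuant-dialect tables + truth
result = run_pipeline(sim.datasets)               # normalize -> calibrate -> classify

cal = result.calibrations[("WT_mild", "rep1")]
print(f"calibration: {cal.n_anchors} anchors, rmse {cal.rmse:.3f} log10 kDa")
for call in result.calls["WT_mild"]:
    if "discrete_fragmentation" in call.flags:
        frag = ", ".join(f"slice {sp.slice} (~{sp.apparent_mass:.0f} kDa)"
                         for sp in call.species)
        print(f"{call.group_id}: cleaved -> {frag}; {call.dependency}")

report = evaluate_against_truth(result.calls, sim.truth)
print("discrete-cleavage recall:", report.recall["discrete_fragmentation"])
```

prints

```
calibration: 288 anchors, rmse 0.000 log10 kDa
SIM0012: cleaved -> slice 22 (~95 kDa); caspase_dependent
SIM0044: cleaved -> slice 12 (~179 kDa); caspase_dependent
SIM0048: cleaved -> slice 23 (~89 kDa); caspase_dependent
SIM0123: cleaved -> slice 40 (~31 kDa); caspase_dependent
SIM0213: cleaved -> slice 35 (~43 kDa); caspase_dependent
SIM0292: cleaved -> slice 28 (~66 kDa); caspase_dependent
discrete-cleavage recall: 1.0
```

Each cleaved protein is reported with the gel slice and apparent mass of
its treated-specific fragment; here every cleavage event was injected only
in the wild-type condition, so all calls come back `caspase_dependent`, and
every injected event was recovered (recall 1.0).  The calibration rmse is
essentially zero because the simulated bands sit exactly on slice centers.

A classic sanity check on real biology: cleaving PARP1 after the aspartate
of its DEVD site (residue 214) must release the well-known ~89 kDa
apoptotic fragment:

```python
from importlib.resources import files
from slicesilac import read_fasta, theoretical_fragment_masses

seq = read_fasta(str(files("slicesilac") / "data" / "parp1_p09874_synthetic.fasta"))["P09874"]
print(round(theoretical_fragment_masses(seq, 214).c_mass, 2))   # 89.09
```

(The bundled PARP1 record is a reconstructed stand-in sequence, marked
synthetic in its header.)

There is also a CLI (`slicesilac simulate/calibrate/process/run/evaluate`);
run `slicesilac --help`.

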