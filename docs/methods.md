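# Methods

## The measurement model

SLICE-SILAC reads out proteoform mass changes from a two-channel SILAC
experiment fractionated by whole-lane SDS-PAGE.  The heavy (H) channel is
the untreated reference, the light (L) channel the treated sample; after
mixing 1:1 and electrophoresis, the lane is cut into `n_slices` (default
46) slices and each slice is quantified as its own MaxQuant experiment.
For an unmodified protein, H and L co-migrate and log2(H/L) ≈ 0 in every
occupied slice.  A treatment-induced proteoform has no H counterpart at its
slice, so log2(H/L) is strongly negative there; loss of full-length protein
in the treated sample drives log2(H/L) positive at the expected slice.
This sign convention (treated-specific = negative) is the single most
error-prone aspect of the analysis and is asserted directly in the test
suite.

## Stages and their assumptions

**Zero-median normalization.**  Each slice carries its own systematic ratio
offset (mixing accuracy, label incorporation, slice-specific losses).  The
per-slice median log2 ratio is subtracted, assuming that in every slice the
majority of quantified proteins are unmodified.  Normalization and
calibration are strictly per dataset (one gel); ratios are never pooled
across gels.

*Numerical choice — lower median.*  The median is the lower middle order
statistic (R quantile type 1) rather than the even-count midpoint.  A data
point maps to exactly 0.0 under subtraction and stays the median under any
monotone transform, so the "slice median is exactly zero" invariant holds
bit-for-bit in floating point; a midpoint median can leave a ~1e-16
residual that no global shift removes.  The normalized log2 value is also
stored explicitly on each quantification (`SliceQuant.log2_normalized`) so
downstream stages do not pay a lossy `2**x`/`log2` round trip.  For the
slice populations involved (tens to hundreds of proteins) the two median
conventions differ by far less than the 0.5-log2 decision threshold.

**Slice-to-mass calibration.**  SDS-PAGE migration is approximately linear
in log molecular mass, so the fit is `log10 M(kDa) = c0 + c1·s + c2·s² +
c3·s³` on slice index `s` — a cubic to absorb the mild compression at the
gel extremes.  Anchors are one per protein, placed at the modal slice
(argmax of summed H+L intensity, falling back to argmax ratio count, then
smallest slice).  Excluded from anchoring: proteins occupying more than
`max_slice_occupancy` (default 0.30) of the slices (smears), and proteins
with any normalized ratio outside `[1/b, b]` with `b =
ratio_exclusion_bound` (default 4) — treatment-perturbed species are
unreliable mass markers.  The symmetric reading of the exclusion bound is a
design choice: a one-sided "ratio below 4" rule would discard almost every
protein, since unperturbed proteins sit near ratio 1.  The fit requires ≥ 6
anchors in ≥ 4 distinct slices (hard errors otherwise) and warns below 8
distinct slices.  Monotonicity over the fit range is checked, not
enforced: a non-monotone calibration makes slice inversion undefined and
`expected_slice` raises rather than silently repairing the fit.
Predictions outside the fit range are clamped with a warning; extrapolating
a cubic is not meaningful.  `expected_slice` returns the integer slice
whose predicted log10 mass is closest to the target, ties broken toward the
gel top (smaller index).

**Candidate filtering.**  Defaults: ≥ 2 quantified slices, ≥ 2 peptide
ratio measurements in every quantified slice, and ≥ 1 slice with
|normalized log2| ≥ 0.5.  The per-slice evidence rule is deliberately a
ratio *count* threshold: a literal "H/L value ≥ 2 everywhere" rule would
discard every treated-enriched (H/L < 1) fragment the method exists to
find.  The literal value reading remains available
(`FilterParams.count_rule="value"`) because the protocol wording is
ambiguous.  Missing ratios never count toward the slice minimum; nothing is
imputed.

**Species calling and pattern taxonomy.**  Slices with normalized log2 ≤
−0.5 are treated-specific species; the expected-slice band (± 1 slice,
matching typical calibration uncertainty) with log2 ≥ +0.5 marks
full-length depletion.  Classification is multi-label over
{discrete_fragmentation, ubiquitination, tagging, degradation, other}:

- ladder (≥ `min_rungs` = 3 species with inter-slice gaps ≤ `max_gap` = 1)
  above the full-length band → ubiquitination;
- ladders above **and** below → degradation (the default `"both"` mode; a
  `"below_only"` variant accepts a lone below-ladder, since the visual
  definition is ambiguous about whether the conjugate ladder above is
  required);
- 1–2 isolated above-band species → tagging;
- 1–3 isolated below-band species with full-length depletion →
  discrete fragmentation;
- any evidence the specific rules leave unexplained → other, so every
  filtered candidate carries at least one flag.

An optional ubiquitin-spacing check (adjacent rungs 8.6 ± 2 kDa apart in
apparent mass) is off by default: the taxonomy is defined by band shape.

**Replicate concordance.**  A flag is reported for a protein in a condition
only when ≥ `min_replicates` (default 2) replicate experiments assign the
same flag with species slices overlapping within ± 1 slice.  "Same
pattern" is inherently a visual criterion; this numeric proxy (same flag +
slice overlap) is configurable.  Reported species come from the
best-supported replicate; `replicate_support` records the agreement count.

**Caspase dependency.**  For paired conditions (`WT_x` vs `DKO_x`), a WT
discrete-fragmentation call is `caspase_dependent` iff the DKO dataset
contains the protein but shows no discrete fragmentation,
`caspase_independent` if it does, and `undetermined` when the protein was
not detected in DKO at all.  The detected-accession set is taken from the
post-contaminant-removal DKO tables, since absence of a *call* cannot
distinguish "unperturbed" from "not measured".

**Cleavage annotation.**  Fragment masses are sums of average residue
masses plus one water per product (average, not monoisotopic: gel mobility
reflects bulk isotopic composition; the residue table is an embedded
versioned constant).  Candidate sites come from a user-supplied table plus
a canonical executioner-caspase motif fallback (Asp at P4 and P1, D-x-x-D);
matches require the N- or C-terminal product mass within `tol_fraction`
(default 0.10) of the species' apparent mass, mirroring ± 1-slice
calibration uncertainty.  Known-table sites rank before motif-only hits,
then by relative mass error.  Annotation never alters flags, species or
dependency labels.

## The synthetic-data generator

The generator forward-simulates the full study design: proteins drawn
log-uniform over the gel's 10–300 kDa range; a monotone-decreasing cubic
gel law (default `(2.60, −0.030, 1e−4, −1e−6)`, spanning ~370 kDa at slice
1 to ~22 kDa at slice 46); an H channel carrying only unmodified
full-length protein; an L channel carrying, for event proteins, the
injected proteoforms; per-slice bias `b_s ~ N(0, slice_bias_sd)` (default
0.1 log2); lognormal ratio noise (default `noise_sd` 0.2 log2); logistic
intensity-dependent dropout (`p_keep = σ(steepness·(log10 I − midpoint))`,
default midpoint 4.5, steepness 2); replicate structure with optionally
replicate-unique events; and WT/DKO condition contrasts
(`dko_event_fraction` controls how many cleavage events persist without
executioner caspases).

Event rendering: classes that cleave the protein (discrete fragmentation,
degradation) convert a fraction `f = 1 − 2^(−effect_log2)` of the treated
pool, so the full-length band shows log2(H/L) = +effect (default effect 2);
ubiquitination, tagging and "other" events convert a sub-stoichiometric
10%, leaving full-length depletion below the 0.5 threshold, as those
patterns are defined without concomitant full-length loss.  Species slices
have no reference-channel signal, so their ratios sit at the configured cap
(|log2| = 6, emulating real quantifier behaviour at one-sided signals); an
optional reference-channel leak term can soften this.  Ratio counts follow
band shape (peak slices get the protein's full peptide count), not
stoichiometry.

Two deliberate simplifications matter for interpreting test results:

- **Sharp bands.**  Each species band renders into a single slice
  (Gaussian band SD 0.25 slices, 1% intensity floor).  Consecutive-slice
  species are by definition ladder rungs, so a physically realistic
  multi-slice band would read as a ladder; real data with broad bands
  would need band-merging upstream of this classifier.
- **Slice-center masses.**  Theoretical masses are quantized to slice
  centers after log-uniform drawing, so in the noiseless limit every
  anchor lies exactly on the generating polynomial and the closed loop is
  exact (recovery to < 1e−6 log10 kDa).  Real anchors scatter within a
  slice, giving calibration rmse of roughly half a slice's mass span.

Other features of real data the generator does not emulate: skewed band
shapes and dye-front smearing, peptide-level identification effects
(shared peptides, missed cleavages), arginine-to-proline conversion, and
abundance-dependent identification bias.  Passing closed-loop tests
therefore demonstrates correctness of the decision rules and plumbing, not
performance on real gels.

Determinism: one root seed; per-dataset substreams are derived from
`(seed, stream-id, condition, replicate)` so outputs are byte-identical
across runs and across platforms with IEEE doubles.

## Problem sizes used in the shipped checks

The verification suite runs the closed loop at 500 proteins × 46 slices
with 20 injected events (4 per class, 2 replicates), the noisy-recovery
check at 500 proteins with 35 events and 3 replicates, and the null
false-call check at 500 proteins × 3 replicates; these sizes give stable
rates while keeping the whole suite in the seconds range.  The bundled
PARP1 record is a reconstructed stand-in sequence (marked synthetic in its
filename and header): 1014 residues whose DEVD site at residues 211–214
yields the canonical ~89 kDa C-terminal fragment mass used by the worked
example.

## Known limitations

- No statistical model of ratio variance: thresholds are fixed constants,
  as in the underlying protocol, so sensitivity depends on the 0.5-log2
  threshold being well clear of the achieved noise level.
- One anchor per protein; no robust or weighted regression, no per-lane
  gel-warping model.
- The concordance and dependency logic assumes condition names encode the
  genotype prefix (`WT_*`/`DKO_*`).
- JSON export schema is a superset of the fields the original viewer
  consumes; the original schema is not published, so field names here are
  the package's own.
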