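# Methods

## Scope and model

`lipidmrm` implements the computational side of a two-method targeted
lipidomics platform for plant tissues: MRM (multiple reaction monitoring)
transition design from lipid chemistry, resolution of the fatty-acid (FA)
composition of isobaric triacylglycerol (TG) molecular species by
overlaying co-eluting extracted ion chromatograms (XICs), single-point
internal-standard quantification to nmol per mg tissue, and the standard
LC-MS method-validation statistics.

### Transition chemistry

Species formulas are built constructively: glycerol backbone + one
condensed headgroup + the free fatty acids, minus one water per ester
bond.  Headgroups are fixed per-class constants (phosphocholine,
phosphoethanolamine, phosphoglycerol, phosphoinositol, phosphoserine, and
one or two anhydro-galactose units for the galactolipids); lyso classes
share the parent headgroup with a single chain.  A glycerol-D5 label
substitutes five backbone hydrogens with deuterium, which is tracked as
its own element symbol so labelled and unlabelled species never collide.

Precursor adducts follow the class rule observed in electrospray:
acylglycerols (MG/DG/TG) ionize as [M+NH4]+ in positive mode; PC and LPC
as acetate adducts [M+CH3COO]- and all other polar classes as [M-H]- in
negative mode.  Product channels: DG/TG lose NH3 plus one fatty acid
(leaving a mono-/diacyl cation); MG yields the acylium cation [RCO]+
(equivalently NH3 + glycerol loss) or, for some saturated odd-chain
standards, the NH3+H2O loss; polar classes yield the deprotonated fatty
acid; glycerol-D5 LPS uses the C3HD5O5P- glycerophosphate-derived
headgroup fragment.

Masses are monoisotopic (NIST atomic masses via pyteomics) with
electron-mass correction per charge.  Internal arithmetic is kept at full
precision; instrument export rounds half-up to one decimal, the
convention of MRM method editors.  Published panels are operator-entered
at roughly unit resolution, so regression against printed values uses a
±0.15 Da band; rows outside the band are flagged as transcription drift —
every flagged row also disagrees with its own printed elemental formula,
which localizes the error to manual entry rather than the chemistry
rules.

### Isobaric TG enumeration and the resolver

A TG precursor mass fixes only total acyl carbons and double bonds.
Candidate triplets are enumerated as 3-multisets over a configurable FA
pool whose default is the set expected in pennycress tissue (16:0, 18:0,
18:1, 18:2, 18:3, 20:0, 20:1, 22:1, 24:1).  One neutral-loss MRM is
emitted per distinct candidate FA per precursor.

The resolver mirrors the manual overlay workflow:

1. **Peak detection** — local maxima above max(min_height, baseline +
   5 × noise SD) with a matching prominence requirement (noise wiggles on
   a peak flank are high in absolute intensity but have negligible
   prominence).  Maxima closer than the co-elution tolerance are merged
   into one peak: with proportional noise a flat apex otherwise splits
   into twin maxima that would each carry half the area.  Bounds run to
   the 1 %-of-apex/baseline floor, hard-limited at the intensity minimum
   towards a neighbouring apex; areas are trapezoidal above baseline.
   The noise SD is estimated robustly from the median absolute first
   difference, or from a user-designated signal-free region when one is
   given.
2. **Co-elution grouping** — single-linkage clustering of same-precursor
   peak apexes, which in one dimension reduces to splitting the sorted
   apex list at gaps larger than `rt_tol` (default 0.05 min, below a
   typical peak half-width of ~0.09 min at the default peak sigma of
   0.08 min).  Consensus RT is the height-weighted mean.
3. **Composition calling** — a candidate is supported when every distinct
   FA of the triplet has a member peak.  Channel heights are fitted to
   the candidate's multiplicities through one scale, s = Σ heights / 3
   (a triplet always carries three chains); the call is *confirmed* when
   every height/s ratio matches its multiplicity m within the acceptance
   band (ratio/m in [0.7, 1.4]), *tentative* when only the presence
   pattern matches.  The single-scale fit handles the degenerate
   single-channel case (a triplet of one FA) that a smallest-channel
   reference cannot.  A ratio-consistent candidate whose FA set is a
   strict subset of another confirmed candidate's in the same group is
   demoted to tentative: its evidence is fully absorbed by the larger
   composition (e.g. a 1:1:1 group of 18:1/18:2/18:3 channels would
   otherwise also "confirm" tri-18:2).  Height, not area, drives the
   inference — heights are insensitive to integration-boundary choices.
4. **Quantifier selection** — one transition per call, preferring
   channels that support no other call of the same precursor, then lowest
   multiplicity, then lowest product m/z (deterministic tie-break).  The
   divisor attached to the quantifier is the multiplicity of its FA, so
   triplets with repeated chains are not over-counted (tri-18:1 is
   divided by 3).  Unsharedness outranks multiplicity: when two isobaric
   species share one channel, neither may quantify on it if any private
   channel exists, even a doubled one — the corrected area is identical
   and the assignment unambiguous.  When a shared channel is the *only*
   evidence for two calls, both are flagged tentative; the area is never
   split between calls.

Equal detector response across FA channels is assumed throughout, as the
manual workflow implicitly assumes; per-species response correction is
out of scope.

### Quantification

Single-point internal-standard normalization:
`nmol/mg = area × IS_nmol / IS_area / tissue_mg`, with one IS per lipid
class (calibration curves are used in validation only, not for
quantification).  TG molecular species use divisor-corrected quantifier
areas.  Class totals are the within-sample sum, summarized as mean ±
sample (n−1) SD across replicates.  FA mol% of a TG profile counts each
triplet's amount once per chain occurrence, normalized over total FA
moles.  The statistics-ready export is a samples × features table with
an optional group-label column, feature columns in canonical sorted
order.

### Validation statistics

LOD = 3 × noise SD / slope and LOQ = 10 × noise SD / slope, so LOQ/LOD is
10/3 identically.  Calibration is ordinary least squares on a serial
dilution; the reported linear range runs from the lowest point at or
above the LOQ to the highest point consistent with the line, where the
top is trimmed by a jackknife rule (predict the top point from the fit
on the points below it; drop it if the relative deviation exceeds 15 %)
so a saturating point cannot mask its own deviation by dragging the fit.
Recovery efficiency RE = IS_before/IS_after × 100 % and matrix effect
ME = IS_after/IS_alone × 100 % − 100 % use ratio-of-means over
replicates (the aggregate intensities enter one ratio; a mean of
per-replicate ratios is a different estimator and is deliberately not
used).  Flags: |ME| > 25 % (suppressed/enhanced) and RE < 75 %
(low recovery); boundary values are acceptable.

## Synthetic data

The simulator generates what the resolver consumes, without an
instrument.  Retention times follow a per-class linear model
`rt = intercept + coef_c × C − coef_db × DB` clipped to the class
elution window; the defaults use the equivalent-carbon-number form
(coef_db = 2 × coef_c) anchored on the platform's observed extremes —
TG from tri-18:3 at 9.7 min to tri-24:1 at 26.7 min, with MG (1.8–3.9
min) and DG (5.2–15.9 min) anchored the same way.  Peaks are Gaussian
(default sigma 0.08 min, consistent with baseline-resolved isobaric TGs
about half a minute apart); each ground-truth species feeds every
acyl-loss channel of its FAs with apex height = abundance ×
multiplicity × response factor (1e5 counts/nmol).  Noise is an additive
baseline (0.5 % of the internal-standard apex) plus a Gaussian term with
SD proportional to local intensity (CV 2 %); between-channel RT jitter
defaults to 0 (ideal co-elution) and is configurable to stress the
grouping tolerance.  All randomness flows through one seeded generator;
traces are bitwise reproducible.

Because the retention model is deterministic in (C, DB), two different
compositions of the *same* sum composition co-elute exactly and cannot
be separated — unlike on a real C30 column, where chain-level structure
shifts retention.  The default ground-truth sampler therefore draws
distinct sum compositions per sample.  What passing tests show is that
the detection → grouping → calling → quantification chain is correct
under the stated co-elution and multiplicity structure; they do not show
robustness to peak asymmetry, ion suppression, response-factor
differences between channels, or chromatographic drift, none of which
the simulator emulates.

## Default study conditions for end-to-end checks

Recovery tests run 20 seeded samples of 10 TG compositions each
(log-uniform abundances 0.5–20 nmol, 10 mg tissue, default noise) and
require ≥ 95 % of ground-truth triplets recovered as confirmed calls
with zero false confirmed calls and amounts within 3 × the simulator
noise CV.  These sizes keep the full suite in the low seconds on one
CPU while exercising every precursor class the default pool generates.

## Numerical choices and degenerate inputs

- Rounding for instrument export is round-half-up (`Decimal`), not
  banker's rounding.
- Formula subtraction that would drive an element count negative raises
  immediately — it always indicates a bookkeeping error in a neutral
  loss.
- Empty enumeration results are valid (a pool that cannot explain a
  precursor); the panel builder warns and emits no channels.
- A co-elution group supporting no candidate returns an empty call list
  with a structured warning rather than failing.
- Zero IS area or missing IS rows raise errors naming the sample and
  class; quantification never silently imputes.
- Single-replicate class totals report an empty SD rather than zero.

## Known limitations

- Double-bond positions, sn-positions, ether/oxidized lipids and
  PA/LPA are out of scope.
- The resolver does not deconvolve partially overlapping peaks by curve
  fitting; peaks closer than the merge separation are treated as one.
- Printed-panel regression validates the chemistry rules, not the
  original instrument's calibration.
- mzML chromatogram ingestion is experimental and not exercised by any
  acceptance path.
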