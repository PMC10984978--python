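# Methods

This note documents the models, conventions and numerical choices
behind `nanorapids`, and what the synthetic-data tests do and do not
demonstrate about real screens.

## Formula arithmetic

Atomic monoisotopic masses are frozen constants (AME2020/CODATA values,
`chem.MONOISOTOPIC_MASS`) so results are reproducible offline.
"Calculated" masses for protonated ions follow the natural-products
reporting convention: the printed formula is the *ion* formula and the
mass is a plain sum of neutral atomic masses, with no electron
subtraction. `protonated_mz(..., electron_correction=True)` adds the
true proton mass instead; the difference is one electron
(≈ 0.000549 Da), plus ~1.5×10⁻⁸ Da of hydrogen binding energy folded
into the frozen H mass. RDBE is `C − H/2 + N/2 + 1` with O/S/P ignored
and halogens counted like hydrogen. A CH₂ homolog series is flagged
when every consecutive m/z difference rounds to 14 *and* lies within a
tolerance (default 0.03 Da, accommodating the few-mDa scatter of
printed ion tables) of the exact CH₂ mass 14.01565 Da.

## Plate model

The fraction collector fills a 16×24 plate serpentine over columns
1–23, 350 wells per sample, 6 s per well; column 24 holds assay
controls and never enters the sample traversal. Orientation (row A
left→right first) is configurable — collectors differ and the
convention is not universal. Fraction *i* covers the half-open window
`[start + i·Δ, start + (i+1)·Δ)`; half-open avoids double-assignment at
boundaries. Normalization divides every well by the median of the
measured wells of that single plate read; controls are excluded from
the median by default (configurable, since a "single measurement" could
reasonably include them — with healthy-growth controls near baseline
the difference is negligible). Negative peaks are runs of at least
`min_width` (default 2) fractions below a normalized threshold
(default 0.8); the assay gives no published cut-off, so the default is
conservative and exposed in the config. Depth is `1 − min(response)`.

## Delay estimation and alignment

The fractionation path runs downstream of the post-column 1:9 flow
split, so the assay trace lags the MS trace by a fixed tubing delay.
Sign convention: `delay = bioassay apex − MS apex`. The MS apex is the
global maximum of the calibrant's base-peak chromatogram. The bioassay
apex is the depth-weighted centroid of the contiguous dip below the
halfway level between baseline and minimum — a plain argmin quantizes
to the 0.1 min fraction grid and ties at window boundaries, which a
centroid resolves. Because plate traces stamp wells by window *start*,
callers pass `well_time_offset = Δ/2` to refer apexes to window
centers; synthetic parameter-recovery tests then recover injected
delays of 0.1/0.3/1.0 min to ≲ 10⁻³ min, well inside the half-fraction
(0.05 min) requirement. Delays beyond a 5 min sanity limit are
rejected as calibration failures. `common_axis` interpolates both
traces linearly onto a uniform grid over the *intersection* of their
time ranges — interpolation only, never extrapolation; full-range
resampling would manufacture values outside either trace's support.

## Feature detection

The chain mirrors the widely used MZmine-2.53 parameterization for
Orbitrap data with open, documented semantics — an independent
reimplementation, not a bit-clone of closed behaviors. All m/z
tolerances are absolute Daltons (as conventionally quoted for these
steps), retention times are minutes.

- **Centroiding** — centroided scans are intensity-thresholded
  (MS1 noise 10⁴, MS2 0); profile scans are centroided at local maxima
  with intensity-weighted m/z over each maximum's contiguous support.
- **Chromatogram building** — per scan, centroids join the nearest
  open EIC within 0.001 Da (highest intensity first) or seed a new
  one; an EIC idle for more than one scan closes. Retention requires
  ≥ 10 consecutive-scan points above 10⁴ and a maximum ≥ 5×10⁴.
- **Deconvolution** — candidate split points are local minima that are
  minimal within ±0.1 min. A valley only resolves two peaks if both
  flanking maxima exceed it by the top/edge ratio (2); weaker valleys
  merge their neighbours, so shoulders stay single features. Surviving
  segments must clear the absolute (10⁴) and relative (1 % of EIC max)
  apex floors and the top/edge ratio against the segment edges. The
  "90 % chromatographic threshold" is interpreted as an intensity
  quantile: the peak body is the contiguous region around the apex
  above the 10 % intensity quantile of the segment, and its span must
  lie in 0.05–3 min. Area is trapezoidal over the full segment; feature
  m/z is the intensity-weighted mean.
- **MS2 pairing** — 0.05 Da / 1 min windows; ties break by smallest
  |Δm/z| then |ΔRT| (mass accuracy outranks elution proximity on a
  high-resolution instrument); among several MS2 per feature the
  highest-precursor-intensity scan is representative.
- **Isotope grouping** — Δm/z = 1.00335/z for z ∈ {1, 2} (configurable;
  small natural products are dominantly singly charged in positive
  ESI), within 0.001 Da and 0.1 min, transitive over A/A+1/A+2 chains;
  the lowest-m/z member represents the group and the pipeline keeps
  only monoisotopic rows.
- **Duplicate filtering** — two sequential passes, (0.001 Da, 0.05 min)
  then (1 Da, 0.05 min), keeping the taller row; rows are processed in
  descending height for determinism.
- **Row filter** — only MS2-bearing rows are exported for networking.

The pipeline is deterministic: all sorts are stable and every tie-break
is explicit.

## Molecular networking

The modified cosine operates on √-intensity peak vectors. Peaks pair if
their m/z agree within the fragment tolerance (0.9 Da — ion-trap MS2
accuracy) directly *or* after shifting by the precursor mass
difference, which is what links structural analogs such as CH₂
homologs. Candidate pairs are ranked by the product of √ intensities
and assigned greedily one-to-one; the test suite keeps an exhaustive
optimal-assignment matcher as an oracle and the greedy score equals it
on all random small-spectrum suites (and is never above it by
construction). Network edges require cosine > 0.7 **and** ≥ 4 matched
peaks ("more than three"); library hits use the slightly looser ≥ 3
matched peaks at score > 0.7 — the two thresholds are deliberately kept
distinct. GNPS-style topK/component-cap pruning exists as an option but
is off by default, since it is a scalability device rather than part of
the scoring model. Spectral families are connected components with ≥ 2
nodes, ordered by size then smallest node id.

## Bioactive mapping

A feature joins a bioactivity peak when its apex RT lies in the peak's
delay-corrected window ± one fraction duration (0.1 min) — mapping is
by retention time only, and the tolerance default equals the collection
resolution. Peaks with no qualifying feature are reported with an empty
feature list rather than dropped: a bioactive fraction can simply lack
an ionizable feature. Co-eluting assigned features are cross-annotated
against a small frozen table of exact mass deltas (H₂O 18.010565,
C₆H₁₀O₂ 114.068080, C₆H₁₀O₃ 130.062995, MeCN 41.026549) at ±0.005 Da —
looser than MS1 accuracy because published ion tables themselves
scatter by a few mDa; chains (sugar loss then water loss) label
pairwise. The table is user-extensible; only relations evidenced in
typical angucycline screens ship by default.

## Synthetic-data generator

The generator emulates the acquisition this pipeline targets: a 41 min
run, MS1 every 1.25 s (1968 scans per run — enough scans per peak to
exercise the group-size rule while keeping default-size runs fast),
m/z 100–2000, data-dependent MS2 on the top 3 precursors with 5 s
dynamic exclusion, Gaussian elution (default σ 0.06 min), A+1/A+2
isotope satellites at 1.1 % per carbon (with the A+2 falloff), and
uniform chemical noise strictly below the 10⁴ centroid floor. Plates
get multiplicative noise (CV 2 %) on a baseline of 5×10⁴ a.u.; active
compounds attenuate the wells their delayed elution window overlaps, in
proportion to the eluted amount, with a default activity depth of 0.8
(potent-antibiotic-like, near-complete inhibition at the dip apex). The
bundled validation scenario injects eight actives — a CH₂ homolog
quartet plus a positional isomer sharing one fragment core, and a
second three-member family with a disjoint core — over three inactive
background compounds.

What passing synthetic tests shows: the arithmetic of every stage, the
threshold semantics, the shifted-cosine clustering of homolog series,
and exact recovery under clean, well-separated peaks. What it does not
show: behaviour under chromatographic tailing, ion suppression,
coelution of unrelated compounds, multiply-charged envelopes, assay
drift, or centroiding of real profile data — real screens will not give
precision/recall of 1.0.

## File formats

mzML and mzXML are read into a common scan model (mzXML via pyteomics;
mzML via a self-contained reader covering the centroid LC-MS/MS subset:
64/32-bit arrays, zlib or no compression); an internal JSON scan format
round-trips losslessly. Synthetic runs can be written to all three.
Feature tables export as an FBMN-style quantification CSV (`row ID`,
`row m/z`, `row retention time`, `<sample> Peak area`; minutes, 4 d.p.)
with a paired MGF (`FEATURE_ID`, `PEPMASS`, `RTINSECONDS`, `SCANS`,
`CHARGE`; full precision) whose ids match one-to-one. Networks export
as GraphML (Cytoscape-openable) and an edge-list TSV. The YAML config
round-trips losslessly and rejects unknown keys by name.

## Problem sizes

Default test and acceptance runs use the full 41-min geometry
(1968 MS1 scans, ≤ 14 compounds, 350-well plates); the cosine oracle
suite uses 500 random pairs of 2–8-peak spectra. The whole suite runs
in well under a minute.
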