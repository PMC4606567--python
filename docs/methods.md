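# Methods

This note documents the models, algorithms and defaults implemented in
`lipidshot`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Acquisition model

An acquisition is a fixed six-segment sequence executed during one infusion:

| segment | polarity | type | range | lock mass |
|---|---|---|---|---|
| pos_sterol | + | MS1 | m/z 402–412 | — |
| pos_wide | + | MS1 | m/z 550–1000 | 680.48022 |
| pos_dia | + | DIA MS/MS | inclusion 500.5–999.75, 1 Da steps | — |
| neg_lyso | − | MS1 | m/z 400–650 | 529.46262 |
| neg_wide | − | MS1 | m/z 520–940 | 529.46262 |
| neg_dia | − | DIA MS/MS | inclusion 590.5–939.5, 1 Da steps | — |

DIA isolation windows are 1.0 Da wide on a 1 Da grid; intervals are treated
as half-open `[center − 0.5, center + 0.5)` so every target maps to exactly
one window and a boundary target is assigned upward. The narrow positive
window is reserved for the ammoniated sterol ion; lyso classes are read from
the low-mass negative window, all other negative classes from the wide one
(the two negative windows overlap in 520–650, so one canonical segment per
class avoids double-counting). Instrument settings (AGC, injection time)
are carried as opaque metadata and never used in computation.

Input is centroided. The canonical on-disk format is a TSV peak list
(6-decimal m/z, 1-decimal intensity) chosen for bit-exact fixtures; mzML is
supported through a read adapter and a minimal writer. The mzML adapter is
self-contained (built on lxml) and handles the common single-run layout with
float binary arrays and optional zlib compression; profile data and
chromatograms are out of scope.

## Chemistry

Isotope masses and abundances are pinned constants (2021 IUPAC/CIAAW values
as compiled by NIST) for H, C, N, O, P, S plus a deuterium label `D`
modelled as monoisotopic — labeled standards such as cholesterol-D6 do not
exchange their label. All ion m/z values include the electron mass: at 2 ppm
and m/z 400 the matching window is 0.8 mDa while the electron is 0.55 mDa.

Isotope envelopes are computed by per-element polynomial convolution
aggregated on the nucleon-shift index (unit-mass bins), the granularity of
centroided data at R = 140 000, where e.g. the ¹³C₂ and ¹⁸O isotopologues
centroid together. Envelopes are truncated at M+3 by default (the M+4 tail
of lipid-sized formulas is < 0.1%) and renormalized; envelope *ratios*
p_k/p0, the quantities the corrections use, are invariant under that
renormalization. The envelope algorithm is verified against brute-force
isotopologue enumeration (≤ 12 atoms, 1e-12 absolute).

Species formulas derive from per-class rules: ester backbones (glycerol,
glycerophospho-X, cholesterol for CE) plus `C_c H_{2c−2−2d} O` per
esterified chain; an ether linkage contributes `C_c H_{2c−2d}` instead
(+H₂, −O relative to the ester); sphingoid classes follow a totals rule
`C_c H_{2c+1−2d} N O_{1+oh}` plus a phosphocholine (SM) or hexose (HexCer)
head. A molecular species and its sum composition map to the identical
formula. All rules are validated against reference formulas for each class.

## Registry and standards

The default registry holds the 22 quantifiable classes with their adduct
(ammonium for Chol/CE/DAG/TAG; acetate for the choline and sphingoid
classes; deprotonation for the acidic classes), identification mode
(MS1-only vs MS1+MS/MS) and reporting depth (species vs molecular species).
TAG is reported at species level even though its chain losses are checked —
three-chain combinatorics defeat molecular assignment without separation.
Cholesterol is species-level: a sterol has no chains to resolve. LPG is
available as an optional 23rd class (`include_lpg=True`); it is excluded
from the default panel.

The 19-component internal standard mixture (pmol per 1 µL plasma) uses
odd-chain or short-chain species absent from plasma, plus deuterated
cholesterol. Ether classes are quantified against the standard of their
diacyl counterpart — they share the head group that dominates ionization
response. Quantifying with one standard per class presumes equal response
factors within a class, which holds at the optimized sample amount; the
package takes it as given.

Default enumeration ranges (diacyl glycerophospholipids C 26–44 / DB 0–10,
lyso C 14–24 / DB 0–6, sphingoid C 26–48 / DB 0–4 / OH 2, CE chain C 10–26 /
DB 0–8, DAG C 24–40, TAG C 36–60 / DB 0–12, odd and even carbons) yield
3222 database entries.

## Identification

Database entries are matched per MS1 segment to their nearest peak,
inclusive at the tolerance: 2 ppm where lock-mass recalibration was applied,
8 ppm otherwise; MS/MS always uses 8 ppm (no lock reference exists there).
Lock-mass correction is single-point multiplicative (calibration error is
ppm-constant on this detector type), searching ±10 ppm around the reference
with the most intense candidate winning; a missing lock is a status that
widens the downstream tier, not an error.

Entries matched to one peak form an ambiguity group. Because exact
cross-class isobars exist — a deprotonated PS X:Y has the identical
elemental composition as the acetate adduct of PC (X−4):(Y+1) — mass error
cannot arbitrate such groups, and the primary annotation is chosen by
fragment evidence first: confirmed candidates outrank unconfirmed, then the
candidate explaining more matched fragment current, then the smaller mass
error. Only the primary is quantified; the group is recorded on the output
row.

Fragment confirmation requires, for chain-resolved classes, a *complete*
candidate: every complementary chain fragment present above the intensity
floor (default 0). A single stray anion from a co-isolated isobar in the
same 1-Da window must not validate a composition it cannot fully explain.
Species-level classes with chain rules (TAG) are probed chain-by-chain;
CE uses the fixed sterol cation (m/z 369.35).

After acceptance, an isotope-peak exclusion pass discards identifications
whose matched peak sits on an isotopologue position (within tolerance) of
another accepted species of a different class and is ≥ 80% explained by
that species' predicted envelope — otherwise MS1-only classes acquire
phantom species from strong neighbors' isotope peaks.

## De-isotoping and quantification

Type I runs within each class series in ascending m/z, subtracting each
species' predicted M+2 (and M+4) intensity — its running corrected
monoisotopic intensity times p_k/p0 — from any later peak within the
centroid-merge window, default 0.011 Da (≈ FWHM at m/z 750 for R 140 000
specified at m/z 200, scaling as the inverse square root). At that window
the ΔDB = 1 / M+2 overlap (8.9 mDa) is corrected while the ΔDB = 2 / M+4
positions (17.9 mDa apart) are resolved and correctly left alone. Negative
results clamp to zero with a flag. A `resolved` mode disables subtraction.

A cross-class pass then repeats the subtraction on the scan-averaging
cluster scale (default 5 ppm) for peaks of *different* classes: the standard
mixture itself contains such an overlap (the LPG standard's M+3 sits
1.7 ppm from the LPC standard and would bias every LPC concentration by
~0.7%). This pass is on by default and can be disabled
(`deisotope_cross_class=False`).

Type II divides each monoisotopic intensity by its own formula's p0; the
standard is corrected by its (possibly label-bearing) formula. Concentration
is the corrected ratio times the spiked amount, rescaled by the extracted
plasma volume; pmol/µL plasma is reported as µM. Citrate-anticoagulated
samples are multiplied by (10+1)/10 = 1.1, undoing the 10:1 v/v dilution of
blood by the citrate solution; EDTA and heparin are untouched.

Deconvolution fractions include the candidate's own channels in the
denominator — the only reading under which fractions sum to one and
molecular concentrations conserve the species total. A chain shared between
candidates contributes its observed intensity to each of them; conservation
holds regardless. When every channel is zero the species stays at species
level. Single-chain molecular classes (lyso, CE) report their single
decomposition at fraction 1.

## QC statistics

CV uses the n−1 sample standard deviation. Quartile reports sort species by
mean concentration descending (ties by name), split into four equal-count
groups (remainder to the most abundant quartiles — a 224-species table
gives 56/56/56/56), and report per-quartile mean CV, species count and mol%
coverage. Dose-response fits are least squares on log10(measured) vs
log10(spiked); LOQ is the smallest level at which all higher levels keep
replicate CV below 20% and the restricted slope stays in [0.9, 1.1]
(configurable; raising the CV threshold can only lower the LOQ). Lipidome
correlation is Pearson on log10 concentrations of the shared species —
concentrations span four orders of magnitude, and a linear-scale r would be
driven entirely by the top species.

## The simulator and what passing tests mean

`simulate_run` renders a ground truth into spectra using the same chemistry
module as the pipeline: MS1 envelopes (M+0..M+3 at ¹³C spacing) at the class
adduct m/z with intensity ∝ concentration (1000 counts/µM/scan; the scale
cancels in ratios), the lock-mass background ion carrying the same
systematic offset as every peak in its segment, and DIA scans with
acyl-anion / neutral-loss fragments ∝ molecular fraction × fragment yield
(default 0.05, an arbitrary but inert choice) × precursor intensity. The
M+2 isotopologue of a species is emitted *onto* its ΔDB = 1 neighbor's
centroid when within the merge window, mirroring what the corrector
assumes. Two repeat MS1 scans per segment are emitted by default, matching
the instrument's two-microscan averaging; with one lognormal intensity
factor per species per scan, averaging and the ratio to the standard leave
the recovered concentration CV approximately equal to `intensity_cv`.
Noise fields (multiplicative CV, ppm jitter, calibration offset, uniform
baseline peaks, additive intensity floor) all default to zero; a single
integer seed fixes a run byte-for-byte, with per-spectrum substreams derived
by hashing (seed, segment, scan).

The committed reference ground truth holds exactly 224 species across the
22 classes, concentrations log-spread over per-class spans within
0.05–2500 µM (the bulk of the molar amount in Chol, PC, CE, SM, TAG, as in
plasma), 0.7/0.3 molecular fractions over two chain-disjoint decompositions
for the deconvolvable classes, and ≥ 10 deliberate ΔDB = 1 overlap pairs.
Two guards keep its identifications unambiguous *by construction*: species
whose isotopologue positions fall within 3 ppm of an MS1-only class's
database target, or within 7 ppm of another chosen class's positions
(centroids would merge), are skipped; the standards' ions are reserved
first.

What the closed-loop tests therefore show: the computational chain —
matching, confirmation, both isotope corrections, the standard ratio, the
deconvolution algebra — is exact (ground truth recovered to < 1e-6
relative without noise, CV ≈ 10% recovered at 10% noise). What they do not
show: robustness to ion suppression and matrix effects, chemical background
beyond random baseline peaks, profile peak-shape effects, or co-isolation
patterns absent from the fixture. In particular, when two same-polarity
species share a DIA window and a chain, the deconvolution attributes the
shared anion current to both parents' candidates — exact fraction recovery
is only guaranteed when candidates share no observed chains, which the
fixture's decompositions arrange within each species but co-isolation can
violate across species.

## Numerical choices and degenerate inputs

Tolerance comparisons are inclusive with a 1e-9 relative guard against
float representation. Averaging clusters peaks greedily in ascending m/z
against the running intensity-weighted mean (5 ppm default); a peak absent
from a scan counts as zero, making averaging linear in total ion current.
Subtraction below zero clamps with a flag. A class whose standard is
missing or zero-intensity is skipped with a warning rather than guessed. An
empty run is an error; an absent lock mass is not. Deterministic tie-breaks:
equal-error ambiguity by lower target m/z, equal-abundance quartile
membership by species name.

## Problem sizes

The default test suite and the acceptance script run the full pipeline on
224-species acquisitions (≈ 1 s per run after warm-up) and a 20-replicate
noise study (≈ 20 s); the database holds 3222 entries. These sizes exercise
every code path, including overlap correction and ambiguity arbitration, at
interactive speeds.
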