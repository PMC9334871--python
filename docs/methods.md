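# Methods

This note documents the models, parameter choices and numerical decisions
behind `cytoval`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Event model and gating

A cytometry sample is modelled as a mixture of four populations: live
singlets, debris, dead cells and doublets. Fluorescence and viability-dye
intensities are lognormal — the standard model for a gated, unimodal
cytometry population — parameterized by arithmetic mean m and arithmetic
coefficient of variation (CV), i.e. `sigma = sqrt(ln(1 + CV²))`,
`mu = ln m − sigma²/2`. Scatter intensities are normal truncated at zero.
Doublets are built mechanistically: pulse *areas* (FSC-A, SSC-A) and
fluorescence are sums of two independent singlet draws, while pulse
*height* (FSC-H) stays singlet-like, so the doublet FSC-A/FSC-H ratio sits
near twice the singlet ratio — exactly the signature the singlet gate
exploits.

Default generator conditions (chosen once, as the study conditions the
pipeline is validated under): 20,000 events per sample (the acquisition
minimum of the emulated protocol), 70% live singlets and 10% each of
debris/dead/doublets, fluorescence CV 0.5. Scatter locations (live FSC-H
1e5 ± 1e4; dead 4e4 ± 6e3; debris 1.5e4 ± 3e3) put the artifact
populations ≥ 6 SD from live cells, matching the regime in which the
recovery guarantees are stated. Dead cells carry a 20-fold brighter
viability dye (geometric separation; misclassification < 0.5%).

Two gating strategies mirror bench practice and are required to agree:

* `scatter_only`: rectangle on FSC-H × FSC-Width excluding low-FSC-H
  debris *and* shrunken dead cells (default FSC-H ≥ 7e4, i.e. −3 SD of the
  live population), then the singlet gate;
* `viability_dye`: a debris-only rectangle (FSC-H ≥ 3e4), a threshold on
  the dye channel (default 500, the geometric midpoint between live ~1e2
  and dead ~2e3 dye means), then the singlet gate.

The singlet gate divides each event's FSC-A/FSC-H ratio by the population
median and keeps the band [0.8, 1.25]. Median normalization makes the gate
insensitive to the (instrument-dependent) absolute area/height calibration;
events with FSC-H = 0 are excluded, counted, and never an error. All gate
regions are closed (boundary events kept) for determinism; gates are
data-independent specs, with an optional percentile helper for placement
that nothing uses by default.

## Staining statistics

MFI is the arithmetic mean (a median variant exists behind a flag and is
never the default); SD uses the n−1 denominator. The stain index uses the
difference form `(MFI_ab − MFI_iso) / (2·SD_iso)` — the standard
definition; a ratio-form wording that sometimes appears for this quantity
is not implemented. Normalized MFI supports both a ratio
(`MFI_ab/MFI_iso`) and a difference (`MFI_ab − MFI_iso`) form because both
are used in practice for different comparisons; callers must name the form
and it is recorded in the output. Blocking efficiencies outside [0, 1] are
reported as-is with an `out_of_range` flag, never clipped: over- and
non-blocking are findings. When the stained signal does not exceed the
no-stain control the efficiency is undefined and raises — the "no
detectable blocking" regime for low-sensitivity antibodies on
low-expressing cells.

## Titration model and the optimal-amount policy

The generator's titration truth is a saturation-binding curve: antibody
`MFI(c) = B + Bmax·c/(Kd + c) + s·c`, isotype `MFI(c) = B + s·c`, with the
nonspecific slope `s` applying to both. The bundled per-clone parameter
sets are calibrated so the generating SI-vs-amount profiles encode the
published titration behaviour of the three emulated clones; for the
LB509-like clone a single hyperbola cannot pass through all three printed
SI values at once, so its parameters reproduce the decision-relevant shape
(which amounts reach the 75% rule, and the choice of the recommended
amount) rather than every printed SI.

The optimal-amount policy — smallest amount with `SI ≥ θ·max SI`,
θ = 0.75, optional isotype-ratio cap — is a reconstruction: it is the
simplest monotone rule that reproduces all three published choices (2 μg,
1 μg, 0.1 μg) from the printed SI tables. θ = 1 degenerates to max-SI;
θ → 0 to the smallest tested amount. When nothing satisfies the
constraints the max-SI amount is returned with a warning rather than an
error, since a titration must end in a usable amount.

## Blocking model

Blocking acts multiplicatively on the specific fluorescence component
only: stained mean `B + S`, blocked mean `B + (1 − κ)·S`, no-stain mean
`B`. Under the ΔMFI/ΔMFI definition the generating efficiency is then
exactly κ, which makes recovery tests exact rather than approximate. The
excess-fold dependence is `κ′ = κ·(fold/600)^h` with h = 0 by default —
saturated blocking, encoding the observation that the two standard
pre-incubation conditions (300-fold, 37 °C, 1 h and 600-fold, RT, 2 h)
block comparably; h is configurable for sensitivity studies. Specificity
thresholds (self ≥ 0.85, cross ≥ 0.40) are invented defaults calibrated to
reproduce the published verbal classifications; both are configurable and
echoed into every report. Mixtures that contain the antigen itself are
never counted as cross-reactants.

## Sequence alignment

The aligner is a three-state Gotoh dynamic program (match, gap-in-A,
gap-in-B) with affine penalties, BLOSUM62, and deterministic traceback
(tie order diagonal > vertical > horizontal; gap-state switches allowed
and charged as fresh openings). Global mode leaves end gaps free by
default (the reference-tool convention) but still reports the full-length
alignment; identity and similarity use the full alignment length including
gap columns as denominator. Two gap-cost conventions are supported —
`open + (g−1)·extend` (default) and `open + g·extend` — because reference
tools disagree on whether the first gapped residue pays the extension; the
convention is recorded on every result. Correctness is established two
ways: exhaustive enumeration of all gapped alignments on small inputs, and
score agreement with an independent reference aligner (Biopython's
`PairwiseAligner`) on random protein pairs. The enumeration oracle covers
all pairs up to length 2 over a 4-letter alphabet plus random pairs up to
length 6 (global) and 5 (local); longer inputs are covered by the
reference-aligner cross-check, which is O(nm) rather than exponential.

The bundled FASTA fixtures: the 140-residue human alpha-synuclein sequence,
and four tubulin entries that are offline reconstructions explicitly
labelled `_SYNTHETIC` in their identifiers and headers. The β3-tubulin
stand-in's aSyn-similar region reproduces the published local-alignment
statistic exactly (33% identity over aSyn residues 114–131); the pig
α-chain stand-ins cannot reproduce chain-specific published identities,
and the corresponding acceptance cases fail honestly rather than assert
against fabricated references.

## Li thresholding and image quantification

`li_threshold` implements the minimum-cross-entropy fixed point
`t ← (μ₁ − μ₂)/(ln μ₁ − ln μ₂)` (class means below/above t), initialized
at the image mean, tolerance 0.5 intensity units; a constant image raises.
Zero or negative minima are handled by an epsilon shift before the
logarithms. An exhaustive scan over all inter-level midpoints of the same
criterion serves as the oracle; on integer histograms the two agree in the
sense that they cut the same inter-level gap (identical partitions) — a
stronger and better-posed check than a fixed numeric tolerance, since gaps
between occupied intensity levels routinely exceed one unit. The threshold
is exactly covariant under multiplicative intensity scaling, and for
well-separated bimodal images a constant brightness offset moves the
threshold within the gap, leaving the mask unchanged — both are tested.
Masks use an inclusive `marker ≥ t` comparison with no morphological
cleanup; batch mode either recomputes the threshold per image or derives
it once from a reference image (or the pooled histogram) and holds it
constant.

## Workflow, configuration and reproducibility

The workflow executes titration → self-blocking → related-protein blocking
→ expression map → physiological contrasts, then assembles assessments and
the final ranking. Configuration is YAML (or a dict) validated by explicit
structural checks that raise `ConfigError` before any computation; every
threshold, seed and strategy is echoed into `report.json` so each number
in a report traces to (inputs, operation, parameters). All randomness
derives from the single config seed through a spawned `SeedSequence` tree
(children reduced mod 2³¹), so re-running a fully synthetic config is
bit-identical; reports contain no timestamps. CSV (written at `%.17g`,
which round-trips IEEE doubles exactly) is the canonical interchange
format; FCS 3.0/3.1 reading supports `$DATATYPE` F/D/I list-mode files and
rejects anything else with a message naming the offending segment.

## Problem sizes used in tests

Recovery tests run at the acquisition scale of 20,000 events per sample —
at that size the MFI estimate lands within 2% of truth, SI within 10%, and
blocking efficiency within ±0.05 of κ. The ranking-replication experiment
runs the full three-clone blocking panel at 20,000 events for 100 seeds.
The estimator-consistency check (SD of the MFI estimate scaling as 1/√n)
uses 50 seeds at 4,000 vs 8,000 events, where the √2 ratio is already
unambiguous.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the analysis assumes —
lognormal unimodal fluorescence, scatter-separable artifact populations,
saturating specific binding with linear nonspecific background, blocking
that removes only specific signal. It does not emulate spectral spillover
realism (compensation is tested as a mathematical contract only, since no
real spillover matrix is available), autofluorescence spectra, instrument
noise beyond the lognormal/normal model, bimodal or skewed real
populations, or debris/dead populations that overlap the live gate.
Passing recovery tests therefore show that the estimators are correct and
well-calibrated under the stated model, not that the model captures every
real instrument artifact. The published cell-line results themselves (SI
values of real HEK/hiPSC/fibroblast/T-cell samples, the knock-down and
gene-dosage contrasts) are not reproducible without the original FCS files
and images; the pipeline instead demonstrates that it *recovers* those
contrasts when they are encoded as ground truth.
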