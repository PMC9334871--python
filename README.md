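# cytoval

Quantitative antibody validation for flow cytometry, with a sequence-similarity
screen and immunofluorescence quantification on the side.

Antibodies against alpha-synuclein (aSyn) — the 140-residue protein whose
aggregation defines Parkinson's disease and related synucleinopathies — vary
wildly in specificity and sensitivity, and most commercial clones are poorly
characterized. `cytoval` implements the computational half of a
flow-cytometry-based validation workflow for such antibodies: gating,
titration analysis, competition-blocking panels, cross-cell-type sensitivity
maps, an epitope-vs-off-target sequence-similarity screen, and Li-threshold
image quantification — plus a synthetic-data generator that emulates the
study design with recorded ground truth, so every estimator in the pipeline
is testable against known parameters.

## The statistics at the core

For a gated live-singlet population, with MFI the arithmetic mean
fluorescence intensity on one detector:

- **Stain index** — signal-over-background separation of an antibody stain
  against its isotype control:
  `SI = (MFI_ab − MFI_iso) / (2 · SD_iso)`.
  SI is invariant under affine rescaling of the intensity axis, so it is
  comparable across instruments.
- **Titration / optimal amount** — across antibody amounts *c* (μg per 50 μl
  staining), the pipeline tabulates SI(c) and ratio MFI
  (`MFI(c) / MFI(c_recommended)`) for antibody and isotype; the optimal
  amount is the smallest *c* with `SI(c) ≥ θ · max SI` (θ = 0.75 by
  default) — near-maximal separation at minimal consumption.
- **Blocking efficiency** — after pre-incubating the antibody with a molar
  excess of a candidate binding partner:
  `E = (MFI_stained − MFI_blocked) / (MFI_stained − MFI_nostain)`,
  the fraction of specific signal removed. Blocking by the antigen itself
  measures specificity; blocking by related proteins (β-/γ-synuclein,
  tubulin) measures cross-reactivity. An antibody is called *specific* when
  mean self-blocking ≥ 0.85, and *cross-reactive* with any other protein
  blocking ≥ 0.40 (both configurable); antibodies are ranked by
  (specific, fewer cross-reactants, stronger self-blocking).
- **Sequence screen** — Smith–Waterman (local) and Needleman–Wunsch
  (global, free end gaps) affine-gap alignments (BLOSUM62, gap open 10,
  extend 0.5) of antibody epitopes against off-target sequences explain
  observed cross-reactivity: e.g. the region of aSyn most similar to
  neuronal β3-tubulin spans residues 114–131, exactly covering the
  C-terminal epitopes (115–122, 118–123) of the cross-reacting clones.
- **Image quantification** — the structural-marker channel is thresholded
  by Li's minimum-cross-entropy method; the target channel's mean gray
  value inside the mask quantifies expression in marker-positive
  structures.

## Worked example

Run the bundled three-clone synthetic study (three antibodies whose
ground-truth binding, blocking and expression parameters encode the
behaviour of the 2A7, LB509 and MJFR1 clones):

```python
from cytoval import run_validation

report = run_validation({
    "seed": 3,
    "output_dir": "out",
    "antibodies": [
        {"name": "2A7", "preset": "2A7"},
        {"name": "LB509", "preset": "LB509"},
        {"name": "MJFR1", "preset": "MJFR1"},
    ],
})
print(report["ranking"])
for name, entry in report["antibodies"].items():
    print(name, entry["titration"]["chosen_amount"],
          {k: round(v, 2) for k, v in entry["blocking"]["efficiencies"].items()})
```

prints

```
['2A7', 'MJFR1', 'LB509']
2A7 2.0 {'aSyn_monomer': 0.92, 'bSyn': 0.49, 'gSyn': 0.15, 'tubulin': 0.07}
LB509 1.0 {'aSyn_monomer': 0.52, 'bSyn': 0.61, 'gSyn': 0.42, 'tubulin': 0.7}
MJFR1 0.1 {'aSyn_monomer': 0.95, 'bSyn': 0.87, 'gSyn': 0.43, 'tubulin': 0.26}
```

Reading: each antibody's titration selected an optimal staining amount
(2 μg, 1 μg, 0.1 μg); the blocking panel recovered each clone's generating
κ values, classifying 2A7 as specific with mild β-synuclein
cross-reactivity, MJFR1 as specific but cross-reactive with β- and
γ-synuclein, and LB509 as non-specific (self-blocking only ~52%, blocked
even better by tubulin than by its own antigen) — hence the ranking.
The same pipeline is exposed as a CLI (`cytoval run --config cfg.yaml`,
plus `simulate`, `gate`, `metrics`, `titrate`, `block`, `expression-map`,
`align`, `icc` subcommands).

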