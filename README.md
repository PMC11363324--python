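# mubridge

Analysis pipeline for studies of μ-opioid-receptor (μOR) ligands that target
the conserved sodium allosteric site *indirectly, through ordered water
molecules*. Such bitopic ligands carry a polar warhead (e.g. a benzyl
alcohol) that engages the sodium-site aspartate D^2.50 via hydrogen-bonded
water bridges rather than a direct salt bridge, which modulates G-protein
efficacy, β-arrestin recruitment and receptor trafficking. The package is
aimed at computational chemists and pharmacologists who need the
downstream statistics of such a study — simulation-frame interaction
scoring, proximity-proteomics deconvolution and concentration/dose-response
summaries — in one tested toolbox, exercisable end-to-end on synthetic data
with known ground truth.

## What it computes

**Water-bridge classification** (`mubridge.bridge`). Each structure
snapshot is labelled by an exclusion hierarchy over the hydrogen-bond graph
on {ligand hydroxyl O} ∪ {water O} ∪ {carboxylate O}:

- `direct` — ligand O hydrogen-bonds a carboxylate O (heavy-atom distance
  in the 2.2–3.0 Å window);
- `water1` — else, a path ligand–water–carboxylate exists;
- `water2` — else, a path through two distinct consecutive waters exists;
- `none` — otherwise (bridges of ≥3 waters are not scored).

Class frequencies (fraction of frames) are aggregated per simulation
replicate with mean ± SEM and compared between ligands with a two-sided
Mann–Whitney U test (exact enumeration for small replicate counts).
Supporting detectors (`mubridge.geometry`) score hydrogen bonds, ring
centroids/normals and face-to-face π–π stacking (centroid distance ≤ 5 Å,
interplanar angle ≤ 30°, lateral offset ≤ 2 Å) — e.g. the ligand-phenyl ↔
Y^7.43 stacking frequency associated with β-arrestin recruitment.

**APEX proximity proteomics** (`mubridge.apex`). From a protein-intensity
matrix of receptor-APEX samples and spatial references (plasma membrane,
early endosome, lysosome): (1) per time point and replicate, the receptor's
subcellular distribution is deconvolved by non-negative least squares on
location-specific indicator-protein intensities, `min‖y − Xβ‖², β ≥ 0`;
(2) per protein, log2 intensities are fitted with a polynomial time course
and an F-test against the intercept-only model scores change over time;
proteins with max |log2FC| > 0.58 and p < 0.001 are called proximal-network
hits.

**Pharmacology** (`mubridge.pharm`). Concentration-response data normalised
to a reference full agonist are fitted with the four-parameter logistic

    y(c) = baseline + (Emax − baseline) / (1 + 10^((log10 EC50 − log10 c)·h)),

reporting Emax, EC50 (nM), pEC50 ± SE and Hill slope h. Antinociception
data (%MPE, warm-water tail withdrawal) are fitted with a two-parameter
log-logistic with floor 0/ceiling 100 to estimate ED50 with a 95% CI, and
brain:plasma exposure is summarised as a concentration ratio.

**Synthetic data** (`mubridge.synth`) generates all of the above with
known ground truth: frames with designed bridge topology (jitter re-sampled
so it never flips the designed class), 4PL curves, APEX time-course
matrices with planted changing proteins, and graded %MPE data.

## Worked example

```python
from mubridge import (bridge_frequencies, classify_frames, fit_4pl,
                      brain_plasma_ratio)
from mubridge.synth import (FrameSpec, CurveTruth, gen_bridge_frames,
                            gen_dose_response)

# 100 frames with a designed 10/60/20/10 direct/water1/water2/none mixture
labels = ("direct",)*10 + ("water1",)*60 + ("water2",)*20 + ("none",)*10
frames, truth = gen_bridge_frames(FrameSpec(labels=labels, jitter_sd=0.05,
                                            seed=7))
half = len(frames) // 2
table = bridge_frequencies({
    "rep1": [c.label for c in classify_frames(frames[:half])],
    "rep2": [c.label for c in classify_frames(frames[half:])],
})
print(table.summary.round(3))

# partial-agonist concentration-response at Emax 65%, pEC50 6.34, 5% noise
fit = fit_4pl(gen_dose_response(CurveTruth(pec50_true=6.34, emax_true=65.0,
                                           noise_sd=5.0, seed=1)))
print(f"Emax = {fit.emax:.1f}%  pEC50 = {fit.pec50:.2f}  "
      f"EC50 = {fit.ec50_nm:.0f} nM  [{fit.activity}]")

print(brain_plasma_ratio(2.8, 5.3))
```

prints

```
        mean  sem
direct   0.1  0.1
water1   0.6  0.2
water2   0.2  0.2
none     0.1  0.1
Emax = 66.8%  pEC50 = 6.32  EC50 = 484 nM  [active]
RatioResult(ratio=0.5283018867924528, reported=0.5)
```

The frequency table is the per-class fraction of frames averaged over the
two replicates (SEM across replicates); the 4PL fit recovers the
generating Emax/pEC50 from noisy data; the brain:plasma ratio of 2.8 μM /
5.3 μM rounds to the conventional one-decimal report of 0.5.

The same stages are scriptable from the shell via the `mubridge` console
command (`mubridge synth|geom|bridge|pharm|apex --help`).

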