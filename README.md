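# nirsmap

Catheter-based near-infrared spectroscopy (NIRS) lesion mapping:
preprocessing of diffuse-reflectance spectra, optical-index extraction
with contact filtering, heart-wise lesion classification, spatial
probability-map construction, and masked map comparison — plus a
synthetic data generator with the statistical structure the analysis
assumes, so the whole pipeline can be exercised and validated without
bench data.

## Pipeline overview

1. **Preprocess** (`nirsmap.preprocess`): raw counts ÷ 99% diffuse
   standard × phantom factor → truncate to 600–1000 nm → resample to a
   1 nm grid → zero-phase 4th-order Butterworth lowpass (0.05 π) →
   normalize at 600 nm.
2. **Indices & contact filter** (`nirsmap.indices`): six scalar indices
   per spectrum; spectra with COI = Rrel(764)/Rrel(730) < 0.93 are
   rejected as poor contact. An exhaustive ratio-index search ranks all
   401 × 400 wavelength pairs by single-feature ROC AUC.
3. **Classify** (`nirsmap.classify`): heart-wise train/test split,
   5-fold heart-grouped cross-validation, probability-averaging
   ensemble; five model families with inverse-frequency class weights.
4. **Map** (`nirsmap.mapping`): homography registration, scattered
   linear interpolation, concave (alpha-shape) boundary mask, masked
   2-D lowpass smoothing, probability thresholding.
5. **Compare** (`nirsmap.compare`): masked SSIM, normalized inner
   product, RMS difference, and Dice between paired maps (e.g. PBS vs
   blood) or prediction vs ground truth.

See [docs/methods.md](docs/methods.md) for the full methods note.

## Worked example

Run the default synthetic study (22 hearts × 800 points × 2 media,
18/4 heart split, random forest) from Python:

```python
from nirsmap import pipeline

result = pipeline.run_pipeline(pipeline.PipelineConfig(seed=1))
print(result.evaluation.as_dict())
print(result.cohort.mean_ssim, result.cohort.mean_dice[0.5])
```

With seed 1 this prints (about two minutes on one CPU):

- test AUC **0.916**, sensitivity **0.817**, specificity **0.855**
  (5080 test spectra from 4 held-out hearts);
- contact rejection **20.7%** of 35,200 spectra;
- PBS-vs-blood map equivalence over the test hearts: mean SSIM
  **0.880**, mean inner product **0.981**, mean Dice at p = 0.5
  **0.907**;
- prediction-vs-truth Dice at p = 0.5: **0.836** averaged over both
  media and all test hearts.

Zeroing the simulated lesion effects
(`synthetic.TissueOpticsParams().zero_effect()`) drops the test AUC to
**0.496** — chance, as it should be.

The same study from the shell:

```bash
nirsmap simulate --seed 1 --out session/     # spectra, metadata, truth
nirsmap analyze  --seed 1 --out run/         # index table + summary.json
```

Both commands accept `--config config.json` mirroring
`pipeline.PipelineConfig` fields, e.g.
`{"session": {"n_hearts": 6, "points_per_heart": 100}}` for a quick
smoke run.

## Tests and acceptance

```bash
python -m pytest -q tests/                    # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` checks the published cohort-table
arithmetic, oracle equivalence of the AUC and index implementations,
filter and registration contracts, and the synthetic-study invariants
(classifier recovery, null calibration, map equivalence, angle
robustness). The acceptance script reports the headline numbers as
JSON.
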