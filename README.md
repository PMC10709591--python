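# vtsct — virtual thin-section CT toolkit

A testbed for through-plane CT super-resolution and its downstream
clinical measurement chain, built entirely around synthetic lung-nodule
phantoms with exact ground truth:

- **`vtsct.phantom`** — seeded 3D nodule phantoms (solid / part-solid /
  pure ground-glass, optionally z-elongated ellipsoids) and cohort
  generation emulating a 93-case early-adenocarcinoma population.
- **`vtsct.slabsim`** — thick-slice simulation by overlap-weighted slab
  averaging (3.0–8.0 mm thickness/interval), random slice-condition
  sampling, and the slice-count fold-increase calculation.
- **`vtsct.vtsgan`** — conditional adversarial slice interpolation: a
  residual NumPy conv-net generator (condition channels for thickness
  and interval) over a data-consistent classical upsampling, trained
  against a 3D patch discriminator with L1 + least-squares adversarial
  losses; classical nearest/linear/cubic baselines included.  Pure
  NumPy, CPU-sized, bit-for-bit deterministic inference.
- **`vtsct.mpr_measure`** — axial/coronal/sagittal plane extraction and
  automated maximal solid/total size measurement (threshold → largest
  26-connected component → per-plane maximum Feret diameter → maximum
  over orientations), plus a simulated human-observer noise model.
- **`vtsct.staging`** — size-based clinical/pathological T category
  assignment (Tis, T1mi, T1a, T1b, T1c, T2a).
- **`vtsct.agreestats`** — ICC(2,1) with F-based CI, Cohen's kappa with
  large-sample CI and agreement bands, Hotelling–Williams comparison of
  dependent correlations, and the observer/modality ANCOVA.
- **`vtsct.study`** — the end-to-end scaled-down validation experiment:
  cohort → thin phantoms → 5 mm degradation → virtual thin
  reconstruction → two simulated observers → staging → full agreement
  battery, all seeded.
- **`vtsct.cli_io`** — NIfTI/MetaImage volume I/O, run manifests with
  checksums, and the `vtsct` command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; the
scaled-down efficacy criterion trains a small model on 20 phantoms and
runs three seeded 93-case studies (≈ 8 minutes on one CPU); everything
else finishes in seconds.

## CLI

```sh
vtsct phantom --out-dir run/ --n 5 --seed 1      # phantoms + ground truth table
vtsct degrade run/phantom_000.mha --out thick.mha --thickness 5 --interval 5
vtsct train --config train.json --out model.npz --seed 1
vtsct infer thick.mha --model model.npz --out virtual.mha
vtsct measure virtual.mha
vtsct stage --total 25 --solid 4
vtsct study --out-dir study_run/                 # full experiment + report
```

Each run directory receives a `manifest.json` recording the tool
version, config hash, seeds and output checksums.

## Python example

```python
from vtsct.study import StudyConfig, run_study, train_toy_model, write_report

model = train_toy_model(seed=0)          # ~6 min on one CPU
report = run_study(StudyConfig(), model=model)
print(write_report(report, "report.json"))
```
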