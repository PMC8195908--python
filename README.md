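# resit — equivalent-source interpolation of bad EEG channels

`resit` reconstructs corrupted ("bad") scalp-EEG channels with the
**Reference Electrode Standardization Interpolation Technique (RESIT)**: an
equivalent dipole source layer inside a three-shell spherical head model is
estimated from the remaining good channels through a Moore–Penrose
pseudoinverse, and the full scalp potential is reconstructed by forward
projection to every electrode. Because the forward model is expressed
against a reference at infinity, the reconstruction simultaneously
standardizes the recording reference (with no bad channels the method
reduces exactly to REST reference standardization).

The package also provides the two classical baselines — **neighbor
averaging (NI)** and **spherical-spline interpolation (SSI)** — reference
transforms, a bad-channel injection benchmark, and a dipole simulator for
fully offline synthetic EEG.

## How it works

1. **Forward model.** The head is three concentric spheres (brain / skull /
   scalp; radii 0.87 / 0.92 / 1.0 scalp-radius units, conductivities
   1.0 / 0.0125 / 1.0). The scalp potential of a dipole is a Legendre
   series whose per-degree transfer coefficients follow from continuity of
   potential and radial current at the shell boundaries.
2. **Equivalent sources.** A fixed layer of 3,000 unit dipoles closes a
   surface inside the brain: 2,600 radially oriented dipoles on a spherical
   cap of radius 0.869 plus 400 +z-oriented dipoles on a transverse plane
   at z = −0.076. The lead field `L` maps these sources to all N
   electrodes, reference at infinity.
3. **Interpolation.** Restrict `L` to the good channels, transform it to
   the data's reference (average over good channels, or a scalp point),
   estimate sources `S = pinv(L_ref) @ V_ref`, and reconstruct
   `V = L @ S` at every electrode — bad channels filled in, reference
   standardized to infinity.

## Quick start

```python
from resit import (ConcentricSphereHeadModel, SimulationConfig, build_source_grid,
                   compute_leadfield, interp_metrics, make_montage_fixture,
                   ni_interpolate, rereference, resit_interpolate, simulate_eeg,
                   ssi_interpolate)

montage = make_montage_fixture(62)
model = ConcentricSphereHeadModel()
leadfield = compute_leadfield(model, montage, build_source_grid())

rec, _ = simulate_eeg(model, montage, SimulationConfig(seed=0))  # 2 s at 500 Hz, SNR 5
bads = ["C3", "Cz", "T8", "PO4"]
corrupted = rec.mark_bad(bads)

for name, est in {
    "NI": ni_interpolate(corrupted, montage),
    "SSI": ssi_interpolate(corrupted, montage),
    "RESIT": rereference(resit_interpolate(corrupted, leadfield), "average"),
}.items():
    mae, rae, r = interp_metrics(rec, est, bads)
    print(f"{name:5s}  mae = {mae:.3f} uV   rae = {rae:.3f}   mean r = {r:.3f}")
```

Output:

```
NI     mae = 2.689 uV   rae = 0.373   mean r = 0.921
SSI    mae = 3.144 uV   rae = 0.436   mean r = 0.901
RESIT  mae = 2.202 uV   rae = 0.305   mean r = 0.952
```

The estimators underneath (`NeighborInterpolator`,
`SphericalSplineInterpolator`, `ResitInterpolator`) follow the
scikit-learn `fit`/`transform` convention on `(n_times, n_channels)`
arrays and expose their fitted linear operators (`weights_`, `transfer_`,
`operator_`, `rank_`).

## Command line

```bash
resit simulate --montage-size 62 --signal rest --duration 10 \
      --out rec.h5 --out-montage montage.sfp
resit interpolate --data rec.h5 --montage montage.sfp \
      --bads Cz,T7 --method resit --output-ref avg --out fixed.h5
resit evaluate --data rec.h5 --montage montage.sfp \
      --fractions 0.02,0.1,0.25,0.5,0.85 --repeats 20 \
      --out-table results.csv --plot curves.png
```

Head model, source grid and interpolation defaults are configurable via
`--config config.yaml` (see `resit.config` for the schema).

## Benchmark

`run_assessment` implements a bad-channel injection protocol: on a clean
average-referenced recording, channels are declared bad at fractions
2%–85% of the montage — scattered uniformly or as one spatially adjacent
patch — each method reconstructs them over repeated draws, and the
reconstruction is scored against the recorded data by mean absolute error
(MAE), relative absolute error and mean per-channel Pearson r. On the
default simulator settings (62 channels, 10 dipolar sources, SNR 5,
20 seeds × 20 draws per cell), mean MAE in µV:

| fraction | RESIT scat. | SSI scat. | NI scat. | RESIT adj. | SSI adj. | NI adj. |
|---------:|------------:|----------:|---------:|-----------:|---------:|--------:|
| 2%       | 2.40        | 3.10      | 2.45     | 2.40       | 3.10     | 2.45    |
| 10%      | 2.46        | 3.17      | 2.59     | 2.48       | 3.48     | 2.83    |
| 25%      | 2.53        | 3.24      | 2.75     | 3.00       | 3.31     | 2.96    |
| 50%      | 2.77        | 3.55      | 3.20     | 3.04       | 3.04     | 3.00    |
| 85%      | 4.14        | 5.45      | 5.59     | 5.36       | 4.08     | 5.07    |

RESIT dominates in the scattered case at every fraction; in the adjacent
case all methods converge toward the sensor-noise floor once the patch
covers a quarter of the montage or more (see `docs/methods.md` for the
quantitative limits of the method).

## Reproduction

* `pytest -q tests/` runs the full suite, including end-to-end acceptance
  tests (the 20-seed benchmark above is recomputed; ~2 minutes). Three
  acceptance tests encode aspirational exact-recovery/dominance targets
  that the method does not meet and are expected to fail; the analysis is
  in `docs/methods.md`.
* `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  re-derives the source-grid configuration counts by classifying the grid
  dipoles at run time.
* `write_fixture_bundle(outdir)` writes a byte-reproducible simulation
  bundle (montage, 60 s resting recording, ERP epochs, JSON manifest).

All computations are deterministic given the seeds; the benchmark uses
`numpy.random.SeedSequence((seed, fraction_index, repeat))` per cell so
draws are paired across methods and reproducible in isolation.
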