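# spcct — multicolour K-edge imaging with photon-counting CT, in silico

Spectral photon-counting CT (SPCCT) detectors sort individual photons into
energy bins by pulse-height thresholds. Because heavy contrast elements —
iodine, gadolinium, gold — carry K absorption edges inside the diagnostic
energy range (33.2, 50.2 and 80.7 keV), five energy bins per ray are enough
to decompose the measured attenuation into up to four basis materials and
produce element-specific concentration maps from a single scan:
"multicolour" imaging. The open question this pipeline addresses is
quantitative: when two agents are *mixed in the same volume* and every
sample is prepared to the same conventional attenuation (~280 HU, the
CT-angiography level), how accurately can each agent still be quantified?

`spcct` is a tested simulation and quantification pipeline for that phantom
experiment. It covers, end to end:

* **Physics** — bundled mass-attenuation tables with K-edge handling,
  a filtered Kramers bremsstrahlung tube spectrum, ideal five-threshold
  detector binning, and the polychromatic bin-count forward model
  λᵢ(a) = Σ_E S(E)·exp(−Σ_b a_b (μ/ρ)_b(E)).
* **Phantom design** — a 13-cm polymer cylinder with 12 tube positions; the
  published tube concentrations as a bundled fixture, plus a calibrated
  solver that designs equal-attenuation (280 HU) mixture series under the
  pipeline's own beam.
* **Scan simulation** — exact chord-length forward projection and
  per-ray, per-bin Poisson counting noise (400 views × 256 detectors and
  10⁵ counts/ray by default; the full 2400-view protocol is a config change).
* **Decomposition** — per-ray maximum-likelihood inversion of the five
  counts into water/iodine/gadolinium/gold areal densities (damped Fisher
  scoring, vectorised over the sinogram), and the one-parameter
  water-equivalent thickness that defines the conventional image.
* **Reconstruction & analysis** — parallel-beam FBP, Gaussian
  post-smoothing, automatic circular ROIs, prepared-vs-measured regression,
  Bland–Altman agreement, cross-contamination RMSE, CNR and CNR slopes, and
  two-way mixed-effects ICC between unmixed and mixed measurements.

## Worked example

```python
from spcct.pipeline import default_config, run_study

res = run_study("IGd_mix", default_config(), seed=1)
rep = res["report"]
print(rep["conventional"]["mean_hu_tubes"])          # 280.8
for agent, blk in rep["per_agent"].items():
    r = blk["regression"]
    print(agent, round(r["slope"], 3), round(r["offset"], 3),
          round(r["r_squared"], 4))
# iodine 0.974 0.056 1.0
# gadolinium 0.984 0.068 0.9999
print(round(rep["water_pbs_roi"]["mean"], 1))        # 1000.6
```

Eleven tubes holding iodine–gadolinium mixtures, all designed to 280 HU,
are scanned with thresholds 30/51/64/72/85 keV, decomposed on a
water–iodine–gadolinium basis and reconstructed. The tubes are
indistinguishable on the conventional image (280.8 HU mean, ~1 HU spread)
yet both agents are recovered with near-unit slope and R² ≥ 0.999; the
water map reads the expected 1000 mg/mL in the pure-PBS tube.

The full analysis is scripted:

```bash
python analysis/01_design_phantoms.py            # calibrated tube designs
python analysis/02_run_studies.py --seed 1       # all five studies, ~1 min
python analysis/03_quantify.py                   # tables, ICC, figures
```

`03_quantify.py` writes `results/regression_table.csv` (slope, offset, R²,
RMSE, 95 % CI and CNR slope per image), cross-contamination and
conventional-HU tables, per-agent ICC, and the figure panels (regression,
Bland–Altman, CNR bars, colour-coded material-map montages).

Characteristic behaviour of the four-material gold–gadolinium study is
reproduced: mixing two K-edge agents costs contrast-to-noise (unmixed /
mixed CNR-slope ratios well above 1.3 for both agents) and the gadolinium
map stays more contrasted than the gold map, which has fewer photons
balanced around its 80.7-keV edge in a 120-kVp beam.

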