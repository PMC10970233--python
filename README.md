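# qfish3d

Quantitative analysis of telomeres imaged by 3D super-resolution
Q-FISH (fluorescence in situ hybridization with peptide-nucleic-acid
probes, recorded by STED-class nanoscopy as raw photon counts).

Telomere length and compaction are usually inferred from the
fluorescence of hybridized probes, but single-plane analyses miss most
telomeres and report biased brightness. `qfish3d` implements the full
3D alternative for researchers quantifying telomere biology in
cultured cells and tissue:

- **detect** — maxima-based 3D spot detection with descending-intensity
  segmentation and saddle-based peak merging on smoothed photon counts
  (background floor 10 counts, minimum size 10 voxels by default);
- **quantify** — per-spot orthogonal lateral line profiles at the
  brightest plane fitted with `y = a + (b − a)·exp(−(x − c)²/2d²)`,
  giving peak brightness `b`, `FWHM = 2√(2 ln 2)·d·px`, ellipsoid
  volume `(π/6)·FWHM_x·FWHM_y·FWHM_z̄`, integrated brightness
  `2π·b̄·d_x·d_y` and signal density (integral/volume);
- **calibrate** — DNA-origami brightness standards (17/34/60
  fluorophores) fitted with a weighted linear regression whose slope
  converts brightness to bound probe molecules, then to labeled bp
  (18 nt per (CCCTAA)₃ probe) and labeling efficiency;
- **stats** — nested (cell-within-condition) hierarchical tests on
  log10-transformed features, Gaussian/lognormal histogram fits and
  the extra-sum-of-squares F test;
- **trf** — mean telomere length from Southern-blot densitometry,
  `MTL = ΣNIᵢ / Σ(NIᵢ/MWᵢ)`, with log-linear ladder calibration;
- **simulate** — seed-deterministic generators (nuclei, cell-cycle
  experiments, origami fields, TRF smears) with exact ground truth.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate an interphase-like nucleus (90 telomeres, lateral σ 56 nm,
Poisson noise) and push it through the whole pipeline:

```python
import numpy as np
import qfish3d as q

cfg = q.SimulationConfig(n_spots=90, seed=1)
stack, truths, mask = q.simulate_nucleus_stack(cfg)
rec = q.quantify_nucleus(stack, mask, cell_id="cell01", phase="interphase")

ok = [f for f in rec.features if f.quality_flag != "rejected"]
fwhm = [0.5 * (f.fwhm_x_nm + f.fwhm_y_nm) for f in ok]
ib = [f.integrated_brightness for f in ok if f.integrated_brightness]
print(len(rec.features), "spots;", len(ok), "quantified")
print("mean lateral FWHM: %.1f nm" % np.mean(fwhm))

curve = q.fit_calibration(
    [q.CalibrationPoint(n, n * 6.0606, 5.0, 100) for n in (17, 34, 60)]
)
gm = np.exp(np.mean(np.log(ib)))
probes = q.brightness_to_probes(gm, curve)
print("factor %.4f; %.1f probes -> %d bp; efficiency %.1f%%" % (
    curve.slope, probes, q.probes_to_bp(probes),
    q.labeling_efficiency(q.probes_to_bp(probes), 18_900),
))
```

Output:

```
90 spots; 90 quantified
mean lateral FWHM: 130.3 nm
factor 0.1650; 163.1 probes -> 2936 bp; efficiency 15.5%
```

All 90 simulated telomeres are recovered; the mean lateral FWHM
(130 nm) matches the generator's 132 nm set-point within the fit
noise; the calibration slope converts the geometric-mean integrated
brightness into ~163 bound probes, i.e. ~2.9 kb of labeled sequence —
about 16% of an 18.9 kb mean telomere, the expected minority coverage
of PNA labeling.

The same stages are scriptable from the shell via the `qfish3d`
console command (`simulate`, `detect`, `quantify`, `calibrate`,
`convert`, `stats`, `trf`), exchanging TIFF stacks, JSON masks/curves
and CSV tables.

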