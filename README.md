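# cdltools

Cochlear duct length (CDL) estimation and method comparison for cochlear
implant electrode planning.

Choosing an electrode array length requires knowing how long the
individual cochlear duct is, but the duct can only be measured indirectly
from pre-operative CT imaging. Several estimators are in clinical use and
they disagree systematically. This package implements the whole
comparison workflow as a reusable, tested library:

* **3D spline method** — rigid alignment of a segmented lateral-wall (LW)
  point cloud into the modiolar frame (spiral axis = z, round window at
  angle 0), angular unwrapping, and arc length of an interpolating cubic
  spline;
* **A-value method** (Escudé) — `LW = 2.62 · A · ln(1 + θ/235)` with the
  basal-turn diameter A in mm and the insertion angle θ in **degrees**
  (θ = 900° ≙ 2.5 turns ≙ 100 % coverage, where the log term is 1.57);
* **elliptic-circular method** (otosurgical planning software) —
  `CDL_LW = pBTL(θ) · [1.18(A−0.7) + 2.69(B−0.7) − √(0.72(A−0.7)(B−0.7))]`
  from the basal-turn diameter A and width B, with the organ-of-Corti
  (×0.9) and voxel-resolution (×10/9) corrections;
* **insertion-angle reference** — `CDL = 31.5 mm · 900° / IA`, inverting
  the coverage relations `CC = 31.5/CDL · 100 %` and `IA = 9 · CC` for
  the measured insertion angle of a fully inserted 31.5 mm array;
* **insertion simulation** — laying an electrode along the wall-offset
  trajectory and reading contact angles in the idealized projection view;
* **comparison statistics** — per-method summary tables, one-way ANOVA
  with Dunnett many-to-one contrasts against the reference (deterministic
  multivariate-t integration), Pearson and Hotelling–Williams dependent
  correlation tests, and two-rater ICC(2,1) reliability with
  poor/fair/good/excellent banding;
* **synthetic cochleas** — a parametric spiral family with analytic
  ground truth (CDL(θ), A, B, H), CT-like voxel phantoms with threshold
  segmentation, and per-method/per-rater measurement error models, so the
  whole pipeline runs end-to-end against known truth.

## Worked example

```python
from cdltools import (make_spiral, sample_point_cloud, align_to_modiolar_frame,
                      fit_lateral_wall_spline, measure_A, measure_B, measure_H,
                      cdl_escude_full, cdl_elliptic, BasalTurnMetrics,
                      predict_cc, simulate_insertion, ElectrodeArray,
                      cdl_reference_from_ia)

curve, truth = make_spiral()                       # synthetic cochlea
cloud = sample_point_cloud(curve, n=500, noise_sd=0.1, seed=0)
aligned = align_to_modiolar_frame(cloud)
spline = fit_lateral_wall_spline(aligned, denoise_window_mm=1.0)

cdl_3d = spline.total_arc_length()
A, B = measure_A(aligned, spline), measure_B(aligned, spline)
cdl_a = cdl_escude_full(A)
cdl_sw = cdl_elliptic(BasalTurnMetrics(A, B))
cov = predict_cc(cdl_3d)
```

prints (via f-strings, exactly these numbers at seed 0):

```
ground-truth CDL 42.82 mm, A 8.60 mm
spline CDL      42.93 mm
A 8.64 mm  B 7.80 mm  H 4.06 mm
A-value CDL     35.63 mm
elliptic CDL    37.44 mm
coverage 73.4 %  predicted IA 660 deg
```

The spline method recovers the true duct length within 0.3 % despite
0.1 mm click jitter; the two formula-based estimators underestimate it by
several mm — the systematic bias the comparison statistics quantify. A
simulated insertion of a 31.5 mm array on the same cochlea gives an
insertion angle of 602° (contact span) / 650° (tip), from which the
reference formula reconstructs a CDL estimate.

## Command line

```sh
cdltools --seed 7 --outdir run simulate --n 20      # synthetic cohort
cdltools --outdir run estimate --clouds run --table run/measurements.csv
cdltools --outdir run insert --clouds run
cdltools --outdir run compare --table run/measurements.csv
```

`compare` writes `report.json` / `report.md` with the summary table,
ANOVA, Dunnett contrasts, correlations and ICC banding;
`--correction 10over9` applies the resolution correction before
comparison.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, through the package's own functions, the worked-example
quantities that are derivable from the study's published summary numbers:
the coverage implied by the mean reference insertion angle, the
many-to-one mean CDL differences between the published per-method means,
and the full-insertion logarithmic constant of the A-value relation. It
also runs a seeded synthetic cohort end-to-end as a smoke test before
reporting.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
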