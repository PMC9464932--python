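# syctqa — dosimetric QA of bulk-density synthetic CTs

On a 1.5-T MR-Linac, the daily adapted plan is not calculated on a CT but on
a *synthetic CT* (syCT) produced by **bulk density assignment**: every
contoured structure is forced to a single relative electron density (ED,
water = 1), with overlaps resolved by a priority order. That approximation
is usually harmless — and occasionally it is not: an inhomogeneous lung
target collapsed onto one mean ED, a whole-brain contour that outranks the
skull and erases the bone, a positioning plate nobody contoured. `syctqa`
implements the pre-treatment audit that catches these cases: it rebuilds the
*ideal* syCT from the reference plan itself, compares the dose recalculated
on it against the reference dose, and applies clinical agreement rules.

The toolkit is aimed at medical physicists commissioning or running
MR-guided adaptive workflows, and at anyone who needs an auditable,
scriptable DVH/gamma comparison between two DICOM-RT dose distributions.

## What it computes

**Ideal syCT.** Each voxel's ED is the mean ED (from a piecewise-linear
HU→ED calibration) of the highest-priority structure covering it, else a
background value. Contours are rasterized by the voxel-center even–odd
rule, so holes (e.g. a skull annulus) work as in a TPS.

**DVH parameters.** From the raw sorted voxel doses: Dmax, Dmean,
D_y% / D_ycc (minimum dose to the hottest y % / y cc), V_xGy (% of volume
receiving ≥ x Gy) and V<sub>Dpre</sub> (% of the target covered by the
prescription dose). Differences are reported as ∇Vx in %-volume and ∇Dy
in Gy.

**3D global gamma.** For each reference voxel *r*,

    γ(r) = min over e of sqrt( |e − r|²/δ² + (D_eval(e) − D_ref(r))²/ΔD² )

with δ the distance-to-agreement (mm) and ΔD the dose criterion as a
percentage of the global normalization dose (the reference maximum). A
voxel passes when γ < 1; pass rates are reported per structure at 3 %/3 mm
and 2 %/2 mm over voxels above a low-dose cutoff (default 10 %).

**Verdict.** A plan pair is in agreement when the body pass rate at
3 %/3 mm exceeds 99 % *and* every target DVH point agrees within
1.5 %-volume or 1 Gy *and* every listed V-/D-parameter delta stays below
1.5 % / 1 Gy. Advisory troubleshooting findings (`INHOMOGENEOUS_STRUCTURE`,
`PRIORITY_SHADOWING`, `ED_MISMATCH`, `UNASSIGNED_HARDWARE`) diagnose *why*
a comparison failed; they never change the verdict.

Because patient DICOM data cannot ship with the package, `syctqa.phantom_fixtures`
generates complete synthetic cases (CT series, RTSTRUCT, paired RTDOSE) with
a deliberately simple broad-beam exponential-attenuation surrogate dose
model whose one guaranteed property is monotone sensitivity to density —
exactly what the QA step must detect.

## Worked example

Generate the inhomogeneous-lung failure case and run the full QA step:

```bash
$ syctqa phantom make --kind lung_inhomogeneous --seed 7 --out demo
wrote lung_inhomogeneous fixture (seed 7) to demo

$ syctqa qa run --config demo/config.yaml
verdict: FAIL
  FAILED Target: ΔVDpre@23.75Gy < 1.5 % (value 3.53 %)
  finding [INHOMOGENEOUS_STRUCTURE] Target: ED std 0.407 exceeds 0.15 (range 0.17–1.10); a single bulk ED cannot represent this structure
```

The exit code is 1 (FAIL; 0 = PASS, 2 = error) and `demo/report.json`
carries the full audit trail. The prescription coverage of the target moved
by 3.5 %-volume (96.5 % on the reference CT vs 100.0 % on the syCT): the
half-aerated, half-solid target was flattened to its mean ED, so the
recalculated dose no longer sees the internal density gradient. The gamma
analysis narrows the disagreement to the target region:

```
3%/3mm: Body 99.9  Target 97.9  Lung 99.8  Cord 100.0  Organ 100.0   (%)
2%/2mm: Body 97.8  Target 78.2  Lung 95.8  Cord 100.0  Organ 100.0   (%)
```

while a `concordant` fixture passes with all rates at 100 % and parameter
deltas below 0.1 Gy / 0.5 %. The same analyses are available from Python
(`make_case`, `run_qa`, `gamma_index`, `compare_plans`, …) and as separate
CLI stages (`syctqa build`, `syctqa dvh compare`, `syctqa gamma`).

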