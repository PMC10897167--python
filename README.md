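# saxstrain

Nanoscale bone-strain analysis from synchrotron SAXS/WAXD during in situ
tensile testing, with whole-bone three-point-bend mechanics and the factorial
statistics used to compare experimental groups — all exercisable end-to-end
on synthetic data with known ground truth.

## The scientific problem

Bone is a composite of collagen fibrils (axial period ≈ 67 nm) and
hydroxyapatite mineral (the (002) lattice spacing ≈ 3.44 Å). During a tensile
test at a synchrotron beamline, each phase produces a Bragg ring — collagen
in the small-angle (SAXS) regime, mineral in the wide-angle (WAXD) regime —
at momentum transfer `q = 2π/d`. As load is applied, the ring shifts: the
**material strain** of a phase is `ε = (d − d₀)/d₀`, with `d₀` the unloaded
reference. Optical markers on the specimen give the bulk **tissue strain**.
The regression slope of material strain on tissue strain is the fraction of
tissue deformation carried by that phase, and the **slope sum**
(collagen + mineral) near 1 diagnoses a stable composite — a deficit points
to unobserved strain pathways such as inter-fibril sliding. Group slopes are
compared with the extra sum-of-squares F test; fibril alignment is tracked by
the second Legendre orientation parameter

    P2 = ⟨ (3 cos²χ − 1)/2 ⟩_{I(χ) sin χ},

which is 1 for perfect axial alignment, 0 for isotropy, −0.5 for transverse.

Because raw synchrotron frames of this kind are rarely deposited, the package
includes a first-class generator that emulates the acquisition — Poisson-noisy
ring patterns on a Pilatus-class detector, 0.5 s exposures every 5 s at
10 keV under a 30 kGy cumulative dose cap, exact marker-encoded strain ramps,
bend curves, and factorial outcome tables — so every stage of the analysis is
testable against known truth.

## What is in the box

| module | contents |
| --- | --- |
| `saxstrain.simulate` | ground-truth generators: calibrant frames, tensile experiments, bend curves, outcome tables |
| `saxstrain.geometry` | detector geometry, beam-center/distance calibration (silver behenate), radial & azimuthal cake integration |
| `saxstrain.peaks` | Bragg-peak fitting, `d = 2π/q` strain series, P2 orientation |
| `saxstrain.pairing` | marker-gauge tissue strain, time-matching, dose ledger, specimen exclusion rules |
| `saxstrain.regression` | pooled strain-slope OLS, extra-SS slope F test, slope-sum diagnostic |
| `saxstrain.bending` | three-point-bend metrics, hollow-ellipse MOI, material properties |
| `saxstrain.stats` | one-/two-way ANOVA, Fisher's LSD, Bonferroni alpha families |
| `saxstrain.pipeline` | end-to-end orchestration (frames → group slope) |

## Worked example

```sh
python examples/02_collagen_strain_recovery.py
```

```
generating collagen slope: 0.7482
recovered group slope:     0.7319 +/- 0.0194 (95% CI 0.6936..0.7702, n = 180 points, 3 specimens)
```

Three specimens are simulated with the collagen phase programmed to carry
74.82 % of the tissue strain; the full pipeline (calibration from a standard,
sector integration, per-frame peak fits, strain referencing, marker strain,
time-matching, pooled OLS) estimates the group slope, and its 95 % CI covers
the generating value. The other examples cover calibration
(`01_calibrate_and_integrate.py`), slope comparison and the slope-sum
diagnostic (`03_slope_comparison_and_sum.py`), bend mechanics
(`04_three_point_bend.py`), and the ANOVA/LSD/Bonferroni framework
(`05_group_statistics.py`), each printing the numbers it computes and what
they mean.

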