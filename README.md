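# vasomech

Active-stress constitutive modelling of vascular smooth muscle cell (VSMC)
contraction in arteries: six active stress formulations embedded in thick-
and thin-walled incompressible cylinder mechanics, with closed-form active
load-bearing terms, analytic limit-point (fold) instability conditions,
instability-region detection, and parameter estimation from sparse (single
contraction point) or dense (paired pressure-diameter curve) data.

## Model families

| family tag        | circumferential active Cauchy stress             |
|-------------------|--------------------------------------------------|
| `constant_cauchy` | `Tc` (constant in the current configuration)     |
| `constant_1pk`    | `Ti * lam_t` (constant 1st Piola-Kirchhoff)      |
| `constant_2pk`    | `Tr * lam_t^2` (constant 2nd Piola-Kirchhoff)    |
| `rachev`          | `TRv * lam_t * f(lam_t)`, bell-shaped `f`        |
| `zulliger`        | `S1 S2 TZr (lam_t lam_pre - 1)`, gated ascending |
| `franchini`       | `S1 2 TFr1 lam_t^2 [1 + a1 E - b1 E^m1]`         |

The passive wall is a four-fibre-family hyperelastic law (isotropic term
plus exponential fibre families at axial, circumferential and +/- diagonal
orientations). Pressures are kPa internally; mmHg accepted at I/O
(1 mmHg = 0.133322 kPa). Lengths are mm.

## Library quick start

```python
from vasomech import (
    VesselGeometry, DeformationState, ConstantSecondPKModel,
    total_pressure, find_instability_regions, fit_single_point,
)
from vasomech.fixtures import make_mouse_like_vessel
from vasomech.estimation import ContractionDatum, imposed_preset

geom, passive, lam_z = make_mouse_like_vessel()
P = total_pressure(geom, DeformationState(0.6, lam_z), passive,
                   ConstantSecondPKModel(Tr=30.0))          # kPa
datum = ContractionDatum(pressure_mmHg=90.0, lambda_z=lam_z,
                         diameter_reduction=0.29)
fit = fit_single_point(geom, passive, datum, "constant_2pk")
```

## Command line

A single `vasomech` entry point with subcommands:

```sh
vasomech simulate  --out curve.csv                      # relaxed P-d curve
vasomech simulate  --model '{"family":"constant_2pk","params":{"Tr_kPa":30}}' --out c.csv
vasomech stability --model '{"family":"constant_cauchy","params":{"Tc_kPa":50}}' --out stab.json
vasomech synth     --model '{"family":"rachev","params":{"TRv_kPa":70,"lambda_m":1.3,"lambda_0":0.3}}' --outdir data/
vasomech gamma-exp --relaxed data/relaxed.csv --contracted data/contracted.csv --out gamma.csv
vasomech fit-curve --samples gamma.csv --family rachev --out fit.json
vasomech fit-point --family constant_2pk --out fit.json
vasomech case-study --config config.json --outdir out/
```

Curve CSVs use columns `pressure_mmHg`, `outer_diameter_mm` and/or
`normalised_outer_diameter`; active-pressure CSVs use
`normalised_outer_diameter`, `gamma_act_kPa`. Configs and fit results are
JSON; every result embeds the config hash and seed.

## Fixtures (synthetic stand-ins)

`vasomech.fixtures` generates all data needed by the test suite:

* `make_mouse_like_vessel()` — a thick-walled vessel with a frozen passive
  parameter set whose inflation response at axial stretch 1.60 has the
  physiological shape of a murine descending thoracic aorta. These
  constants **emulate** the original animal's behaviour; they are not the
  published supplementary parameter values (which are not redistributed
  here), so sparse-fit stress estimates on this fixture are stand-in
  values, not reproductions of the published table.
* `generate_contraction_datum()` — exact forward-simulated contraction data
  for recovery round trips.
* `generate_cox_like_curves()` — paired relaxed/contracted membrane curves
  sampled every 20 mmHg over 0-240 mmHg, with optional seeded pressure
  noise (noise is placed on the measured pressure axis).

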