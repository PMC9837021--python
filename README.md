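# fibermech

Multiscale micromechanics of plant fibers: predicting the axial Young's
modulus and tensile elastic limit of technical fibers (flax, hemp, jute,
coir, bamboo, …) from their physicochemical composition, by upscaling the
properties of the crystalline cellulose nanofibril — axial modulus
167.8 GPa, axial tensile strength 2.3 GPa — through four representative
volume elements:

    polymer network  →  cellulose microfibril  →  cell wall  →  technical fiber
    (self-consistent)   (Mori–Tanaka,             (Mori–Tanaka,  (Mori–Tanaka,
     5 spherical         aligned infinite          azimuth-       cylindrical
     phases)             cylinders)                averaged,      lumen voids)
                                                   tilted by MFA ϑ)

All fourth-order tensor algebra is carried out on 6×6 Kelvin–Mandel
matrices; Hill polarization tensors for spheres and infinitely long
cylinders in arbitrary (an)isotropic media are evaluated by numerically
converged quadrature. The axial modulus is `E_fib = 1/D_fib,LLLL`; the
elastic limit follows from elasto-brittle nanofibril failure,
`Σ_ult = σ_ult_NF / σ_NF,ll(Σ=1)`, with the nanofibril axial stress
obtained by downscaling a unit macroscopic tension through the cached
strain concentration operators.

The package ships a database of 26 common plant fibers (bast, grass,
leaf, fruit/seed and straw types) with literature min/average/max values
of cellulose/hemicellulose/lignin/pectin/ash mass fractions, cellulose
crystallinity, microfibril angle and fiber density, and builds
unfavorable/average/favorable prediction scenarios from them. See
`docs/methods.md` for the model description, numerical choices and known
limitations — notably the behavior of the strength prediction above
microfibril angles of ~30°.

Intended for researchers in natural-fiber composites and plant
biomechanics who want transparent, composition-based estimates of fiber
stiffness and strength, or a base layer for biocomposite models.

## Worked example

Predict the three scenarios for flax:

```sh
$ fibermech predict --fiber Flax
name,type,scenario,E_fib_GPa,Sigma_ult_MPa,rho_cw_g_cm3,f_lum,theta_deg,...
Flax,bast,min,50.237582132004086,707.2013990184118,1.4838773376436483,0.0700039922495227,10.0,...
Flax,bast,avg,84.6114399130359,1167.433718226097,1.4838773376436483,0.0700039922495227,6.0,...
Flax,bast,max,117.55556698197874,1616.5186790387165,1.4838773376436483,0.0,5.0,...
```

Reading this: flax's average composition (73 % cellulose at 78 %
crystallinity, 6° microfibril angle, 7 % lumen porosity, cell-wall
density 1.48 g/cm³) yields an axial modulus of 84.6 GPa and a tensile
elastic limit of 1167 MPa. The min/max rows combine the unfavorable and
favorable ends of the reported property intervals (e.g. 10° vs 5° angle,
81 % cellulose and zero lumen porosity in the favorable case), spanning
50–118 GPa and 707–1617 MPa — the interval against which scattered
single-fiber test data should be compared.

The same from Python:

```python
import fibermech as fm

db = fm.load_fibers()
scenario = fm.build_scenarios(db["Flax"])["avg"]
h = fm.predict_stiffness(scenario)
print(h.E_fib)                      # 84.6114399130359   [GPa]
print(fm.tensile_elastic_limit(h))  # 1167.433718226097  [MPa]
```

Other entry points: `fibermech predict` (all 26 fibers ×
min/avg/max), `fibermech sweep --fiber Flax --param mfa` (sensitivity of
the prediction to one property over its reported interval, with an
envelope band from co-varying the remaining properties), `fibermech
tables` (the derived cell-wall density / lumen porosity / volume-fraction
tables), and `fibermech validate` (per-fiber predicted intervals, with an
optional experimental-interval CSV and comparison figure). Numerical and
physical knobs (azimuth quadrature order, self-consistent tolerance,
nanofibril strength, pectin Poisson assumption, the orientation-average
normalization variant) live in `ModelConfig` and can be set from a plain
`key=value` config file via `--config`.

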