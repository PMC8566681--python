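# oxishelf

Shelf-life estimation for cold-pressed (expeller-pressed) seed oils from
accelerated oxidation tests and fatty-acid composition.

Unrefined pressed oils keep the minor constituents that refining removes —
free fatty acids, pigments, tocopherols — so their oxidative stability, and
hence their safe storage time, varies widely and is rarely labelled.
Accelerated oxidation instruments (OXITEST-type reactors) measure stability
by sealing a few grams of oil under ~800 kPa of oxygen at an elevated
temperature and recording the headspace pressure: the **induction period
(IP)** is the time at which oxygen consumption suddenly accelerates.
`oxishelf` implements the full desk side of that workflow for food-lipid
chemists and QC labs:

1. **Two-tangent IP detection** — the IP is the intersection of a baseline
   tangent (fitted over the slow pre-oxidation decay) with the tangent at
   the steepest-descent point of the smoothed pressure curve.
2. **Zero-order log-linear kinetics** — across test temperatures the IP
   follows the OSI-convention law (universally called "Arrhenius" in this
   field, with temperature in plain °C):

   ```
   log10 IP = Log IP0 − k0 · T
   ```

   fitted by OLS to IPs measured at ≥3 temperatures (typically 70/90/100 °C),
   then evaluated at ambient temperature (20 or 25 °C) and converted from
   hours to days to give the predicted shelf-life.
3. **Composition scores** — SFA/MUFA/PUFA class sums and the calculated
   iodine value (AOCS Cd 1c-85 weighting of unsaturated fatty-acid
   percentages).
4. **Prediction models** — a Pearson correlation screen of shelf-life
   against label-available properties, and grouped multiple regression
   `y = b0 + b1·X1 + b2·X2` where `X1` is a fatty-acid class (UFA% works
   best) and `X2 ∈ {0, 1}` separates two oil families with offset but
   parallel shelf-life/UFA lines (a grouping attributed to tocopherol
   profiles, supplied as data).
5. **A seeded curve simulator** — logistic-consumption pressure curves with
   a closed-form ground-truth IP (`t_c − 2/s`), so the detector and the
   kinetics chain are testable end to end without an instrument.

The package ships the published reference tables for ten expeller-pressed
oils (almond, black sesame, camellia, golden linseed, peanut, pecan, pine
nut, pumpkin seed, sunflower, walnut) and a `reproduce-paper` workflow that
recomputes every derived number from them.

## Worked example

Fit the kinetic law to a real almond-oil accelerated series and predict its
ambient shelf-life:

```python
>>> import oxishelf as ox
>>> ms = [ox.IPMeasurement(ip=ip, temperature=t)
...       for ip, t in [(85.00, 70), (20.62, 90), (8.83, 100)]]
>>> ox.fit_kinetics(ms)
KineticFit(log_ip0=4.2126, k0=0.0325, r_squared=0.9979, n_points=3,
           temperatures_used=(70.0, 90.0, 100.0))
>>> ox.extrapolate_shelf_life(ox.fit_kinetics(ms), 25.0)
ShelfLifeEstimate(temperature=25.0, ip_hours=2512.4648813287704, days=105)
```

The intercept `Log IP0 = 4.2126` (log10 hours) and rate constant
`k0 = 0.0325` per °C describe how fast the induction period shrinks with
temperature; the line explains 99.8% of the variance. Evaluated at 25 °C
the law predicts an IP of ~2512 h, i.e. a shelf-life of **105 days** in
dark ambient storage.

The same chain runs on simulated instrument data — generate noisy curves
whose true IPs follow that law, detect, refit, extrapolate:

```python
>>> law = ox.KineticLaw(4.2126, 0.0325)
>>> curves = ox.simulate_temperature_series(
...     law, [70, 90, 100], ox.CurveParams(noise_sd=0.5, seed=7))
>>> res = ox.pipeline_shelf_life(curves, ambient=25.0)
>>> [m.ip for m in res.measurements], res.fit.log_ip0, res.estimate.days
([86.63, 19.38, 9.26], 4.2043, 103)
```

Detection recovers the three IPs to a fraction of a percent and the
round-trip shelf-life (103 days) lands within 2% of the generating law's
closed-form 104.7 days.

From the shell the equivalent subcommands are `oxishelf simulate`,
`detect-ip`, `fit-kinetics` and `predict`; `oxishelf reproduce-paper`
recomputes the complete published numeric surface (iodine values, kinetic
parameters, shelf-lives, correlation screen, regression models) from the
packaged tables and annotates each cell match/mismatch at print precision.

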