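# postbuffer

Address-weighted postcode-buffer land-cover exposure for small statistical
geographies.

## The problem

Environmental-health studies routinely attach land-cover exposure (greenspace,
woodland, built-up area, ...) to small census geographies such as English
LSOAs by computing the percentage cover of each class over the whole unit
polygon. Because these units are built to hold similar populations, their
land area varies enormously between urban and rural settings (roughly 0.02 to
several hundred km²). In a large rural unit most of the polygon may be far
from anyone's home, so the whole-unit percentage misrepresents what residents
actually live next to — a classic source of exposure misclassification.

`postbuffer` implements an alternative that anchors exposure to where people
live, using only openly structured inputs: postcode point locations, the
number of domestic delivery addresses per postcode (a population-distribution
proxy), a classed land-cover polygon map, and the unit boundaries.

## The two methods

For land-cover class *c* and statistical unit *u*:

- **Typical method** — percentage cover over the whole unit polygon:

  `T_u(c) = 100 · area(u ∩ c \ X) / (area(u) − area(u ∩ X))`

  where `X` is the out-of-country exclusion layer (e.g. land across the
  national border that buffers can reach). Sea and estuary classes stay in
  the denominator; only `X` is removed.

- **Proposed method** — buffer each postcode point *p* in the unit by
  *r* = 300 m, compute its fractional covers
  `f_p(c) = area(B_p ∩ c \ X) / (area(B_p) − area(B_p ∩ X))`,
  then average within the unit weighted by domestic delivery counts `w_p`:

  `P_u(c) = 100 · Σ_p w_p f_p(c) / Σ_p w_p`

  The 300 m radius matches common accessible-greenspace policy targets
  (≈ 5-minute walk). Buffers cross unit boundaries, so a unit is credited
  with land cover its residents live beside even when it lies outside the
  polygon — and conversely, land far from any home stops contributing.

The comparison suite contrasts the two per class with the two-sample
Kolmogorov–Smirnov test, Kendall's tau-b (robust to the many tied zeros in
habitat covers), and Mann–Whitney U stratified by unit size class
(logarithmic bins, default edges 0.5 / 5 / 50 km²), region, and urban/rural
status. Reported differences are always `typical − proposed`.

Land-cover inputs are first merged into a non-overlapping composite:
habitats > estuaries > exclusion > a derived sea ring (land buffered outward
by 500 m, minus land), with any remaining gap kept as an explicit `residual`
class so every row sums to 100.

## Worked example

Everything is testable without licensed national data: the `synth` command
generates a landscape, units and postcodes with known ground truth.

```sh
postbuffer synth --preset urban-rural --seed 42 --out demo
postbuffer run --config demo/config.yml
```

which prints

```
wrote scene + config to demo (164 units, 405 postcodes)
done: 164 proposed rows, 164 typical rows, 6 classes compared -> demo/out
```

The scene has square units whose areas grow geometrically west→east
(emulating the urban→rural size gradient), a striped multi-class landscape
underneath, and an out-of-country strip along the western edge.
`demo/out/proposed.csv` then starts

```
unit_id,missing,total_weight,water,improved grassland,built-up areas and gardens,...
b0r000c000,0,7,0.000000,45.108013,47.493333,...
```

— unit `b0r000c000` has 7 domestic delivery addresses across its postcodes,
whose 300 m surroundings are ~45% improved grassland and ~47% built-up area.
`demo/out/report/per_class.csv` holds the method comparison, e.g.

```
class,n,ks_stat,ks_p,tau,tau_p,tau_stars
water,164,0.152439,0.0395763,0.851749,1.20286e-41,***
improved grassland,164,0.219512,0.000597652,0.753114,1.62228e-30,***
```

so for improved grassland the two methods' distributions differ
(KS D = 0.22, p < 0.001) while still ranking units very similarly
(tau-b = 0.75). `report/stratified.csv` adds the Mann–Whitney tests and
median `typical − proposed` differences per size class, region, and
urban/rural stratum, and `out/manifest.json` records the config hash, seed,
and bookkeeping counts (unusable postcodes, missing units, repaired
geometries) so a run can be audited and reproduced byte-for-byte.

Individual stages are also available: `postbuffer preprocess`, `propose`,
`typical`, and `compare` (see `--help`).

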