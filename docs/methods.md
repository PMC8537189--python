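# Methods

## Measurement model

A study comprises species, each with three leaf batches exposed for a known
period (default 7 d). Each batch is eluted in two wash steps — deionized
water with brushing (surface pool, SPM), then chloroform (in-wax pool,
WPM) — and each eluate passes a 10 → 2.5 → 0.1 µm membrane cascade.
Cascade semantics are fixed: the 10 µm filter holds PM>10, the 2.5 µm
filter PM2.5–10, the 0.1 µm filter PM0.1–2.5, and the final filtrate's
total dissolved solids (TDS) is the soluble fraction (DPM for water, OPM
for chloroform). Totals (SPM, WPM, total PM) are always derived sums of
the eight cells, never stored, so fraction closure holds by construction.

**Filter mass.** Each membrane is weighed several times before and after
filtration; the PM mass is mean(loaded) − mean(tare). Replicates are
aggregated by the arithmetic mean. A negative difference within the QC
tolerance (default 0.05 mg, the precision class of a 0.1 mg analytical
balance) is clamped to zero with a warning; a larger negative difference is
a data error and is rejected, not silently truncated.

**Soluble mass.** DPM and OPM are TDS concentration × eluate volume. The
same formula is applied to both wash steps. Note a physical caveat: TDS by
conductivity is well defined for aqueous eluates; for the chloroform eluate
conductivity is a doubtful proxy, and the identical treatment here follows
the laboratory protocol being modelled rather than an endorsement of it.
Note also a nominal mismatch: TDS is conventionally defined against a 2 µm
filter, whereas the cascade's final membrane is 0.1 µm; the soluble
fraction is therefore *operationally* "whatever passes 0.1 µm".

**Needle area.** Conifer batches report needle length L (m), count n and
mean displaced volume V′ (m³) instead of a scanned area; the total surface
area is A = 2L(1 + π/n)·√(nV′/(πL)), the displaced-volume formula for
cylinder-like needles (the sheet this was transcribed from prints the
formula with its radical lost; the form used here is the dimensionally
consistent reading, yielding m²). Broadleaf areas are inputs from scans
and are used exactly as provided ("as-measured"); no one-sided/total
convention is imposed.

**Aggregation.** Batch masses are normalised to densities (mg/m²) first
and then averaged across a species' batches with equal weight. Batches
differ in leaf count and area, so normalise-then-average is the defensible
order; weighting by area would let large batches dominate.

## Surface free energy

Owens–Wendt with two probe liquids: water (γ, γᵖ, γᵈ = 72.8, 51.0,
21.8 mJ/m²) and diiodomethane (50.8, 2.3, 48.5), both overridable. Per
liquid, γ_l(1+cos θ)/2 = a√(γ_lᵖ) + b√(γ_lᵈ) with (a, b) = (√γ_sᵖ, √γ_sᵈ);
the 2×2 linear system is solved exactly and the roots squared. Angles are
degrees at the API boundary, radians internally. The solve uses the mean
angle per species (per-replicate solving would propagate droplet noise
nonlinearly through cos θ). A marginally negative root — which occurs for
nearly apolar, highly non-wettable surfaces such as dense wax-crystal
leaves — is clamped to zero and flagged rather than re-fitted under a
nonnegativity constraint: the clamp is transparent, and the affected
component is at the edge of the physical domain where the two-liquid
system is barely determined. Wettability classes follow the usual contact
angle conventions: <90° wettable, 90–130° non-wettable, >130° highly
non-wettable.

On the built-in reference table the solver reproduces all twenty published
(γᵖ, γᵈ, γ) rows to within ±0.15 mJ/m² of the one-decimal printed values;
the single clamped species (TrRe) prints γᵖ = 0.1 where the unconstrained
root is −0.001² — not reproducible exactly from the printed angles, and
excluded from the component-level reproduction test for that reason.

## Retention efficiency

Only the surface pool enters efficiency: in-wax PM is not removed by rain
or wind, so it saturates rather than renews (the inventory still reports
WPM masses and proportions). AE_leaf = density / exposure time;
AE_plant = AE_leaf × LA with LA = LAI·πD²/4 from the leaf area index and
crown diameter; AE_land = AE_leaf × LAI. Exposure time is a batch
attribute, not a global constant, so other exposure designs re-use the
code unchanged. Internally everything is full precision; one-decimal
rounding happens only at report time. Rankings sort descending with
alphabetical tie-breaks.

A consistency identity worth noting: AE_land/AE_leaf must be one constant
(the LAI) across all five fractions of a species, and AE_land/AE_plant =
4/(πD²). On the reference table, printed at one decimal, the ratio is
constant within 1.5% except where a fraction's printed value is small
enough that half-ULP rounding dominates (e.g. a leaf value of 1.0 carries
±2.5% rounding by itself); the shipped consistency test allows exactly
that rounding margin on top of 1.5%, computed per cell as 0.05/leaf +
0.05/land.

## Statistics

The replication unit is the batch (three per species) — pseudo-replication
relative to trees is inherited from the sampling design and acknowledged,
not corrected. One-way fixed-effects ANOVA (scipy) with Tukey HSD
(studentized range, scipy; cross-checked in the test suite against
statsmodels) at α = 0.05. Correlations are Pearson by default with OLS
slopes. Capacity clustering is K-means (scikit-learn, Lloyd's algorithm,
best of 50 restarts) with k = 3 on the per-species density profile: the
eight inventory cells plus total PM, standardized to zero mean / unit
variance — without standardization the coarse >10 µm fraction, an order of
magnitude larger than the fine fractions, would dominate the distance.
Cluster labels are renumbered so cluster 1 has the smallest mean total PM
and cluster 3 the largest; the default seed 20181218 (the reference
campaign's sampling date) and restart count live in the run config, so
clustering is reproducible by construction. The exact feature scaling
behind the published cluster column is not documented at the source, so
published labels are a qualitative comparison only, not a reproduction
target.

## Synthetic-data generator

The generator emulates the complete measurement record of the reference
campaign from known truth, with these default study conditions:

- 20 species × 3 batches, 7 d exposure, batch leaf areas U(0.04, 0.12) m²;
- three capacity tiers assigned round-robin; total PM density ~
  N(tier mean, 140) mg/m² with tier means (500, 1200, 1900) — successive
  means are five within-tier SDs apart, matching the separation under
  which tier recovery is asserted, and spanning the density range implied
  by the reference efficiencies (≈160–1200 mg/m² of SPM over 7 d);
- composition shares drawn uniformly from the campaign's reported ranges:
  SPM 44.9–66.9% of total PM, DPM 12.9–22.1%, SPM fine 1.4–3.8%, SPM mid
  3.6–9.3%, OPM 1.2–8.8%, WPM fine 0.7–3.8%, WPM mid 2.1–7.1%; each wash
  step's >10 µm share is the remainder, so shares sum to one exactly (the
  config validator rejects range combinations that could go negative);
- surface energy coupled positively to capacity — γᵖ = 12 + 7z, γᵈ =
  25 + 3z (plus small Gaussian jitter, clipped to the physical domain),
  where z is the species' total PM standardized to the tier span — so the
  field's observed PM–energy correlation has a known planted sign and the
  correlation stage has a ground truth to recover;
- measurement noise: i.i.d. Gaussian 0.05 mg per replicate weighing (three
  tare + three loaded per filter), Gaussian 5° per contact-angle droplet
  (fifteen per liquid, truncated to (0,180) by redraw), TDS exact by
  default (conductivity error is secondary to weighing error) with an
  optional relative-noise knob;
- protocol constants: eluate volumes 0.35 L (water) and 0.15 L
  (chloroform), filter tares U(100, 150) mg.

All randomness flows from explicit `numpy.random.Generator` objects;
`simulate_study` derives independent child seeds for truth and measurement
noise from one study seed, so a fixed truth can be re-measured across
Monte-Carlo replicates.

With all noise at zero the pipeline recovers densities and surface
energies exactly (the weighing clamp never triggers), which pins the
estimator's bookkeeping; at default noise the density estimator is
unbiased to well under 2% per fraction (checked over 200 replicate
studies), and estimated-vs-true efficiency regresses through the origin
with slope 1 ± 5% at all three scales.

What the generator does **not** emulate: spatial or temporal deposition
dynamics (rain resuspension, turbulence, leaf age), correlated balance
drift, heteroscedastic TDS error, between-batch biological variation in
true density (batch spread comes only from measurement noise), or
non-Gaussian droplet error on rough surfaces. Passing tests therefore
validate the accounting and estimation machinery, not any field-scale
deposition model.

## Numerical choices and degenerate inputs

- Replicate means are plain arithmetic means; weighing order is
  irrelevant by construction.
- The Owens–Wendt system is solved by direct 2×2 linear algebra; a
  determinant below 1e-9 (proportional liquid vectors) is rejected as
  singular rather than solved in least squares.
- Forward contact angles raise when the implied cosine leaves [−1, 1]
  (complete wetting/non-wetting has no finite angle).
- Proportions are undefined for a zero-mass inventory and raise.
- Ranking ties break alphabetically by species code, making reports
  deterministic.
- Report CSVs are written with fixed float formats (`%.1f` human,
  `%.12g` machine) so identical runs are byte-identical.

## Known limitations

- The efficiency accounting treats deposition as linear in time over the
  exposure window; saturation and washing events within the window are
  out of scope.
- OPM-by-conductivity is reproduced as specified but physically dubious
  (see above).
- The reference dataset carries two documented quirks upstream of this
  package: one species appears under different codes in different tables
  (PhSu vs PhVi; shipped verbatim, flagged by the loader), and one
  species' printed polar component (0.1 mJ/m²) is not reproducible from
  its printed contact angles.
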