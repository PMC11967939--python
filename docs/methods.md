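# Methods

This note records the models, conventions and design choices behind
`benthoscape`, in the order the pipeline runs them.

## Coverage from grid annotations

A station's seabed image is annotated as a 10 × 10 grid of majority
substratum labels; cells that cannot be identified are `unknown`. The
raw vocabulary (algae, seagrass, maerl, gravel, mud, sand, boulder,
pebble) is merged to five analysis classes before counting: maerl —
live or dead — into gravel, seagrass into sand, boulder into pebble,
and all algal types into algae. These merges reflect field practice:
the absorbed classes are too sparse in typical surveys to krige on
their own, and they are sedimentologically closest to their hosts. The
merge map is a plain dict and can be replaced per call.

Proportions are counts over *identifiable* cells only, so a station
with 20 unknown cells still yields a valid composition on the simplex.
A station with every cell unknown has no defined composition and is
rejected. Stations with fewer than 50 identifiable cells (configurable)
are flagged but retained: there is no principled minimum, and dropping
them would bias coverage against turbid sites. Cell *positions* never
matter — the profile is a position-free statistic — and this is tested
as a property.

## Variograms and ordinary kriging

The spatial model is an intrinsically stationary, isotropic random
field per variable. The empirical semivariogram uses the
method-of-moments estimator γ̂(h) = Σ(zᵢ−zⱼ)²/2N(h) on uniform distance
bins up to a cutoff of ⅓ the maximum pairwise distance (15 bins by
default); bin centres are mean pair distances, and empty bins are
dropped. Anisotropy is not modelled: survey layouts of ~150–500
stations over a coastal embayment rarely support stable directional
fitting, and none of the pipeline's downstream consumers use it.

Model fitting minimises Σ N(h)/h² (γ̂−γ)² over spherical, exponential
and gaussian candidates with nonnegative bounds, keeping the family
with the smallest weighted SSE — the weighting of automatic variogram
fitting practice, which privileges short, well-populated lags where
kriging weights are decided. The fit uses bounded trust-region least
squares from three starts (nugget-heavy, sill-heavy, long-range) to
avoid the flat-valley local minima these objectives have. Parameters
follow the gstat convention, where the exponential/gaussian `range_m`
is the distance parameter rather than the practical range;
`VariogramModel.practical_range` converts (×3 and ×√3 respectively) so
ranges are comparable across families.

`OrdinaryKriging` is an sklearn-style estimator: `fit` validates the
(n, 2) metre coordinates, averages exact duplicate locations (with a
warning — duplicates make the kriging matrix singular), optionally
auto-fits the variogram, and LU-factorises the augmented system once;
`predict` solves for all targets against that factorisation. The
kriging variance λ·γ₀ + μ is clamped at zero before the square root:
tiny negative values arise from round-off when a target coincides with
a datum. Coverage classes are kriged independently and clamped to
[0, 1] but *not* renormalised across classes — a kriged cell is a
mixture estimate per class, not an exclusive classification, and
renormalising would propagate error from poorly-sampled classes into
well-sampled ones.

Cross-validation partitions stations into k = 5 random folds by an
explicit integer seed and refits the variogram inside every training
split, so the diagnostics carry no leakage. The five reported
statistics are the conventional automatic-kriging diagnostics: ME
(mean error, bias), MPSE (mean predicted standard error), MSNE (mean
square normalised error — ≈1 when the SEs are calibrated), COP
(correlation of observed and predicted) and CPR (correlation of
predicted with residual; near 0 when the predictor exhausts the signal).
The acronym expansion of CPR in survey reports is ambiguous; the
predicted-versus-residual correlation is implemented because it is the
diagnostic this workflow conventionally prints alongside the other four.

## Diversity

Inverse Simpson D = 1/Σpᵢ² on relative MaxN abundances, the effective
number of equally abundant species (1 ≤ D ≤ S). The naive plug-in
estimator is used deliberately: MaxN is an index, not an abundance, so
bias-corrected estimators would add no real accuracy. Stations with one
individual give D = 1 and are flagged as low-information; stations with
no individuals have undefined diversity and are dropped from the
diversity table with a warning.

## Landscape patches and hotspots

Patches are connected components of cells whose predicted coverage
exceeds 0.2 — with five classes, 0.2 is the level above which a class
is more than proportionally represented, and it suppresses patch
inflation from sporadic low-coverage predictions. Default connectivity
is 8 (diagonal neighbours join), the common landscape-metrics
convention; 4-connectivity is available and always yields at least as
many patches. Because layers are mixtures, patches of different
substrata may overlap; layers are processed independently and never
merged.

Per patch, in cell units: area A = n cells, perimeter P = exposed cell
edges (counted against background, NaN mask and the grid boundary),
RPA = P/A (4 is the single-cell ceiling), and the perimeter–area
fractal dimension FDI = 2 ln(P/4)/ln(A), defined as 1 for single-cell
patches where the formula is 0/0. FDI is exactly 1 for solid squares
and grows toward 2 with edge complexity; verbal descriptions of this
index sometimes claim a 0–2 range, but the perimeter–area form is
bounded below by 1 for grid patches. Metre-unit area and perimeter are
reported alongside, but the shape indices are computed in cell units
where their closed forms hold.

Hotspots: the threshold is the empirical quantile at (1 − f) of finite
predicted-diversity cells, f = 0.2 by default, with numpy's
linear-interpolation quantile definition; the mask selects cells
strictly above it, so a constant surface yields no hotspots.

## Zonal aggregation and tests

Surfaces are averaged over a 500 m × 500 m grid overlay (a raster cell
belongs to the square containing its centre; empty squares are
omitted); each square takes the management zone containing its
centroid. Diversity comparisons use Kruskal–Wallis (tie-corrected, χ²
upper-tail p with df = groups − 1), Dunn's pairwise post-hoc on pooled
midranks with Bonferroni adjustment, and the tie-corrected normal
approximation rank-sum test for single pairs; the χ² approximation is
used at all group sizes. For the substratum comparison each station is
assigned its modal class, ties broken by the fixed order algae, gravel,
mud, sand, pebble. Both the station-level and grid-square pathways are
produced, since zonal summaries can legitimately be computed either way.

## Synthetic study conditions

The generator's defaults define the conditions every test and the
acceptance script run under, chosen once as a realistic desk-scale
analogue of a coastal MPA survey:

| parameter | default | why |
|---|---|---|
| domain | 10 km × 10 km | MPA-scale extent that holds 150 separated stations |
| grid | 50 × 50 cells of 200 m | inside the 10⁴-cell dense-factorisation guard |
| stations | 150, ≥ 500 m apart | deployment-separation rule of BRUV surveys |
| field variograms | spherical, nugget 0.05, sill 1.05; ranges 800 m (algae) – 2500 m (mud, sand) | algae patchy at short range; soft sediments extensive |
| softmax temperature | 1.0 | mixtures dominated by 1–2 classes, rarely one-hot |
| unknown rate | 0.1 | ~10 obscured cells per image |
| species pool | 20, expected total MaxN 60 | typical BRUV deployment richness/counts |
| diversity coupling | 0.75 | station D* = 1 + 0.75·E_sub + zone offset, giving D ≈ 1.8–4.8 |
| zone offsets | BT 0, TND 0.5, DTDC 0.5, NTZ 1.0 | a detectable, ordered management effect |

Fields are simulated by dense Cholesky factorisation of
C(h) = sill − γ(h) (a spectral simulator is out of scope at these grid
sizes; factors are cached across replicates). Compositions use a
softmax link — simplex-valid and smooth by construction; additive
log-ratio links were rejected as needlessly indirect for a forward
model. Station placement is uniform-with-separation; the depth
stratification of real survey designs is not emulated because depth
enters no computation in the pipeline. Species counts arise from a
geometric-series abundance profile whose parameter is solved (Brent)
so the series' inverse Simpson equals the target D*, then Poisson
thinning produces integer MaxN.

What the generator does *not* emulate: bait-plume attraction dynamics,
camera field-of-view geometry, annotation error correlated within an
image, tide/daylight constraints, and real shoreline/bathymetry
geometry. Passing tests therefore demonstrate that the estimators
recover the stated generating processes, not that any particular real
survey meets those assumptions.

## Numerical conventions

- γ(0) = 0 exactly; the nugget is a discontinuity at the origin.
- Kriging variance clamped at 0 before the root; SE = 0 at data points
  when nugget = 0.
- Duplicate data coordinates averaged (warning) rather than rejected.
- All-zero empirical variograms return a degenerate flat model with a
  warning instead of failing, so constant fields propagate as constants.
- Quantiles use linear interpolation; hotspot masks use strict `>`.
- Fold assignment, field simulation and all sampling take explicit
  integer seeds or `numpy.random.Generator`s; reruns are byte-identical.

## Problem sizes

Unit and property tests run on small configurations (tens of stations,
≤ 50 × 50 grids). The acceptance checks use 150–400 stations, 20 seeds
for variogram recovery and CV calibration, 50 replicates for zone-effect
detection and 10 simulated surveys for field recovery — sizes at which
the medians of the checked statistics are stable across seeds.

## Known limitations

- Isotropic variograms only; no universal or co-kriging, so systematic
  trends (e.g. depth gradients) fold into the variogram.
- Independent per-class kriging ignores the compositional constraint;
  predicted class sums need not equal 1 (by design, but worth knowing).
- The χ² approximation for Kruskal–Wallis is rough below ~5 values per
  group; exact small-sample p-values are out of scope.
- The plug-in inverse Simpson is biased low at very small total MaxN.
- Dense-factorisation field simulation caps synthetic grids at 10⁴
  cells.
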