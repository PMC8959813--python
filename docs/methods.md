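# Methods

## Generative tree and stand model

Each synthetic tree is a pair of solids of revolution around a vertical
axis. The stem follows the taper family

    d(h) = d0 · ((H − h)/H)^k ,  k ≥ 0,

which is monotone, reaches zero at the tip, and has closed-form volume
`(π/4)·d0²·H/(2k+1)` and closed-form cumulative-volume heights — the reason
this family was chosen over more flexible taper models. `k = 0` is a
cylinder and `k = 1` a cone; stand presets use `k = 0.8` as a compromise
between the near-cylindrical mid-bole and the conical tip of mature pine.

The crown is one of three profiles `r(h)` on `[hb, H]` with maximum radius
`rc` at height `hm` (`0 < hb < hm < H`): a two-piece ellipsoid (default), a
bicone, or a spheroid cap with a linear lower ramp. All three are convex,
so the convex hull of dense interior samples converges to the solid itself
and hull volume/surface have analytic or 1 mm-grid numeric references.
`hm` defaults to a quarter of the crown length above the crown base —
pine-like, bottom-heavy — which also keeps the widest point well inside one
height-percentile slice (at exactly 20/30% of crown volume it would sit on
a slice boundary and make the maximum-diameter slice an unstable tie).

Point sampling: stem points on the taper surface with area-weighted height
density (points/m²), crown points uniformly inside the crown solid
(points/m³), ground points on a smooth sinusoid (amplitude ≤ 0.5 m,
defaults 0.15 m over a 25 m wavelength) at points/m², isotropic Gaussian
coordinate noise (default 5 mm, matching millimeter-class phase-shift
scanners more than coarse profilers). Default densities (60 pts/m³ crown,
400 pts/m² stem, 25 pts/m² ground) are far below a real co-registered
multi-scan TLS campaign; they were chosen so a 21-plot experiment runs in
minutes while every structure the pipeline exploits (circular stem slices,
smooth canopy envelope, ground sheet) is well resolved. Validation suites
that probe estimator *accuracy* (taper, trait recovery) use 1500–2000
pts/m² and pts/m³ noiseless clouds instead; suites that probe *detection*
(segmentation) use 500–600. What the generator does **not** emulate:
occlusion and range shadowing, beam footprint, branch-level structure,
foliage clumping, crown asymmetry, and multi-scan registration error. Tests
passing here therefore demonstrate correctness of the algorithms under
ideal sampling, not field performance.

Treatment presets follow the stand tables of a two-intensity ×
three-type thinning trial plus control: densities ~1250 (control), 720,
910, 940 (moderate), 290, 450, 470 (intensive) stems/ha, DBH and height
distributions per treatment, crown radius increasing and crown base
dropping as density falls (`hb/H` from 0.55 at 1250/ha down to 0.40 at
290/ha). The experiment generator adds multiplicative lognormal-style site
(4%) and plot-in-site (5%) effects on mean crown radius, DBH and height,
producing the nested variance structure the two-level model estimates.
Moderate-treatment crown radii sit close to the control (1.37–1.42 m vs
1.30 m) while intensive ones are much larger (2.05–2.45 m), so the
moderate-vs-control contrast is genuinely null-ish at plot-level power
while intensive-vs-control is strong — the qualitative pattern the
statistics layer is expected to reproduce.

Synthetic growth columns are drawn as `growth = a + b·SAHMC_true + noise`
with positive slopes, placing treatment-level growth means inside the
reported field ranges (e.g. DBH growth ≈ 4–9 cm over the growth period).

## Pipeline choices

**Terrain model.** Per 0.5 m cell, the lowest return after a per-cell
2.5×IQR low-outlier rejection. Cells more than 0.5 m above the lowest cell
within a 6 m window are discarded as canopy-only (crowns overhanging the
plot edge leave cells with no ground returns at all); remaining holes are
nearest-neighbor filled and smoothed once with a 3×3 mean. Heights are
normalized by bilinear interpolation of the cell-center grid, clamped to
nearest at the raster edge.

**Segmentation.** CHM = max height per 20 cm cell, one 3×3 median pass
against pits. A treetop is a strict maximum inside a circular window;
the default window `max(0.5, 0.04·h)` m suits dense boreal canopies, and
`spacing_window()` builds the natural alternative when stand spacing is
known: a constant radius just under half the minimum stem spacing, which
guarantees every crown cell sees its own apex while no window reaches a
neighboring crown. Equal-height ties keep the first cell in row-major
order. Crowns are watershed basins of the inverted CHM grown from treetop
markers, masked below 2 m canopy height; points inherit the label of their
half-open `[x0,x1)×[y0,y1)` cell.

**Stem/crown classification.** Per point, PCA over the 20 nearest
neighbors; verticality = 1 − |normal·up| ≥ 0.8 marks candidates. From the
base upward in 0.5 m bins: fit a circle (algebraic fit, iterated
inlier-reselection, trimmed refit), accept the bin if ≥ 60% of its
candidates lie within 3 cm of the circle, the center drifts ≤ 25 cm from
the previous accepted circle, and the diameter stays below a 0.8 m
plausibility cap (without the cap, a dense-stand segment can lock onto an
arc through neighboring material and report meter-scale "stems"). Stop
after 3 consecutive rejections; if no bin in the lowest 2 m is acceptable
the tree is flagged and everything returned as crown. Stem points are all
points (candidates or not) within tolerance of an accepted bin's circle —
membership by residual rescues stem returns whose verticality suffered
neighborhood edge effects at the stem base.

**Taper and stem traits.** Circles per 0.5 m slice of the classified stem
points with a trimmed refit (keep the 85% smallest residuals, twice):
slice sets carry a thin rind of foliage returns whose density grows with
radius, and plain least squares absorbs that asymmetry as a millimeter-
scale outward diameter bias. Slices are dropped on residual > 3 cm or a
> 10% diameter increase over the previous accepted slice; an interpolating
cubic spline runs through the accepted (height, diameter) knots. Below the
first knot the curve extends linearly (cubic extrapolation can swing);
above the last knot the diameter tapers linearly to zero at the measured
tree top. Stem volume stacks 10 cm cylinders with diameters at bin
midpoints (midpoint evaluation halves the bias of end-evaluation for
monotone tapers); the half-volume height interpolates linearly inside the
crossing bin.

**Crown traits.** "Height percentiles of 10%" are read as equal-point-count
deciles of the crown-point height distribution (the percentile wording);
equal-height bands remain available via configuration. The slice
representative height is its mean point height; diameter ties at the
maximum resolve to the lowest slice, the conservative (longest-crown)
choice. The analytic oracle mirrors these definitions exactly — deciles of
the crown solid's volume distribution, volume-weighted mean heights, the
same tie rule — so oracle-vs-pipeline comparisons measure estimation error,
not definition mismatch. SAHMC converts the taper diameter to cm before
squaring.

## Statistical layer

The nested model is REML-fitted with cell-means treatment coding (one β per
treatment, no intercept), a site random intercept and a plot-within-site
variance component. The fixed-effect covariance is computed by GLS from the
estimated variance components rather than from the optimizer's Hessian,
which degenerates when a variance estimate hits the zero boundary (common
with three sites). Tukey p-values use the studentized-range distribution on
the fitted covariance with containment degrees of freedom at the plot level
(`n_plots − n_treatments`), the appropriate error stratum for a plot-level
factor; a Satterthwaite approximation per contrast would need Hessian
pieces the backend does not expose. Both Pearson and Spearman correlations
are reported side by side in the trait screen, and each single-predictor
model keeps the full random structure with a Wald test on the slope.

A note on calibration: with only three sites, the site variance is
estimated on ~2 degrees of freedom, so ±2·(estimated SE) intervals for the
treatment means cover at roughly 90%, not the nominal 95% — a well-known
property of few-group REML, not an estimator defect. The recovery test
therefore checks (a) that estimates fall within two *sampling* standard
errors of truth at the nominal rate and (b) that the mean reported SE
matches the sampling SD.

## Problem sizes

Validation runs use: 30 dense noiseless single trees for trait recovery;
32×32 m stands at 290 and 1250 stems/ha for segmentation; 200 replicates of
the 3 sites × 9 plots × 25 trees design for fixed-effect recovery and 500
replicates (10 trees/plot) for the null family-wise error rate; the study
emulation processes 3 sites × 7 plots end to end at the default point
densities. These sizes keep the whole suite within a few minutes on a
single CPU while leaving Monte-Carlo error well below the tested margins.

## Known limitations

- Interlocking crowns are split by 2D watershed only; no voxel/3D
  separation, so point assignment degrades as crowns overlap (the control
  stands lose a few suppressed trees to non-detection, as real CHM-based
  detection does).
- Forked or leaning stems violate the single-circle-per-slice assumption.
- The stem classifier is a geometric procedure specified here; it was not
  calibrated against any external classifier implementation.
- Growth is generated, not measured: the screen's growth rows validate
  statistical recovery of a planted relationship, nothing about real
  growth.
- "Relative stem volume" is not computed (no operational definition was
  available).
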