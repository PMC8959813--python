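"""Synthetic TLS stands of Scots-pine-like trees with analytic ground truth.

Each tree is a parametric solid: a stem of revolution with taper
``d(h) = d0 * ((H - h)/H)**k`` and a crown solid of revolution (two-piece
ellipsoid, bicone, or spheroid cap) described by crown-base height ``hb``,
maximum crown radius ``rc`` and the height ``hm`` at which that radius is
attained.  Point clouds are sampled from these solids (stem surface at a
points/m^2 density, crown volume at points/m^3, ground at points/m^2) with
per-point class labels, so every downstream pipeline stage can be scored
against exact generative truth.

Stands emulate a thinning experiment with seven treatments: two thinning
intensities (moderate ~68% and intensive ~34% of basal area retained) times
three thinning types (from below, from above, systematic) plus an unthinned
control, with residual densities of roughly 1250, 720, 910, 940, 290, 450
and 470 stems/ha.  Crown size grows and crown base drops as density falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pointcloud_io import CROWN, GROUND, STEM, PointCloud

CROWN_SHAPES = ("ellipsoid", "cone", "spheroid_cap")

#: The seven thinning treatments in conventional reporting order.
TREATMENTS = (
    "no_treatment",
    "moderate_below",
    "moderate_above",
    "moderate_systematic",
    "intensive_below",
    "intensive_above",
    "intensive_systematic",
)


@dataclass
class TreeModel:
    """Generative parameters of one tree (all lengths in meters)."""

    position: tuple[float, float] = (0.0, 0.0)
    height: float = 20.0
    d0: float = 0.22              # basal stem diameter
    taper_exponent: float = 0.8   # k >= 0; 0 = cylinder, 1 = cone
    crown_shape: str = "ellipsoid"
    crown_base: float = 10.0      # hb
    crown_radius: float = 1.8     # rc
    crown_max_height: float = 12.5  # hm, height of the maximum crown radius
    crown_density: float = 60.0   # points / m^3
    stem_density: float = 400.0   # points / m^2
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not (0 < self.crown_base < self.crown_max_height < self.height):
            raise ValueError(
                f"crown geometry must satisfy 0 < hb < hm < H, got "
                f"hb={self.crown_base}, hm={self.crown_max_height}, H={self.height}"
            )
        if self.crown_radius <= 0:
            raise ValueError("crown radius must be positive")
        if self.d0 <= 0 or self.taper_exponent < 0:
            raise ValueError("stem taper requires d0 > 0 and k >= 0")
        if self.crown_shape not in CROWN_SHAPES:
            raise ValueError(f"unknown crown shape {self.crown_shape!r}")

    # ---- analytic stem ----

    def stem_diameter(self, h: np.ndarray | float) -> np.ndarray | float:
        """True taper d(h); zero above the tip."""
        rel = np.clip((self.height - np.asarray(h, dtype=float)) / self.height, 0.0, 1.0)
        return self.d0 * rel ** self.taper_exponent

    def stem_volume_m3(self) -> float:
        """Exact solid-of-revolution stem volume: (pi/4) d0^2 H / (2k+1)."""
        return math.pi / 4 * self.d0**2 * self.height / (2 * self.taper_exponent + 1)

    def height_at_volume_fraction(self, frac: float) -> float:
        """Exact height below which ``frac`` of the stem volume accumulates."""
        p = 2 * self.taper_exponent + 1
        return self.height * (1 - (1 - frac) ** (1 / p))

    # ---- analytic crown profile ----

    def crown_radius_at(self, h: np.ndarray | float) -> np.ndarray:
        """Crown solid radius r(h); zero outside [hb, H]."""
        h = np.asarray(h, dtype=float)
        hb, hm, H, rc = self.crown_base, self.crown_max_height, self.height, self.crown_radius
        r = np.zeros_like(h)
        lo = (h >= hb) & (h <= hm)
        up = (h > hm) & (h <= H)
        if self.crown_shape == "ellipsoid":
            r[lo] = rc * np.sqrt(np.clip(1 - ((h[lo] - hm) / (hm - hb)) ** 2, 0, 1))
            r[up] = rc * np.sqrt(np.clip(1 - ((h[up] - hm) / (H - hm)) ** 2, 0, 1))
        elif self.crown_shape == "cone":
            r[lo] = rc * (h[lo] - hb) / (hm - hb)
            r[up] = rc * (H - h[up]) / (H - hm)
        else:  # spheroid_cap: linear ramp below hm, spheroidal cap above
            r[lo] = rc * (h[lo] - hb) / (hm - hb)
            r[up] = rc * np.sqrt(np.clip(1 - ((h[up] - hm) / (H - hm)) ** 2, 0, 1))
        return r

    def crown_volume_m3(self) -> float:
        hb, hm, H, rc = self.crown_base, self.crown_max_height, self.height, self.crown_radius
        if self.crown_shape == "ellipsoid":
            return 2 / 3 * math.pi * rc**2 * (H - hb)
        if self.crown_shape == "cone":
            return math.pi / 3 * rc**2 * (H - hb)
        return math.pi / 3 * rc**2 * (hm - hb) + 2 / 3 * math.pi * rc**2 * (H - hm)


def generate_tree(model: TreeModel, seed: int | np.random.Generator,
                  ground_radius: float | None = None,
                  ground_density: float = 25.0) -> PointCloud:
    """Sample a labeled point cloud from one tree model.

    Stem points are sampled on the taper surface (area-weighted in height),
    crown points uniformly inside the crown solid, and an optional flat
    ground patch around the stem foot.  Isotropic Gaussian noise of
    ``model.noise_sd`` is added to every coordinate.  Deterministic for a
    given integer seed.
    """
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H, k, d0 = model.height, model.taper_exponent, model.d0
    parts: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # stem: lateral area ~ pi * d(h) dh; height pdf proportional to (H-h)^k
    area = math.pi * d0 * H / (k + 1)
    n_stem = rng.poisson(model.stem_density * area)
    u = rng.random(n_stem)
    h = H - H * (1 - u) ** (1 / (k + 1))
    theta = rng.random(n_stem) * 2 * math.pi
    r = model.stem_diameter(h) / 2
    parts.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), h]))
    labels.append(np.full(n_stem, STEM))

    # crown: rejection sampling in the bounding cylinder of the crown solid
    n_crown = rng.poisson(model.crown_density * model.crown_volume_m3())
    pts = np.empty((0, 3))
    hb, rc = model.crown_base, model.crown_radius
    while pts.shape[0] < n_crown:
        m = max(1024, 2 * (n_crown - pts.shape[0]))
        hc = hb + rng.random(m) * (H - hb)
        rr = rc * np.sqrt(rng.random(m))
        th = rng.random(m) * 2 * math.pi
        ok = rr <= model.crown_radius_at(hc)
        pts = np.vstack([pts, np.column_stack([rr[ok] * np.cos(th[ok]),
                                               rr[ok] * np.sin(th[ok]), hc[ok]])])
    parts.append(pts[:n_crown])
    labels.append(np.full(n_crown, CROWN))

    if ground_radius is None:
        ground_radius = model.crown_radius + 1.0
    if ground_radius > 0 and ground_density > 0:
        n_g = rng.poisson(ground_density * math.pi * ground_radius**2)
        rg = ground_radius * np.sqrt(rng.random(n_g))
        tg = rng.random(n_g) * 2 * math.pi
        parts.append(np.column_stack([rg * np.cos(tg), rg * np.sin(tg), np.zeros(n_g)]))
        labels.append(np.full(n_g, GROUND))

    xyz = np.vstack(parts)
    if model.noise_sd > 0:
        xyz = xyz + rng.normal(0, model.noise_sd, xyz.shape)
    xyz[:, 0] += model.position[0]
    xyz[:, 1] += model.position[1]
    return PointCloud(xyz, np.concatenate(labels))


# --------------------------------------------------------------------------
# analytic trait oracle
# --------------------------------------------------------------------------

def oracle_traits(model: TreeModel, n_slices: int = 10, step: float = 0.001) -> dict:
    """Exact (closed-form or <=1 mm numeric) values of every pipeline trait.

    Crown slice traits mirror the pipeline's equal-count decile definition:
    under uniform volumetric sampling the point-height distribution has
    density proportional to r(h)^2, so decile boundaries are equal-volume
    heights, a slice's diameter is twice the maximum solid radius inside it,
    and its representative height is the volume-weighted mean height.  SAHMC
    evaluates the true taper at the slice-based HMC.
    """
    model.validate()
    H, hb = model.height, model.crown_base
    hs = np.arange(hb, H + step, step)
    w = model.crown_radius_at(hs) ** 2  # un-normalized point-height density
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(hs))])
    cdf /= cdf[-1]
    bounds = np.interp(np.linspace(0, 1, n_slices + 1), cdf, hs)

    slice_d = np.empty(n_slices)
    slice_h = np.empty(n_slices)
    for i in range(n_slices):
        m = (hs >= bounds[i]) & (hs <= bounds[i + 1])
        slice_d[i] = 2 * model.crown_radius_at(hs[m]).max()
        slice_h[i] = np.average(hs[m], weights=np.maximum(w[m], 1e-300))
    imax = int(np.flatnonzero(slice_d >= slice_d.max() - 1e-9)[0])  # tie -> lowest
    hmc = float(slice_h[imax])

    # crown hull (solids are convex for all three shapes): volume = solid
    # volume, surface = lateral surface of revolution (no end caps: r=0).
    r = model.crown_radius_at(hs)
    drdh = np.gradient(r, hs)
    surface = float(np.trapezoid(2 * math.pi * r * np.sqrt(1 + drdh**2), hs))

    dbh_cm = 100 * float(model.stem_diameter(1.3))
    d_hmc_cm = 100 * float(model.stem_diameter(hmc))
    crown = {
        "crown_projection_area_m2": math.pi * model.crown_radius**2,
        "crown_volume_m3": model.crown_volume_m3(),
        "crown_surface_area_m2": surface,
        **{f"crown_diameter_p{10 * (i + 1)}_m": float(slice_d[i]) for i in range(n_slices)},
        "max_crown_diameter_m": 2 * model.crown_radius,
        "mean_crown_diameter_m": float(slice_d.mean()),
        "sd_crown_diameter_m": float(slice_d.std(ddof=1)),
        "hmc_m": hmc,
        "crown_length_m": H - hmc,
        "crown_tapering_m": float(slice_d.max() - slice_d.min()),
        "live_crown_ratio": (H - hmc) / H,
        "sahmc_cm2": math.pi / 4 * d_hmc_cm**2,
    }
    stem = {
        "dbh_cm": dbh_cm,
        "tree_height_m": H,
        "stem_volume_dm3": 1000 * model.stem_volume_m3(),
        "height_50pct_volume_m": model.height_at_volume_fraction(0.5),
        "height_dbh_ratio": H / dbh_cm,
    }
    return {**crown, **stem}


# --------------------------------------------------------------------------
# stands and the thinning experiment
# --------------------------------------------------------------------------

@dataclass
class TreeParamDistribution:
    """Stand-level distributions the per-tree parameters are drawn from."""

    dbh_mean_cm: float = 20.0
    dbh_sd_cm: float = 4.0
    height_mean_m: float = 20.0
    height_sd_m: float = 2.0
    rc_mean_m: float = 1.6
    rc_sd_m: float = 0.12
    hb_frac_mean: float = 0.48   # crown-base height as a fraction of H
    hb_frac_sd: float = 0.04
    hm_frac: float = 0.25        # max-radius height as a fraction of crown length
    taper_exponent: float = 0.8
    crown_shape: str = "ellipsoid"


#: Per-treatment defaults emulating the study stands after the growth period
#: (density in stems/ha; tree size from the reported stand tables; crown
#: radius increasing and crown base dropping as density decreases).
TREATMENT_DEFAULTS: dict[str, dict] = {
    "no_treatment":        dict(density=1250, dbh=18.7, dbh_sd=5.0, h=20.2, h_sd=3.0, rc=1.30),
    "moderate_below":      dict(density=720,  dbh=22.2, dbh_sd=3.7, h=21.2, h_sd=2.1, rc=1.42),
    "moderate_above":      dict(density=910,  dbh=19.3, dbh_sd=4.3, h=20.4, h_sd=1.6, rc=1.38),
    "moderate_systematic": dict(density=940,  dbh=18.8, dbh_sd=4.2, h=19.4, h_sd=2.2, rc=1.37),
    "intensive_below":     dict(density=290,  dbh=26.4, dbh_sd=3.9, h=21.2, h_sd=1.7, rc=2.45),
    "intensive_above":     dict(density=450,  dbh=21.1, dbh_sd=3.5, h=19.1, h_sd=1.5, rc=2.05),
    "intensive_systematic": dict(density=470, dbh=20.8, dbh_sd=4.3, h=19.6, h_sd=2.8, rc=2.05),
}


def _hb_frac_for_density(density: float) -> float:
    # crown base rises with competition: 0.40 at 290/ha up to 0.55 at 1250/ha
    return 0.40 + 0.15 * np.clip((density - 290) / 960, 0, 1)


def treatment_distribution(treatment: str) -> TreeParamDistribution:
    d = TREATMENT_DEFAULTS[treatment]
    return TreeParamDistribution(
        dbh_mean_cm=d["dbh"], dbh_sd_cm=d["dbh_sd"],
        height_mean_m=d["h"], height_sd_m=d["h_sd"],
        rc_mean_m=d["rc"],
        hb_frac_mean=float(_hb_frac_for_density(d["density"])),
    )


#: Synthetic growth columns: growth = a + b * SAHMC_true + N(0, sd^2).
#: Intercepts/slopes chosen so treatment-level growth means land in the
#: reported growth ranges and all four SAHMC-growth slopes are positive.
GROWTH_MODEL: dict[str, tuple[float, float, float]] = {
    "d_dbh_cm": (1.5, 0.045, 1.0),
    "d_height_m": (4.0, 0.006, 0.8),
    "d_volume_dm3": (60.0, 1.8, 50.0),
    "d_height_dbh": (-0.10, 0.0012, 0.05),
}


@dataclass
class StandSpec:
    """Specification of one synthetic plot."""

    width_m: float = 32.0
    length_m: float = 32.0
    treatment: str = "no_treatment"
    target_density: float = 1250.0   # stems/ha; 0 = ground only
    params: TreeParamDistribution = field(default_factory=TreeParamDistribution)
    crown_density: float = 60.0      # points/m^3
    stem_density: float = 400.0      # points/m^2
    ground_density: float = 25.0     # points/m^2
    ground_amplitude_m: float = 0.15
    ground_wavelength_m: float = 25.0
    noise_sd: float = 0.005
    min_spacing_m: float | None = None  # default: 0.55 * mean Poisson spacing
    seed: int = 0

    def validate(self) -> None:
        area = self.width_m * self.length_m
        if not (1.0 <= area):
            raise ValueError("plot area must be positive")
        if self.target_density != 0 and not (250 <= self.target_density <= 1400):
            raise ValueError("stand density must be 0 or within [250, 1400] stems/ha")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.ground_amplitude_m > 0.5:
            raise ValueError("ground amplitude must be <= 0.5 m")

    @property
    def area_m2(self) -> float:
        return self.width_m * self.length_m

    def ground_surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        lam = self.ground_wavelength_m
        return self.ground_amplitude_m * 0.5 * (
            np.sin(2 * math.pi * np.asarray(x) / lam)
            + np.cos(2 * math.pi * np.asarray(y) / lam)
        )


def for_treatment(treatment: str, seed: int = 0, **overrides) -> StandSpec:
    """StandSpec preset for one of the seven thinning treatments."""
    d = TREATMENT_DEFAULTS[treatment]
    spec = StandSpec(treatment=treatment, target_density=d["density"],
                     params=treatment_distribution(treatment), seed=seed)
    return replace(spec, **overrides)


def _place_stems(spec: StandSpec, rng: np.random.Generator) -> np.ndarray:
    n_target = int(round(spec.target_density * spec.area_m2 / 10_000))
    if n_target == 0:
        return np.empty((0, 2))
    spacing = spec.min_spacing_m
    if spacing is None:
        spacing = 0.55 * math.sqrt(spec.area_m2 / n_target)
    pos: list[tuple[float, float]] = []
    margin = 0.5  # keep stems off the plot edge
    attempts = 0
    max_attempts = 400 * n_target
    while len(pos) < n_target and attempts < max_attempts:
        attempts += 1
        p = (margin + rng.random() * (spec.width_m - 2 * margin),
             margin + rng.random() * (spec.length_m - 2 * margin))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= spacing**2 for q in pos):
            pos.append(p)
    if len(pos) < 0.9 * n_target:
        raise ValueError(
            f"cannot place {n_target} stems at minimum spacing {spacing:.2f} m "
            f"in a {spec.area_m2:.0f} m^2 plot (placed {len(pos)})"
        )
    return np.asarray(pos)


def generate_stand(spec: StandSpec, site: str = "S1", plot: str = "P1",
                   sample_points: bool = True) -> tuple[PointCloud, pd.DataFrame]:
    """Generate one plot: labeled cloud + per-tree ground-truth table.

    The returned cloud is in absolute elevations (trees stand on a smooth
    sinusoidal ground surface); the truth table holds every oracle trait,
    the generative parameters, and the synthetic growth columns.  With
    ``sample_points=False`` only the truth table is populated (fast path for
    statistical simulations); the cloud is empty.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    positions = _place_stems(spec, rng)

    clouds: list[PointCloud] = []
    tree_ids: list[np.ndarray] = []
    rows: list[dict] = []
    p = spec.params
    for i, (x, y) in enumerate(positions, start=1):
        H = max(10.0, rng.normal(p.height_mean_m, p.height_sd_m))
        dbh = max(8.0, rng.normal(p.dbh_mean_cm, p.dbh_sd_cm))
        rc = max(0.5, rng.normal(p.rc_mean_m, p.rc_sd_m))
        hb_frac = float(np.clip(rng.normal(p.hb_frac_mean, p.hb_frac_sd), 0.25, 0.75))
        hb = hb_frac * H
        hm = hb + p.hm_frac * (H - hb)
        k = p.taper_exponent
        d0 = dbh / 100 / ((H - 1.3) / H) ** k
        model = TreeModel(
            position=(float(x), float(y)), height=H, d0=d0, taper_exponent=k,
            crown_shape=p.crown_shape, crown_base=hb, crown_radius=rc,
            crown_max_height=hm, crown_density=spec.crown_density,
            stem_density=spec.stem_density, noise_sd=spec.noise_sd,
        )
        traits = oracle_traits(model)
        row = {"site": site, "plot": plot, "treatment": spec.treatment,
               "tree_id": i, "x": float(x), "y": float(y), **traits}
        for col, (a, b, sd) in GROWTH_MODEL.items():
            row[col] = a + b * traits["sahmc_cm2"] + rng.normal(0, sd)
        rows.append(row)

        if sample_points:
            pc = generate_tree(model, rng, ground_radius=0)  # plot-wide ground below
            pc.xyz[:, 2] += float(spec.ground_surface(x, y))
            clouds.append(pc)
            tree_ids.append(np.full(len(pc), i))

    # ground over the whole plot
    n_g = rng.poisson(spec.ground_density * spec.area_m2) if sample_points else 0
    gx = rng.random(n_g) * spec.width_m
    gy = rng.random(n_g) * spec.length_m
    gz = spec.ground_surface(gx, gy)
    if spec.noise_sd > 0:
        gz = gz + rng.normal(0, spec.noise_sd, n_g)
    ground = PointCloud(np.column_stack([gx, gy, gz]), np.full(n_g, GROUND))
    clouds.append(ground)
    tree_ids.append(np.zeros(n_g, dtype=int))

    cloud = PointCloud.concat(clouds)
    cloud.tree_id = np.concatenate(tree_ids)
    truth = pd.DataFrame(rows)
    return cloud, truth


def simulate_experiment(
    n_sites: int = 3,
    seed: int = 0,
    site_sd_frac: float = 0.04,
    plot_sd_frac: float = 0.05,
    generate_clouds: bool = False,
    **spec_overrides,
) -> tuple[pd.DataFrame, dict[tuple[str, str], PointCloud]]:
    """Emulate the thinning experiment: per site, one plot per treatment.

    Site- and plot-level lognormal-style multiplicative effects are applied
    to the mean crown radius, DBH and height, producing the nested
    variance structure the two-level mixed model targets.  Returns the
    pooled ground-truth trait table and (optionally) the plot clouds.
    """
    rng = np.random.default_rng(seed)
    tables = []
    clouds: dict[tuple[str, str], PointCloud] = {}
    for s in range(n_sites):
        site = f"site{s + 1}"
        site_eff = rng.normal(0, site_sd_frac)
        for t, treatment in enumerate(TREATMENTS):
            plot = f"{site}_plot{t + 1}"
            plot_eff = rng.normal(0, plot_sd_frac)
            scale = math.exp(site_eff + plot_eff)
            base = treatment_distribution(treatment)
            params = replace(
                base,
                rc_mean_m=base.rc_mean_m * scale,
                dbh_mean_cm=base.dbh_mean_cm * scale,
                height_mean_m=base.height_mean_m * scale,
            )
            spec = for_treatment(
                treatment,
                seed=int(rng.integers(2**31 - 1)),
                params=params,
                **spec_overrides,
            )
            cloud, truth = generate_stand(spec, site=site, plot=plot,
                                          sample_points=generate_clouds)
            if generate_clouds:
                clouds[(site, plot)] = cloud
            tables.append(truth)
    return pd.concat(tables, ignore_index=True), clouds
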