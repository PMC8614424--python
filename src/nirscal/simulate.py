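"""Synthetic straw spectra and compositions for desk-scale pipeline testing.

The forward model is a Beer–Lambert linear mixture: each constituent
contributes a fixed non-negative absorptivity curve (a sum of Gaussian
bands over the 850–2500 nm grid) scaled by its concentration, and every
sample is further distorted by multiplicative scatter, an additive offset,
a linear baseline tilt, and white noise — exactly the distortions that
SNV/MSC/detrend pretreatments exist to remove.

Compositions are drawn per species from truncated normal distributions
whose realized mean and SD match the profile's values (the parent normal
is moment-matched numerically, since truncation otherwise shifts both
moments).  Hemicellulose is sampled and NDF derived as ADF + hemicellulose
so the fiber identity holds exactly in the synthetic truth.

All randomness flows from one profile seed through per-sample substreams,
so generating more samples never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset import CONSTITUENTS, ReferenceTable, SpectraSet
from .errors import IdentifiabilityError, ProfileError

# substream tags (second word of the SeedSequence entropy)
_STREAM_COMPOSITIONS = 11
_STREAM_SPECTRA = 23


# ---------------------------------------------------------------------------
# component library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBand:
    center: float  # nm
    width: float   # nm (Gaussian sigma)
    amplitude: float  # absorbance per % concentration at the peak


@dataclass
class ComponentLibrary:
    """Per-constituent absorptivity curves on a shared wavelength grid."""

    grid: np.ndarray                 # (p,) nm
    curves: dict[str, np.ndarray]    # name -> (p,) non-negative

    @property
    def names(self) -> list[str]:
        return list(self.curves)

    def matrix(self, names) -> np.ndarray:
        return np.vstack([self.curves[n] for n in names])


# The main absorption features of air-dried straw sit near 1450, 1900,
# 2100, 2300 and 2450 nm (O-H of water and carbohydrate, N-H of protein,
# C-H of lignin/cuticle).  The band mixes below give each constituent a
# distinct, non-proportional signature; amplitudes are sized so that a
# typical straw composition yields absorbance of order 0.5-1.5.
DEFAULT_BANDS: dict[str, tuple[GaussianBand, ...]] = {
    "moisture": (
        GaussianBand(1450, 45, 0.012),
        GaussianBand(1900, 40, 0.016),
    ),
    "cp": (
        GaussianBand(2100, 35, 0.009),
        GaussianBand(2300, 55, 0.004),
        GaussianBand(1450, 70, 0.002),
    ),
    "ndf": (
        GaussianBand(2100, 70, 0.0020),
        GaussianBand(1450, 55, 0.0012),
        GaussianBand(2300, 45, 0.0014),
    ),
    "adf": (
        GaussianBand(2100, 50, 0.0030),
        GaussianBand(2300, 70, 0.0022),
        GaussianBand(1900, 65, 0.0010),
    ),
    "adl": (
        GaussianBand(2300, 40, 0.0050),
        GaussianBand(2450, 50, 0.0035),
        GaussianBand(1900, 90, 0.0012),
    ),
    "hemicellulose": (
        GaussianBand(2100, 40, 0.0026),
        GaussianBand(2450, 70, 0.0016),
        GaussianBand(1450, 40, 0.0010),
    ),
}

_COSINE_LIMIT = 0.999  # pairwise curve similarity above this is unidentifiable


def make_component_library(
    bands: dict[str, tuple[GaussianBand, ...]] | None = None,
    grid: np.ndarray | None = None,
) -> ComponentLibrary:
    """Build absorptivity curves as sums of Gaussian bands.

    Curves are non-negative by construction; pairwise cosine similarity
    must stay below 0.999 so the regression problem is identifiable.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    curves: dict[str, np.ndarray] = {}
    for name, blist in bands.items():
        curve = np.zeros_like(grid)
        for b in blist:
            if not lo <= b.center <= hi:
                raise ProfileError(
                    f"band center {b.center} nm for {name!r} outside grid "
                    f"span [{lo}, {hi}] nm"
                )
            curve += b.amplitude * np.exp(-0.5 * ((grid - b.center) / b.width) ** 2)
        curves[name] = curve
    names = list(curves)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ca, cb = curves[a], curves[b]
            cos = ca @ cb / (np.linalg.norm(ca) * np.linalg.norm(cb))
            if cos > _COSINE_LIMIT:
                raise IdentifiabilityError(
                    f"absorptivity curves for {a!r} and {b!r} are nearly "
                    f"proportional (cosine {cos:.6f})"
                )
    return ComponentLibrary(grid=grid, curves=curves)


def default_grid() -> np.ndarray:
    """The scanner's grid: 850-2500 nm at 0.5 nm, 3301 points."""
    return np.arange(850.0, 2500.0 + 0.25, 0.5)


# ---------------------------------------------------------------------------
# composition profiles
# ---------------------------------------------------------------------------

@dataclass
class SimulationProfile:
    """Per-species composition moments plus scatter/noise magnitudes.

    ``means``/``sds``/``bounds`` describe the realized (truncated) per-
    constituent distributions in % DM.  NDF is derived (ADF +
    hemicellulose), so its entries are descriptive only and never sampled.
    Scatter: per-sample multiplicative slope ~ N(1, slope_sd), additive
    offset ~ N(0, offset_sd), linear tilt ~ N(0, tilt_sd) across the grid,
    and white noise of SD noise_sd (absorbance units).
    """

    species: str
    means: dict[str, float]
    sds: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    slope_sd: float = 0.1
    offset_sd: float = 0.05
    tilt_sd: float = 0.02
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ProfileError(
                    f"{self.species}/{name}: bounds min {lo} >= max {hi}"
                )
        for name, sd in self.sds.items():
            if sd < 0:
                raise ProfileError(f"{self.species}/{name}: negative SD {sd}")
        if int(self.seed) != self.seed:
            raise ProfileError("seed must be an integer")
        self.seed = int(self.seed)

    def with_seed(self, seed: int) -> "SimulationProfile":
        return replace(self, seed=int(seed))


def _profile(species, rows, **kw) -> SimulationProfile:
    means, sds, bounds = {}, {}, {}
    for name, (lo, hi, mean, sd) in rows.items():
        means[name], sds[name], bounds[name] = mean, sd, (lo, hi)
    return SimulationProfile(species=species, means=means, sds=sds,
                             bounds=bounds, **kw)


# Default profiles: calibration-set descriptive statistics (min, max,
# mean, SD in % DM) of the two straw populations this package emulates.
CORN_STOVER = _profile("corn_stover", {
    "moisture":      (3.01, 7.41, 5.35, 1.14),
    "cp":            (2.15, 10.15, 5.18, 1.34),
    "ndf":           (43.73, 80.71, 63.97, 6.21),
    "adf":           (23.36, 66.57, 36.28, 4.71),
    "adl":           (1.17, 10.70, 3.26, 1.61),
    "hemicellulose": (13.53, 37.47, 27.78, 3.58),
})

WHEAT_STRAW = _profile("wheat_straw", {
    "moisture":      (2.68, 7.05, 4.62, 1.10),
    "cp":            (1.52, 6.75, 3.36, 0.94),
    "ndf":           (64.64, 87.81, 77.27, 5.94),
    "adf":           (35.73, 58.72, 46.79, 4.98),
    "adl":           (4.34, 9.93, 6.92, 1.55),
    "hemicellulose": (23.34, 44.91, 30.58, 3.67),
})

DEFAULT_PROFILES: dict[str, SimulationProfile] = {
    "corn_stover": CORN_STOVER,
    "wheat_straw": WHEAT_STRAW,
}

#: Constituents that are sampled directly; NDF is always derived.
_SAMPLED = ("moisture", "cp", "adf", "adl", "hemicellulose")

_MAX_REDRAWS = 1000


@lru_cache(maxsize=256)
def _matched_parent(mean: float, sd: float, lo: float, hi: float):
    """Parent-normal (mu, sigma) whose [lo, hi]-truncation has the given
    mean and SD.  Cached: profiles reuse the same constants run after run."""
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ProfileError(f"degenerate mean {mean} outside bounds")
        return mean, 0.0

    def resid(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.least_squares(
        resid, x0=[mean, np.log(sd)], xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    if max(abs(r) for r in resid(sol.x)) > 1e-6 * max(sd, 1.0):
        raise ProfileError(
            f"cannot moment-match truncated normal (mean {mean}, sd {sd}, "
            f"bounds [{lo}, {hi}])"
        )
    return float(mu), sigma


def _draw_truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    mu, sigma = _matched_parent(mean, sd, lo, hi)
    if sigma == 0.0:
        rng.random()  # keep the stream layout fixed
        return mu
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    u = rng.random()
    return float(stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma))


def draw_compositions(
    profile: SimulationProfile, n: int, id_prefix: str | None = None
) -> ReferenceTable:
    """Draw ``n`` compositions from the profile's truncated normals.

    Moisture, CP, ADF, ADL and hemicellulose are sampled; NDF is set to
    ADF + hemicellulose exactly; ADL > ADF triggers an ADL redraw.
    Deterministic under the profile seed, with one substream per sample.
    """
    if n < 1:
        raise ProfileError("n must be >= 1")
    prefix = id_prefix if id_prefix is not None else profile.species
    rows = np.empty((n, len(_SAMPLED)))
    for i in range(n):
        rng = np.random.default_rng(
            [profile.seed, _STREAM_COMPOSITIONS, i]
        )
        vals = {}
        for j, name in enumerate(_SAMPLED):
            vals[name] = _draw_truncnorm(
                rng, profile.means[name], profile.sds[name], *profile.bounds[name]
            )
        redraws = 0
        while vals["adl"] > vals["adf"]:
            if redraws >= _MAX_REDRAWS:
                raise ProfileError(
                    "cannot satisfy ADL <= ADF under this profile"
                )
            vals["adl"] = _draw_truncnorm(
                rng, profile.means["adl"], profile.sds["adl"], *profile.bounds["adl"]
            )
            redraws += 1
        rows[i] = [vals[name] for name in _SAMPLED]
    df = pd.DataFrame(rows, columns=list(_SAMPLED))
    df["ndf"] = df["adf"] + df["hemicellulose"]
    df = df[list(CONSTITUENTS)]
    df.index = pd.Index(
        [f"{prefix}_{i:04d}" for i in range(n)], name="sample_id"
    )
    species = pd.Series(profile.species, index=df.index, name="species")
    return ReferenceTable(data=df, species=species)


def simulate_spectra(
    ref: ReferenceTable,
    lib: ComponentLibrary,
    profile: SimulationProfile,
) -> SpectraSet:
    """Forward-simulate absorbance rows for a reference table.

    row_i = b_i * sum_c conc_ic * curve_c  +  a_i  +  t_i * (lam - mid)/span
            + noise,  with b_i ~ N(1, slope_sd), a_i ~ N(0, offset_sd),
    t_i ~ N(0, tilt_sd).  Deterministic under the profile seed.
    """
    names = [c for c in ref.constituents if c in lib.curves]
    missing = set(ref.constituents) - set(lib.curves)
    if missing:
        raise ProfileError(
            f"reference constituents {sorted(missing)} absent from library"
        )
    conc = ref.data[names].to_numpy()
    if np.any(~np.isfinite(conc)):
        raise ProfileError("cannot simulate spectra from missing reference values")
    mix = conc @ lib.matrix(names)  # (n, p)
    grid = lib.grid
    ramp = (grid - 0.5 * (grid[0] + grid[-1])) / (grid[-1] - grid[0])
    n, p = mix.shape
    out = np.empty_like(mix)
    for i in range(n):
        rng = np.random.default_rng([profile.seed, _STREAM_SPECTRA, i])
        b = 1.0 + profile.slope_sd * rng.standard_normal()
        a = profile.offset_sd * rng.standard_normal()
        t = profile.tilt_sd * rng.standard_normal()
        eps = profile.noise_sd * rng.standard_normal(p)
        out[i] = b * mix[i] + a + t * ramp + eps
    return SpectraSet(
        wavelengths=grid.copy(),
        absorbance=out,
        sample_ids=ref.sample_ids,
        species=list(ref.species) if ref.species is not None else None,
    )


def simulate_dataset(
    profile: SimulationProfile,
    n: int,
    lib: ComponentLibrary | None = None,
) -> tuple[SpectraSet, ReferenceTable]:
    """Convenience: compositions + spectra in one call."""
    if lib is None:
        lib = make_component_library()
    ref = draw_compositions(profile, n)
    return simulate_spectra(ref, lib, profile), ref
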