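"""Synthetic lake-survey generator with known ground truth.

Emulates the statistical structure the analysis assumes so every downstream
stage is testable without field data:

* a right-skewed occupancy-frequency distribution across taxa (truncated
  log-normal on occupied-site counts);
* site covariates with positive spatial autocorrelation — Gaussian fields
  with exponential covariance exp(-d/rho) over inter-site distances, mixed
  with independent noise, then mapped to plausible covariate ranges;
* presences of focal-group members driven by a logistic model on
  unit-rescaled covariates (positive total-phosphorus and conductivity
  effects, negative Secchi-depth effect by default), with per-member
  intercept offsets producing a common-to-rare prevalence gradient;
* all remaining taxa placed at random with their sampled occupancy counts.

All randomness flows from a single root seed through ``numpy`` generators;
the same config and seed reproduce the survey exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .types import OccurrenceMatrix, SiteTable
from . import predictors

#: Focal functional group label used by generated surveys.
GROUP_LABEL = "floating"
OTHER_LABEL = "other"

#: Synthetic stand-ins for the focal group's member taxa, common to rare.
MEMBER_TAXA = (
    "Lemna_minor", "Spirodela_polyrhiza", "Wolffia_sp",
    "Azolla_sp", "Eichhornia_crassipes", "Lemna_trisulca",
)

# Per-covariate marginal profiles: transform, param1, param2, (lo, hi) clip.
# lognormal: exp(mu + sigma*z); normal: mean + sd*z.
_PROFILES: dict[str, tuple[str, float, float, tuple[float | None, float | None]]] = {
    "size":      ("lognormal", np.log(20.0), 1.2, (0.5, None)),   # ha
    "shoreline": ("lognormal", np.log(1.5), 0.25, (1.0, None)),
    "depth":     ("lognormal", np.log(4.0), 0.7, (0.3, None)),    # m
    "totalP":    ("lognormal", np.log(0.025), 0.8, (0.001, None)),  # mg/L
    "pH":        ("normal", 7.0, 0.7, (4.0, 10.0)),
    "cond":      ("lognormal", np.log(150.0), 0.6, (10.0, None)),  # uS/cm
    "alk":       ("lognormal", np.log(40.0), 0.8, (1.0, None)),   # mg/L
    "secchi":    ("lognormal", np.log(2.0), 0.5, (0.2, None)),    # m
    "nonFP":     ("lognormal", np.log(14.0), 0.5, (0.0, None)),   # count, rounded
}

# Loadings of each covariate on the two latent spatial fields
# ("chemistry", "morphometry"); the remainder is covariate-specific.
# Chemistry ties cond/alk/pH/totalP together and opposes secchi;
# morphometry ties size/depth/shoreline/secchi together — mimicking the
# correlation structure real surveys show (alkalinity ~ conductivity,
# depth ~ secchi/size), which is what the collinearity screen exists for.
_LOADINGS: dict[str, tuple[float, float]] = {
    "size":      (0.0, 0.80),
    "shoreline": (0.0, 0.40),
    "depth":     (-0.10, 0.80),
    "totalP":    (0.60, -0.20),
    "pH":        (0.70, 0.0),
    "cond":      (0.85, 0.0),
    "alk":       (0.85, -0.10),
    "secchi":    (-0.50, 0.60),
    "nonFP":     (-0.20, 0.30),
}


@dataclass
class SynthConfig:
    """Study conditions for a generated survey.

    Defaults mirror the surveyed system: 176 water bodies, 124 plant taxa,
    a six-member focal group, occupancy counts truncated-log-normal with
    mean ~19 of 176 sites, covariates spatially autocorrelated over ~30 km,
    and logistic effects of +5 (totalP), +5 (cond), -5 (secchi) on
    unit-rescaled covariates.
    """

    n_sites: int = 176
    n_taxa: int = 124
    group_size: int = 6
    # truncated log-normal on occupied-site counts, support [1, n_sites]
    occupancy_location: float = 2.48122
    occupancy_scale: float = 1.0
    # bounding box, decimal degrees (roughly Connecticut)
    lat_range: tuple[float, float] = (41.0, 42.05)
    lon_range: tuple[float, float] = (-73.73, -71.79)
    # exponential-covariance range (km) and iid-noise variance fraction
    spatial_range_km: float = 30.0
    noise_fraction: float = 0.3
    # logistic coefficients on unit-rescaled covariates, intercept under key
    # "intercept"; applied to every group member plus its intercept offset
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "intercept": -2.0, "totalP": 5.0, "cond": 5.0, "secchi": -5.0,
    })
    # per-member intercept offsets, common to rare (calibrated so default
    # conditions yield roughly a 56/31/23/<=4 occupancy pattern)
    member_offsets: tuple[float, ...] = (0.0, -1.1, -1.6, -3.6, -4.0, -4.6)
    boatlaunch_base: float = -1.0
    boatlaunch_slope: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not 1 <= self.group_size <= self.n_taxa:
            raise ValueError("group_size must lie in [1, n_taxa]")
        if self.spatial_range_km < 0:
            raise ValueError("spatial_range_km must be >= 0")
        if not 0 <= self.noise_fraction <= 1:
            raise ValueError("noise_fraction must lie in [0, 1]")
        if (self.lat_range[1] <= self.lat_range[0]
                or self.lon_range[1] <= self.lon_range[0]):
            raise ValueError("degenerate bounding box")
        if len(self.member_offsets) < self.group_size:
            raise ValueError("need one intercept offset per group member")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["member_offsets"] = list(d["member_offsets"])
        return d


def _spatial_field(rng: np.random.Generator, chol: np.ndarray | None,
                   n: int, noise_fraction: float) -> np.ndarray:
    """Unit-variance field: sqrt(1-f) * GP + sqrt(f) * iid noise."""
    eps = rng.standard_normal(n)
    if chol is None or noise_fraction >= 1.0:
        return eps
    gp = chol @ rng.standard_normal(n)
    return np.sqrt(1.0 - noise_fraction) * gp + np.sqrt(noise_fraction) * eps


def generate_sites(config: SynthConfig,
                   rng: np.random.Generator | None = None) -> SiteTable:
    """Simulate site coordinates and spatially structured covariates.

    Coordinates are uniform in the bounding box.  Each covariate is a linear
    blend of two shared latent spatial fields (chemistry, morphometry) and a
    covariate-specific field, each an exponential-covariance Gaussian process
    diluted with iid noise per ``noise_fraction``, then pushed through its
    marginal profile (log-normal or normal with clipping).  ``boatlaunch`` is
    Bernoulli with log-odds increasing in the morphometry field.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_sites
    lat = rng.uniform(*config.lat_range, n)
    lon = rng.uniform(*config.lon_range, n)
    data = pd.DataFrame({
        "site_id": [f"site{i + 1:03d}" for i in range(n)],
        "latitude": lat,
        "longitude": lon,
    })
    chol = None
    if config.spatial_range_km > 0 and config.noise_fraction < 1.0:
        d = np.asarray(predictors.haversine_km(
            lat[:, None], lon[:, None], lat[None, :], lon[None, :]))
        cov = np.exp(-d / config.spatial_range_km)
        cov[np.diag_indices_from(cov)] += 1e-9  # jitter for Cholesky
        chol = np.linalg.cholesky(cov)
    chem = _spatial_field(rng, chol, n, config.noise_fraction)
    morpho = _spatial_field(rng, chol, n, config.noise_fraction)
    for name, (kind, p1, p2, (lo, hi)) in _PROFILES.items():
        a, b = _LOADINGS[name]
        resid = np.sqrt(max(0.0, 1.0 - a * a - b * b))
        z = a * chem + b * morpho + resid * _spatial_field(
            rng, chol, n, config.noise_fraction)
        vals = np.exp(p1 + p2 * z) if kind == "lognormal" else p1 + p2 * z
        vals = np.clip(vals, lo, hi)
        if name == "nonFP":
            vals = np.round(vals)
        data[name] = vals
    p_launch = 1.0 / (1.0 + np.exp(-(config.boatlaunch_base
                                     + config.boatlaunch_slope * morpho)))
    data["boatlaunch"] = (rng.random(n) < p_launch).astype(int)
    return SiteTable(data)


def sample_occupancy_frequencies(config: SynthConfig, n: int,
                                 rng: np.random.Generator | None = None
                                 ) -> np.ndarray:
    """Draw ``n`` occupancy counts from the truncated log-normal law.

    Continuous truncation to [1, n_sites] by inverse-CDF sampling, then
    rounding to the nearest integer; all counts land in [1, n_sites].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dist = stats.lognorm(s=config.occupancy_scale,
                         scale=np.exp(config.occupancy_location))
    fa, fb = dist.cdf(1.0), dist.cdf(float(config.n_sites))
    u = rng.uniform(fa, fb, n)
    counts = np.rint(dist.ppf(u)).astype(int)
    return np.clip(counts, 1, config.n_sites)


def truncated_occupancy_mean(config: SynthConfig) -> float:
    """Exact mean of the rounded, truncated occupancy law (analytic oracle)."""
    dist = stats.lognorm(s=config.occupancy_scale,
                         scale=np.exp(config.occupancy_location))
    n = config.n_sites
    fa, fb = dist.cdf(1.0), dist.cdf(float(n))
    ks = np.arange(1, n + 1)
    lo = np.maximum(ks - 0.5, 1.0)
    hi = np.minimum(ks + 0.5, float(n))
    p = (dist.cdf(hi) - dist.cdf(lo)) / (fb - fa)
    return float((ks * p).sum())


def assemble_random_community(frequencies, n_sites: int,
                              seed: int | np.random.Generator | None = None,
                              taxa: list[str] | None = None,
                              site_ids: list[str] | None = None,
                              group_of: dict[str, str] | None = None,
                              ) -> OccurrenceMatrix:
    """Place each taxon in exactly its occupancy count of sites, at random.

    Taxon i occupies k_i distinct sites drawn uniformly without replacement,
    independently across taxa — the random-assembly assumption of the
    species-pool null model.
    """
    frequencies = np.asarray(frequencies, dtype=int)
    if np.any((frequencies < 0) | (frequencies > n_sites)):
        raise ValueError("occupancy counts must lie in [0, n_sites]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if site_ids is None:
        site_ids = [f"site{i + 1:03d}" for i in range(n_sites)]
    if taxa is None:
        taxa = [f"taxon{i + 1:03d}" for i in range(len(frequencies))]
    presence = np.zeros((n_sites, len(frequencies)), dtype=np.int8)
    for j, k in enumerate(frequencies):
        presence[rng.choice(n_sites, size=k, replace=False), j] = 1
    df = pd.DataFrame(presence, index=pd.Index(site_ids, name="site_id"),
                      columns=taxa)
    return OccurrenceMatrix(df, dict(group_of) if group_of else {})


def generate_group_presence(sites: SiteTable, beta: dict[str, float],
                            rng: np.random.Generator | int | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli presences from a logistic model on unit-rescaled covariates.

    ``beta`` maps covariate names to slopes, with the intercept under
    ``"intercept"``.  Returns ``(presence, true_probabilities)`` so recovery
    tests can compare fits against the generating truth.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    eta = np.full(sites.n_sites, float(beta.get("intercept", 0.0)))
    for name, slope in beta.items():
        if name == "intercept":
            continue
        try:
            x = sites.covariate(name)
        except KeyError:
            raise KeyError(f"coefficient names unknown covariate {name!r}") from None
        eta = eta + slope * predictors.rescale_unit_interval(x)
    p = 1.0 / (1.0 + np.exp(-eta))
    presence = (rng.random(sites.n_sites) < p).astype(np.int8)
    return presence, p


def generate_survey(config: SynthConfig
                    ) -> tuple[SiteTable, OccurrenceMatrix, dict]:
    """Full synthetic survey: sites, occurrences, and generating truth.

    Group members get logistic presences (shared slopes, per-member intercept
    offsets); the remaining taxa are placed at random with sampled occupancy
    counts.  Derived spatial predictors (neighbour counts within 1 and 10 km,
    distance to the nearest water body occupied by each of the three most
    common members) are appended to the site table, mirroring what a GIS
    workflow would measure.  Returns metadata with the seed, the generating
    coefficients and the per-member true probabilities.
    """
    root = np.random.default_rng(config.seed)
    streams = root.spawn(4)
    sites = generate_sites(config, streams[0])

    member_taxa = list(MEMBER_TAXA[:config.group_size])
    presences = {}
    true_probs = {}
    for m, taxon in enumerate(member_taxa):
        beta = dict(config.coefficients)
        beta["intercept"] = beta.get("intercept", 0.0) + config.member_offsets[m]
        presences[taxon], true_probs[taxon] = generate_group_presence(
            sites, beta, streams[1])

    n_other = config.n_taxa - config.group_size
    freqs = sample_occupancy_frequencies(config, n_other, streams[2])
    other = assemble_random_community(
        freqs, config.n_sites, streams[3],
        taxa=[f"taxon{i + 1:03d}" for i in range(n_other)],
        site_ids=list(sites.site_ids))

    presence = pd.DataFrame(presences, index=pd.Index(list(sites.site_ids),
                                                      name="site_id"))
    presence = pd.concat([presence, other.presence], axis=1)
    group_of = {t: GROUP_LABEL for t in member_taxa}
    group_of.update({t: OTHER_LABEL for t in other.taxa})
    occ = OccurrenceMatrix(presence, group_of)

    # derived spatial predictors, as the real workflow computes them
    dist = predictors.pairwise_distances_km(sites)
    sites.data["lakes1km"] = predictors.neighbor_counts(sites, 1.0, dist).to_numpy()
    sites.data["lakes10km"] = predictors.neighbor_counts(sites, 10.0, dist).to_numpy()
    for code, taxon in zip(("distLM", "distSP", "distW"), member_taxa[:3]):
        sites.data[code] = predictors.nearest_occupied_distances(
            sites, occ, taxon, dist).to_numpy()

    meta = {
        "seed": config.seed,
        "config": config.to_dict(),
        "member_taxa": member_taxa,
        "coefficients": dict(config.coefficients),
        "member_offsets": list(config.member_offsets[:config.group_size]),
        "true_probabilities": {t: true_probs[t].tolist() for t in member_taxa},
    }
    return sites, occ, meta
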