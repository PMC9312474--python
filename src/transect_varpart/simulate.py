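"""Synthetic video-transect studies with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline can be exercised and scored against
truth without any field data:

* a balanced hierarchical design (islands / locations / transects) with
  every transect covered back-to-back by each observer;
* species-specific latent log-abundances with Gaussian random effects for
  Location, Transect, Observer and the Observer x Location /
  Observer x Transect interactions, plus an AR(1) carryover across the 18
  ordered passes of a transect (fish lingering between passes);
* COM-Poisson counts (per-species dispersion, two-thirds of species
  overdispersed and one-third underdispersed by default);
* structural zeros per (species, location) — habitat unsuitability;
* binomial detection thinning with turbidity-dependent detectability and an
  order effect on the detection odds (attraction or deterrence by the
  observer);
* gamma clump multipliers for schooling species; and
* per-detection time stamps with short on-screen intervals, so MinCount
  (MaxN) and distance-window splitting are meaningful.

Randomness uses one root :class:`numpy.random.SeedSequence` with a child
stream per species (design-level draws use child 0), so adding species to a
configuration does not reshuffle earlier species' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compoisson import com_poisson_sample
from .core import DetectionEvent, ObservationRecord, StudyDesign


@dataclass(frozen=True)
class SpeciesTraits:
    """Species-level parameters of the generator.

    ``nu`` is the COM-Poisson shape (nu < 1 overdispersed, nu > 1
    underdispersed); ``order_effect`` is the log-odds change in detection
    per pass (negative = deterred by observers, positive = attracted);
    ``schooling_k`` is the gamma shape of the clump-size multiplier
    (``math.inf`` disables schooling).
    """

    name: str
    base_log_abundance: float = 0.8
    island_effect: tuple[float, ...] = (0.0, 0.0)
    nu: float = 1.0
    structural_zero_prob: float = 0.0
    detectability: float = 1.0
    order_effect: float = 0.0
    ar1_rho: float = 0.0
    schooling_k: float = math.inf
    turbidity_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if not 0 < self.detectability <= 1:
            raise ValueError("detectability must be in (0, 1]")
        if not 0 <= self.structural_zero_prob <= 1:
            raise ValueError("structural_zero_prob must be in [0, 1]")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.schooling_k <= 0:
            raise ValueError("schooling_k must be positive (math.inf disables)")
        if self.turbidity_sensitivity < 0:
            raise ValueError("turbidity_sensitivity must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Design, variance components (latent log scale) and species traits."""

    design: StudyDesign = field(default_factory=StudyDesign)
    n_species: int = 36
    sigma2_location: float = 0.40
    sigma2_transect: float = 0.25
    sigma2_observer: float = 0.02
    sigma2_obs_location: float = 0.05
    sigma2_obs_transect: float = 0.10
    sigma2_residual: float = 0.30
    turbidity: tuple[int, ...] | None = None  # ordinal grade per transect
    seed: int = 0
    species_traits: tuple[SpeciesTraits, ...] | None = None
    mean_duration_s: float = 276.0
    sd_duration_s: float = 42.0

    def __post_init__(self) -> None:
        for name in (
            "sigma2_location",
            "sigma2_transect",
            "sigma2_observer",
            "sigma2_obs_location",
            "sigma2_obs_transect",
            "sigma2_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if self.turbidity is not None and len(self.turbidity) != self.design.n_transects:
            raise ValueError("turbidity must have one grade per transect")

    @property
    def variance_components(self) -> dict[str, float]:
        return {
            "location": self.sigma2_location,
            "transect": self.sigma2_transect,
            "observer": self.sigma2_observer,
            "location:observer": self.sigma2_obs_location,
            "transect:observer": self.sigma2_obs_transect,
            "Residual": self.sigma2_residual,
        }


@dataclass
class SimulationTruth:
    """Every latent draw and parameter of one simulated study."""

    config: SimulationConfig
    traits: list[SpeciesTraits]
    turbidity: np.ndarray                      # grade per transect
    latent: dict[str, dict[str, np.ndarray]]   # species -> draw name -> array
    eta: np.ndarray                            # species x observations latent log-mean
    true_counts: np.ndarray                    # species x observations
    detected_counts: np.ndarray                # species x observations


def default_traits(n_species: int, design: StudyDesign, rng: np.random.Generator
                   ) -> list[SpeciesTraits]:
    """Trait draws emulating a reef-fish community.

    Every third species is underdispersed (nu > 1) so the community shows
    the one-third / two-thirds dispersion mix; a minority of species school,
    carry temporal dependence, or react to observers.
    """
    traits = []
    for s in range(n_species):
        under = s % 3 == 0
        nu = float(np.exp(rng.normal(np.log(1.6), 0.15))) if under else float(
            np.exp(rng.normal(np.log(0.65), 0.15)))
        reaction = rng.random()
        if reaction < 0.15:
            gamma = -0.15
        elif reaction < 0.30:
            gamma = 0.15
        else:
            gamma = 0.0
        traits.append(
            SpeciesTraits(
                name=f"sp{s:02d}",
                base_log_abundance=float(rng.normal(0.6, 0.8)),
                island_effect=tuple(rng.normal(0.0, 0.5, size=design.n_islands)),
                nu=nu,
                structural_zero_prob=float(rng.uniform(0.0, 0.25)),
                detectability=float(rng.beta(8, 2)),
                order_effect=gamma,
                ar1_rho=0.4 if rng.random() < 0.2 else 0.0,
                schooling_k=0.5 if rng.random() < 0.2 else math.inf,
                turbidity_sensitivity=0.15,
            )
        )
    return traits


def _observer_order(transect_index: int, n_observers: int) -> list[int]:
    """Rotate the sequence of observers across transects so the temporal
    block an observer occupies is not confounded with the observer."""
    return [(transect_index + k) % n_observers for k in range(n_observers)]


def simulate_study(config: SimulationConfig
                   ) -> tuple[list[ObservationRecord], SimulationTruth]:
    """Generate one study: observation records plus the full truth."""
    design = config.design
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + config.n_species)
    rng_design = np.random.default_rng(children[0])

    n_isl = design.n_islands
    n_loc = n_isl * design.locations_per_island
    n_tr = design.n_transects
    n_obs_f = design.n_observers
    n_pass = design.passes_per_transect
    n_total = design.n_observations

    # design-level structure -------------------------------------------------
    if config.turbidity is None:
        turbidity = rng_design.integers(1, 4, size=n_tr)
    else:
        turbidity = np.asarray(config.turbidity, dtype=int)
    durations = np.clip(
        rng_design.normal(config.mean_duration_s, config.sd_duration_s, size=n_total),
        120.0, None,
    )
    traits_rng = np.random.default_rng(rng_design.integers(0, 2**31 - 1))
    if config.species_traits is None:
        traits = default_traits(config.n_species, design, traits_rng)
    else:
        traits = list(config.species_traits)
        if len(traits) != config.n_species:
            raise ValueError("species_traits length must equal n_species")

    # observation skeleton ---------------------------------------------------
    obs_island = np.empty(n_total, dtype=int)
    obs_loc = np.empty(n_total, dtype=int)      # global location index
    obs_tr = np.empty(n_total, dtype=int)       # global transect index
    obs_observer = np.empty(n_total, dtype=int)
    obs_order = np.empty(n_total, dtype=int)    # 1..n_pass within transect
    obs_repeat = np.empty(n_total, dtype=int)   # 1..repeats within observer
    idx = 0
    for isl in range(n_isl):
        for loc in range(design.locations_per_island):
            gloc = isl * design.locations_per_island + loc
            for tr in range(design.transects_per_location):
                gtr = gloc * design.transects_per_location + tr
                order = 0
                for obs in _observer_order(gtr, n_obs_f):
                    for rep in range(design.repeats_per_observer):
                        order += 1
                        obs_island[idx] = isl
                        obs_loc[idx] = gloc
                        obs_tr[idx] = gtr
                        obs_observer[idx] = obs
                        obs_order[idx] = order
                        obs_repeat[idx] = rep + 1
                        idx += 1

    tr_turb = turbidity[obs_tr]
    turb_scale = (tr_turb - 1) / 2.0  # grades 1..3 -> 0, .5, 1

    # species-level draws ----------------------------------------------------
    eta = np.zeros((config.n_species, n_total))
    true_counts = np.zeros((config.n_species, n_total), dtype=int)
    det_counts = np.zeros((config.n_species, n_total), dtype=int)
    latent: dict[str, dict[str, np.ndarray]] = {}
    events_per_obs: list[list[DetectionEvent]] = [[] for _ in range(n_total)]

    for s, tr_s in enumerate(traits):
        rng = np.random.default_rng(children[1 + s])
        u_loc = rng.normal(0, np.sqrt(config.sigma2_location), size=n_loc)
        u_tr = rng.normal(0, np.sqrt(config.sigma2_transect), size=n_tr)
        u_obs = rng.normal(0, np.sqrt(config.sigma2_observer), size=n_obs_f)
        u_ol = rng.normal(0, np.sqrt(config.sigma2_obs_location), size=(n_obs_f, n_loc))
        u_ot = rng.normal(0, np.sqrt(config.sigma2_obs_transect), size=(n_obs_f, n_tr))
        zero_loc = rng.random(n_loc) < tr_s.structural_zero_prob

        # AR(1) residual series per transect across the ordered passes
        eps = np.empty((n_tr, n_pass))
        sd = np.sqrt(config.sigma2_residual)
        rho = tr_s.ar1_rho
        innov = rng.normal(0, 1, size=(n_tr, n_pass))
        eps[:, 0] = sd * innov[:, 0]
        for t in range(1, n_pass):
            eps[:, t] = rho * eps[:, t - 1] + sd * np.sqrt(1 - rho**2) * innov[:, t]

        eta_s = (
            tr_s.base_log_abundance
            + np.asarray(tr_s.island_effect)[obs_island]
            + u_loc[obs_loc]
            + u_tr[obs_tr]
            + u_obs[obs_observer]
            + u_ol[obs_observer, obs_loc]
            + u_ot[obs_observer, obs_tr]
            + eps[obs_tr, obs_order - 1]
        )
        lam = np.exp(eta_s)
        if math.isfinite(tr_s.schooling_k):
            lam = lam * rng.gamma(tr_s.schooling_k, 1.0 / tr_s.schooling_k, size=n_total)
        # cap the implied expected count (~lam^(1/nu)) at ~800 individuals
        # per pass: rare latent spikes would otherwise imply absurd schools
        lam = np.minimum(lam, 800.0 ** tr_s.nu)
        n_true = com_poisson_sample(lam, tr_s.nu, rng)
        n_true = np.where(zero_loc[obs_loc], 0, n_true)

        # detection: turbidity-scaled detectability, order-tilted odds
        p0 = np.clip(tr_s.detectability * (1 - tr_s.turbidity_sensitivity * turb_scale),
                     1e-6, 1.0)
        logit = np.log(p0 / (1 - p0 + 1e-12))
        logit = logit + tr_s.order_effect * (obs_order - (n_pass + 1) / 2.0)
        p_det = 1.0 / (1.0 + np.exp(-logit))
        n_det = rng.binomial(n_true, np.clip(p_det, 0.0, 1.0))

        eta[s] = eta_s
        true_counts[s] = n_true
        det_counts[s] = n_det
        latent[tr_s.name] = {
            "u_location": u_loc, "u_transect": u_tr, "u_observer": u_obs,
            "u_obs_location": u_ol, "u_obs_transect": u_ot,
            "structural_zero": zero_loc, "eps": eps,
        }

        # detection events with time stamps; schooling species clump
        for i in np.nonzero(n_det)[0]:
            remaining = int(n_det[i])
            clumps = []
            if math.isfinite(tr_s.schooling_k):
                while remaining > 0:
                    size = min(remaining, 1 + int(rng.geometric(0.35)))
                    clumps.append(size)
                    remaining -= size
            else:
                clumps = [1] * remaining
            for size in clumps:
                t0 = rng.uniform(0, durations[i])
                span = rng.uniform(2.0, 10.0)
                events_per_obs[i].append(
                    DetectionEvent(
                        species_id=tr_s.name,
                        t_start=float(t0),
                        t_end=float(min(t0 + span, durations[i])),
                        n_individuals=int(size),
                    )
                )

    # assemble records -------------------------------------------------------
    records = []
    for i in range(n_total):
        records.append(
            ObservationRecord(
                island=f"island{obs_island[i] + 1}",
                location=f"loc{obs_loc[i] + 1:02d}",
                transect=f"tr{obs_tr[i] + 1:02d}",
                observer=f"obs{obs_observer[i] + 1}",
                repeat_index=int(obs_repeat[i]),
                order_index=int(obs_order[i]),
                direction="forward" if obs_order[i] % 2 == 1 else "reverse",
                duration_s=float(durations[i]),
                turbidity_grade=int(tr_turb[i]),
                events=sorted(events_per_obs[i], key=lambda e: e.t_start),
            )
        )

    truth = SimulationTruth(
        config=config,
        traits=traits,
        turbidity=turbidity,
        latent=latent,
        eta=eta,
        true_counts=true_counts,
        detected_counts=det_counts,
    )
    return records, truth


def poisson_null_config(n_species: int = 6, seed: int = 0, base: float = 1.0,
                        design: StudyDesign | None = None) -> SimulationConfig:
    """Degenerate configuration: no random effects, perfect detection,
    Poisson counts — every pass of a transect has identical expected counts."""
    design = design or StudyDesign()
    traits = tuple(
        SpeciesTraits(name=f"sp{s:02d}", base_log_abundance=base,
                      island_effect=(0.0,) * design.n_islands)
        for s in range(n_species)
    )
    return SimulationConfig(
        design=design, n_species=n_species,
        sigma2_location=0.0, sigma2_transect=0.0, sigma2_observer=0.0,
        sigma2_obs_location=0.0, sigma2_obs_transect=0.0, sigma2_residual=0.0,
        turbidity=tuple([1] * design.n_transects), seed=seed,
        species_traits=traits,
    )
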