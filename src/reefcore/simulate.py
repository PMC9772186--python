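"""Synthetic cores, temperature loggers, and genotype cohorts with ground truth.

Generative stand-ins for the study's three data streams, so every downstream
stage is testable against known truth:

* ``simulate_core`` — annual density banding (one sinusoidal high/low couplet
  per year mapped through cumulative extension) with optional injected
  high-density stress anomalies and Gaussian noise;
* ``simulate_logger`` — seasonal (365.25 d) + diurnal (24 h) sinusoids around
  a site mean, with noise and offset anomaly windows;
* ``simulate_genotypes`` — K source populations under the Balding-Nichols
  model (per-population allele frequencies drawn around shared ancestral
  frequencies with drift ``F``), unadmixed or admixed individuals, uniform
  missingness;
* ``simulate_cohort`` — colonies with a lineage, a habitat, a core simulated
  from the lineage's template (stress events sampled per lineage x habitat
  probability) and genotypes from the lineage, joined in a truth table.

All generators are deterministic under a fixed seed; one seed threads to all
sub-generators via named substreams.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .densitometry import DensityProfile
from .popgen import MISSING, GenotypeMatrix
from .thermal import TemperatureSeries

__all__ = [
    "CoreSimSpec",
    "LoggerSimSpec",
    "PopSimSpec",
    "CoreTruth",
    "simulate_core",
    "simulate_logger",
    "simulate_genotypes",
    "simulate_cohort",
]

#: Default lineage names matching the four-cluster structure of the study
#: system (two Rock Island-associated, two outer reef-associated lineages).
LINEAGES = ("DB", "LB", "PI", "RD")
HABITATS = ("Rock Island", "outer reef")


def _rng(seed, *key: str) -> np.random.Generator:
    """Named substream: one top-level seed, independent stream per stage."""
    salt = [int.from_bytes(k.encode(), "little") % (2**32) for k in key]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(salt)))


# ---------------------------------------------------------------------------
# Cores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreSimSpec:
    """Parameters of one synthetic skeletal core.

    ``extension_by_year`` (cm/yr) is a scalar or a sequence ordered from the
    topmost (most recent complete) year downward; ``stress_events`` is a list
    of ``(year, amplitude, thickness_mm)`` with amplitude in units of the
    clean-profile SD.  ``collection_year`` anchors calendar years: the
    topmost band is ``collection_year - 1``.
    """

    n_years: int = 15
    extension_by_year: float | tuple = 1.0
    mean_density: float = 1.2
    annual_density_amplitude: float = 0.15
    noise_sd: float = 0.0
    sample_spacing: float = 0.1
    stress_events: tuple = ()
    collection_year: int = 2012
    seed: int | None = None

    def extensions_mm(self) -> np.ndarray:
        ext = np.asarray(
            np.broadcast_to(self.extension_by_year, (self.n_years,)), dtype=float
        )
        if np.any(ext <= 0):
            raise ValueError("extension values must be positive")
        return ext * 10.0  # cm/yr -> mm/yr

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")
        self.extensions_mm()
        for year, amp, thick in self.stress_events:
            if thick <= 0:
                raise ValueError("stress event thickness must be positive")
            if not np.isfinite(amp):
                raise ValueError("stress event amplitude must be finite")
            lo = self.collection_year - self.n_years
            if not lo <= year < self.collection_year:
                raise ValueError(
                    f"stress event year {year} outside simulated span "
                    f"{lo}-{self.collection_year - 1}"
                )


@dataclass(frozen=True)
class CoreTruth:
    """Ground truth for a simulated core."""

    years: np.ndarray  # descending, topmost band first
    boundaries_mm: np.ndarray  # length n_years + 1, starting at 0
    extensions_cm: np.ndarray
    stress_intervals: list  # (start_mm, end_mm, year)
    baseline_sd: float


def _tukey_bump(z: np.ndarray, center: float, thickness: float, taper: float = 0.5):
    """Flat-topped tapered-cosine anomaly with compact support = thickness.

    Stress bands are regions of uniformly elevated density with tapered
    edges; the flat top keeps the above-threshold run close to the nominal
    thickness.
    """
    half = thickness / 2.0
    x = np.abs(z - center) / half  # 0 at center, 1 at support edge
    w = np.zeros_like(z)
    flat = x <= 1.0 - taper
    edge = (x > 1.0 - taper) & (x < 1.0)
    w[flat] = 1.0
    s = (x[edge] - (1.0 - taper)) / taper
    w[edge] = 0.5 * (1.0 + np.cos(np.pi * s))
    return w


def simulate_core(spec: CoreSimSpec) -> tuple[DensityProfile, CoreTruth]:
    """Simulate one density profile plus its ground truth.

    Density = mean + annual sinusoid (one cycle per year, troughs at year
    boundaries, mapped through cumulative extension) + Gaussian noise; each
    stress event adds a smooth positive anomaly of the stated thickness whose
    peak is ``amplitude`` clean-profile SDs, centered at the middle of its
    year's band.
    """
    ext_mm = spec.extensions_mm()
    boundaries = np.concatenate([[0.0], np.cumsum(ext_mm)])
    total_mm = boundaries[-1]
    n = int(round(total_mm / spec.sample_spacing))
    z = np.arange(n) * spec.sample_spacing
    years = spec.collection_year - 1 - np.arange(spec.n_years)

    band = np.clip(np.searchsorted(boundaries, z, side="right") - 1, 0, spec.n_years - 1)
    # Fraction of the calendar year elapsed: depth grows with age, so the
    # bottom of a band is the start of its year.
    frac = 1.0 - (z - boundaries[band]) / ext_mm[band]
    density = spec.mean_density - spec.annual_density_amplitude * np.cos(
        2.0 * np.pi * frac
    )

    # Clean-profile SD defines the anomaly amplitude unit.
    sine_sd = spec.annual_density_amplitude / np.sqrt(2.0)
    baseline_sd = float(np.hypot(sine_sd, spec.noise_sd))

    intervals = []
    for year, amp, thick in spec.stress_events:
        b = int(spec.collection_year - 1 - year)
        center = 0.5 * (boundaries[b] + boundaries[b + 1])
        density = density + amp * baseline_sd * _tukey_bump(z, center, thick)
        lo = max(0.0, center - thick / 2.0)
        hi = min(total_mm, center + thick / 2.0)
        intervals.append((lo, hi, int(year)))

    if spec.noise_sd > 0:
        density = density + _rng(spec.seed, "core-noise").normal(
            0.0, spec.noise_sd, size=n
        )
    density = np.maximum(density, 1e-3)

    profile = DensityProfile(
        core_id=f"sim-{spec.seed}" if spec.seed is not None else "sim",
        positions=z,
        density=density,
        collection_date=_dt.date(spec.collection_year, 1, 1),
    )
    truth = CoreTruth(
        years=years,
        boundaries_mm=boundaries,
        extensions_cm=ext_mm / 10.0,
        stress_intervals=sorted(intervals),
        baseline_sd=baseline_sd,
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Loggers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoggerSimSpec:
    """Parameters of one synthetic temperature logger record.

    Defaults emulate an outer-reef Palau site (mean 29.11 degC); a Rock
    Island analogue uses ``site_mean=30.29`` and a larger diurnal amplitude.
    ``anomaly_events`` is a list of ``(start, end, offset_c)`` date windows.
    """

    site_id: str = "site"
    habitat: str = "outer reef"
    site_mean: float = 29.11
    seasonal_amplitude: float = 0.9
    diurnal_amplitude: float = 0.16
    noise_sd: float = 0.05
    cadence_min: int = 30
    start: str = "2011-01-01"
    end: str = "2013-01-01"
    anomaly_events: tuple = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diurnal_amplitude < 0:
            raise ValueError("diurnal_amplitude must be >= 0")
        if (24 * 60) % self.cadence_min != 0:
            raise ValueError("cadence must divide 24 h evenly")
        if pd.Timestamp(self.end) - pd.Timestamp(self.start) < pd.Timedelta(days=1):
            raise ValueError("span must be at least one day")


def simulate_logger(spec: LoggerSimSpec) -> TemperatureSeries:
    """Simulate one logger series: seasonal + diurnal sinusoids + noise."""
    idx = pd.date_range(
        spec.start, spec.end, freq=f"{spec.cadence_min}min", inclusive="left"
    )
    hours = (idx - idx[0]) / pd.Timedelta(hours=1)
    t = hours.to_numpy(dtype=float)
    temp = (
        spec.site_mean
        + spec.seasonal_amplitude * np.sin(2.0 * np.pi * t / (365.25 * 24.0))
        + spec.diurnal_amplitude * np.sin(2.0 * np.pi * t / 24.0)
    )
    if spec.noise_sd > 0:
        temp = temp + _rng(spec.seed, "logger-noise", spec.site_id).normal(
            0.0, spec.noise_sd, size=len(idx)
        )
    for start, end, offset in spec.anomaly_events:
        mask = (idx >= pd.Timestamp(start)) & (idx < pd.Timestamp(end))
        temp[mask] += offset
    return TemperatureSeries(
        site_id=spec.site_id,
        habitat=spec.habitat,
        data=pd.Series(temp, index=idx, name="temp_c"),
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopSimSpec:
    """Parameters of a K-population Balding-Nichols genotype simulation.

    ``divergence_F`` (scalar or one value per population, each in (0, 1)) is
    the target pairwise Nei's FST between populations: per-population allele
    frequencies are drawn around shared ancestral frequencies with a
    Balding-Nichols drift parameter calibrated to ``2F / (1 + F)`` so that
    the expected pairwise Nei's FST between two populations with target F
    equals F (the raw drift parameter would yield ``F / (2 - F)``).
    ``admixture_mix`` is the fraction of individuals whose ancestry vector is
    drawn from a symmetric Dirichlet(1) instead of being a unit vector;
    ``n_alleles`` > 2 switches to multiallelic (microsatellite-like) loci.
    """

    K: int = 4
    divergence_F: float | tuple = 0.3
    n_per_pop: int | tuple = 50
    n_loci: int = 300
    n_alleles: int = 2
    admixture_mix: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None

    def pop_sizes(self) -> np.ndarray:
        return np.asarray(np.broadcast_to(self.n_per_pop, (self.K,)), dtype=int)

    def target_fst(self) -> np.ndarray:
        return np.asarray(np.broadcast_to(self.divergence_F, (self.K,)), dtype=float)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not np.all((self.target_fst() > 0.0) & (self.target_fst() < 1.0)):
            raise ValueError("divergence_F must lie in (0, 1)")
        if self.n_alleles < 2:
            raise ValueError("n_alleles must be >= 2")
        if not 0.0 <= self.admixture_mix <= 1.0:
            raise ValueError("admixture_mix must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def _balding_nichols_freqs(spec: PopSimSpec, rng: np.random.Generator):
    """Per-population allele frequencies (L, K, m) around ancestral (L, m).

    The per-population drift parameter is calibrated to ``2F / (1 + F)`` so
    that the expected pairwise multi-locus Nei's FST between populations
    matches the target ``divergence_F`` (see PopSimSpec).
    """
    L, K, m = spec.n_loci, spec.K, spec.n_alleles
    F = spec.target_fst()
    drift = 2.0 * F / (1.0 + F)
    scale = (1.0 - drift) / drift  # per population, shape (K,)
    if m == 2:
        anc = rng.uniform(0.1, 0.9, size=L)
        p = rng.beta(
            anc[:, None] * scale[None, :],
            (1.0 - anc[:, None]) * scale[None, :],
            size=(L, K),
        )
        freqs = np.stack([p, 1.0 - p], axis=2)
        ancestral = np.stack([anc, 1.0 - anc], axis=1)
    else:
        ancestral = rng.dirichlet(np.full(m, 2.0), size=L)
        freqs = np.empty((L, K, m))
        for l in range(L):
            for k in range(K):
                freqs[l, k] = rng.dirichlet(
                    np.maximum(ancestral[l] * scale[k], 1e-6)
                )
    return ancestral, freqs


def simulate_genotypes(
    spec: PopSimSpec,
    sample_prefix: str = "ind",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate genotypes and return them with the true ancestry matrix Q.

    Unadmixed individuals draw both gene copies from their population's
    frequencies; admixed individuals draw each copy from a population chosen
    per their ancestry vector.  Missing cells are inserted uniformly at
    random at ``missing_rate``.
    """
    rng = _rng(spec.seed, "genotypes")
    sizes = spec.pop_sizes()
    n = int(sizes.sum())
    _, freqs = _balding_nichols_freqs(spec, rng)  # (L, K, m)

    Q = np.zeros((n, spec.K))
    pop_of = np.repeat(np.arange(spec.K), sizes)
    for i in range(n):
        Q[i, pop_of[i]] = 1.0
    if spec.admixture_mix > 0:
        mixed = rng.random(n) < spec.admixture_mix
        Q[mixed] = rng.dirichlet(np.ones(spec.K), size=int(mixed.sum()))

    calls = np.empty((n, spec.n_loci, 2), dtype=np.int32)
    for c in range(2):
        src = np.array([rng.choice(spec.K, size=spec.n_loci, p=Q[i]) for i in range(n)])
        u = rng.random((n, spec.n_loci))
        cum = np.cumsum(freqs, axis=2)  # (L, K, m)
        # allele = first index where cumulative frequency exceeds u
        cu = cum[np.arange(spec.n_loci)[None, :], src, :]  # (n, L, m)
        calls[:, :, c] = (u[:, :, None] > cu).sum(axis=2)

    if spec.missing_rate > 0:
        miss = rng.random((n, spec.n_loci)) < spec.missing_rate
        calls[miss] = MISSING

    samples = [f"{sample_prefix}{i:04d}" for i in range(n)]
    loci = [f"locus{l:04d}" for l in range(spec.n_loci)]
    if spec.n_alleles == 2:
        alleles = [["A", "T"] for _ in range(spec.n_loci)]
    else:
        alleles = [
            [150 + 2 * a for a in range(spec.n_alleles)] for _ in range(spec.n_loci)
        ]
    g = GenotypeMatrix(samples=samples, loci=loci, alleles=alleles, calls=calls)
    return g, Q


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    pop: PopSimSpec,
    core_templates: dict[str, CoreSimSpec] | None = None,
    stress_prob: dict | float = 0.0,
    habitat_prob: dict[str, float] | float = 0.5,
    event_year: int = 1998,
    lineage_names: tuple = LINEAGES,
    colony_density_sd: float = 0.12,
    colony_extension_sd: float = 0.12,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, list[DensityProfile], pd.DataFrame]:
    """Simulate a cohort of colonies with genotypes, cores and a truth table.

    Each colony belongs to one of ``pop.K`` lineages; its habitat is Rock
    Island with probability ``habitat_prob`` (scalar or per-lineage dict); its
    core is simulated from the lineage's template with the colony's own mean
    density and extension drawn around the template values
    (``colony_density_sd`` g/cm^3 and ``colony_extension_sd`` cm/yr of
    colony-to-colony spread, as massive *Porites* colonies vary), plus a
    stress event in ``event_year`` sampled with probability
    ``stress_prob[lineage][habitat]`` (or a scalar); its genotypes come from
    the lineage's allele frequencies.  Returns ``(genotypes, profiles,
    truth)`` where ``truth`` has one row per colony: id, lineage, habitat,
    the colony's true growth parameters, and the stress-band truth flag.
    """
    names = list(lineage_names)[: pop.K]
    if len(names) != pop.K:
        raise ValueError("need one lineage name per population")
    if core_templates is None:
        core_templates = {name: CoreSimSpec(noise_sd=0.05) for name in names}
    for name in names:
        if name not in core_templates:
            raise ValueError(f"missing core template for lineage {name!r}")

    def _prob(table, lineage, habitat):
        if isinstance(table, dict):
            val = table[lineage]
            val = val[habitat] if isinstance(val, dict) else val
        else:
            val = table
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"probability {val} outside [0, 1]")
        return float(val)

    gen_spec = replace(pop, seed=_rng(seed, "cohort-genotypes").integers(2**31))
    genotypes, Q = simulate_genotypes(gen_spec, sample_prefix="colony")

    rng = _rng(seed, "cohort-assign")
    sizes = pop.pop_sizes()
    lineage_of = np.repeat(np.arange(pop.K), sizes)
    profiles: list[DensityProfile] = []
    rows = []
    for i, sample in enumerate(genotypes.samples):
        lineage = names[lineage_of[i]]
        p_ri = _prob(habitat_prob, lineage, None)
        habitat = HABITATS[0] if rng.random() < p_ri else HABITATS[1]
        p_stress = _prob(stress_prob, lineage, habitat)
        stressed = bool(rng.random() < p_stress)
        template = core_templates[lineage]
        events = tuple(template.stress_events)
        if stressed:
            events = events + ((event_year, 4.0, 2.0),)
        density_i = max(0.3, template.mean_density + rng.normal(0.0, colony_density_sd))
        ext_i = np.maximum(
            0.2,
            np.asarray(template.extensions_mm()) / 10.0
            + rng.normal(0.0, colony_extension_sd),
        )
        spec_i = replace(
            template,
            mean_density=density_i,
            extension_by_year=tuple(ext_i),
            stress_events=events,
            seed=int(rng.integers(2**31)),
        )
        profile, truth = simulate_core(spec_i)
        profile = DensityProfile(
            core_id=sample,
            positions=profile.positions,
            density=profile.density,
            collection_date=profile.collection_date,
        )
        profiles.append(profile)
        rows.append(
            {
                "id": sample,
                "lineage": lineage,
                "habitat": habitat,
                "true_mean_density": density_i,
                "true_extension_cm": float(np.mean(ext_i)),
                f"true_stress_{event_year}": stressed,
            }
        )
    meta = pd.DataFrame(rows).set_index("id")
    genotypes = GenotypeMatrix(
        samples=genotypes.samples,
        loci=genotypes.loci,
        alleles=genotypes.alleles,
        calls=genotypes.calls,
        metadata=meta,
    )
    return genotypes, profiles, meta.reset_index()
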