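"""Synthetic residue time series emulating a stored-rice pesticide study.

The emulated design: five pesticides (imidacloprid, carbaryl, fenitrothion,
chlorpyrifos-methyl, deltamethrin) each observed daily for 30 days under eight
storage-condition series — 25/30/35/40 °C at 65 % relative humidity and
65/70/75/80 % RH at 25 °C (the 25 °C / 65 % arm belongs to both sweeps and is
counted twice), giving 5 × 8 × 30 = 1200 records.

Decay is bi-exponential (a fast compartment that dominates the first week and
a slow tail, so curves flatten after about day 7; chlorpyrifos-methyl gets a
smaller fast rate so it flattens near day 15).  The fast rate responds to
temperature and humidity through a Gaussian in each factor, peaking at a
critical temperature/humidity so degradation first accelerates and then slows
as either factor keeps rising.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StorageCondition",
    "PesticideProfile",
    "ResidueSeries",
    "StudyDesign",
    "DEFAULT_PROFILES",
    "degradation_rate",
    "simulate_series",
    "generate_study_dataset",
    "generate_tiered_m_samples",
]


@dataclass(frozen=True)
class StorageCondition:
    """A storage climate: temperature in °C and relative humidity in %."""

    temperature_C: float
    rh_pct: float

    def __post_init__(self) -> None:
        if not 0.0 < self.temperature_C < 60.0:
            raise ValueError(
                f"temperature_C must lie in (0, 60) °C, got {self.temperature_C}"
            )
        if not 0.0 < self.rh_pct <= 100.0:
            raise ValueError(f"rh_pct must lie in (0, 100] %, got {self.rh_pct}")


@dataclass(frozen=True)
class PesticideProfile:
    """Degradation parameters for one pesticide.

    ``C0`` is the initial concentration (mg/kg).  The decay curve is
    ``C(t) = C0 * (f * exp(-k_f t) + (1 - f) * exp(-k_slow t))`` where the fast
    rate ``k_f`` depends on the storage condition (see
    :func:`degradation_rate`) and peaks at ``k_base`` when the condition sits
    at ``(T_opt, H_opt)``.  ``noise_sd`` is the relative standard deviation of
    multiplicative lognormal observation noise.
    """

    name: str
    C0: float
    fast_fraction: float
    k_base: float
    k_slow: float
    T_opt: float
    sigma_T: float
    H_opt: float
    sigma_H: float
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")
        if not 0.0 < self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in (0, 1]")
        if not 0.0 < self.k_slow < self.k_base:
            raise ValueError("need 0 < k_slow < k_base")
        if self.sigma_T <= 0 or self.sigma_H <= 0:
            raise ValueError("sigma_T and sigma_H must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class ResidueSeries:
    """Daily residue concentrations for one pesticide under one condition."""

    pesticide: str
    condition: StorageCondition
    days: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        conc = np.asarray(self.conc, dtype=float)
        if days.shape != conc.shape or days.ndim != 1:
            raise ValueError("days and conc must be 1-D and the same length")
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "conc", conc)

    def __len__(self) -> int:
        return len(self.days)


# Defaults chosen so that four pesticides flatten after ~day 7 (fast rate
# around 0.35-0.5/day at study conditions) while chlorpyrifos-methyl, with a
# much smaller fast rate, flattens near day 15.  T_opt=38 °C / H_opt=78 % keep
# degradation mostly accelerating over the 25-40 °C / 65-80 % study range with
# a peak inside reach, so the fitted half-life surface is non-monotone.
DEFAULT_PROFILES: tuple[PesticideProfile, ...] = (
    PesticideProfile("imidacloprid", C0=2.6, fast_fraction=0.85, k_base=0.50,
                     k_slow=0.012, T_opt=38.0, sigma_T=8.0, H_opt=78.0, sigma_H=14.0),
    PesticideProfile("carbaryl", C0=2.9, fast_fraction=0.80, k_base=0.45,
                     k_slow=0.010, T_opt=37.0, sigma_T=9.0, H_opt=77.0, sigma_H=15.0),
    PesticideProfile("fenitrothion", C0=5.2, fast_fraction=0.88, k_base=0.55,
                     k_slow=0.015, T_opt=39.0, sigma_T=7.0, H_opt=79.0, sigma_H=13.0),
    PesticideProfile("chlorpyrifos-methyl", C0=4.1, fast_fraction=0.90, k_base=0.18,
                     k_slow=0.008, T_opt=38.0, sigma_T=8.5, H_opt=78.0, sigma_H=14.0),
    PesticideProfile("deltamethrin", C0=3.3, fast_fraction=0.75, k_base=0.40,
                     k_slow=0.011, T_opt=36.0, sigma_T=8.0, H_opt=76.0, sigma_H=15.0),
)


@dataclass(frozen=True)
class StudyDesign:
    """The two one-factor sweeps of the storage experiment.

    ``temperatures_at_ref_rh`` vary temperature at the reference humidity;
    ``humidities_at_ref_T`` vary humidity at the reference temperature.  The
    shared reference condition appears in both sweeps and is generated once
    per sweep (8 condition series by default, 1200 records), unless
    ``deduplicate`` is set.
    """

    temperatures_at_ref_rh: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)
    humidities_at_ref_T: tuple[float, ...] = (65.0, 70.0, 75.0, 80.0)
    ref_temperature_C: float = 25.0
    ref_rh_pct: float = 65.0
    days: int = 30
    pesticides: tuple[PesticideProfile, ...] = DEFAULT_PROFILES
    deduplicate: bool = False

    def conditions(self) -> list[StorageCondition]:
        conds = [StorageCondition(t, self.ref_rh_pct)
                 for t in self.temperatures_at_ref_rh]
        conds += [StorageCondition(self.ref_temperature_C, h)
                  for h in self.humidities_at_ref_T]
        if self.deduplicate:
            seen: set[tuple[float, float]] = set()
            unique = []
            for c in conds:
                key = (c.temperature_C, c.rh_pct)
                if key not in seen:
                    seen.add(key)
                    unique.append(c)
            conds = unique
        return conds


def noiseless(profile: PesticideProfile) -> PesticideProfile:
    """A copy of *profile* with observation noise switched off."""
    return replace(profile, noise_sd=0.0)


def degradation_rate(profile: PesticideProfile, condition: StorageCondition) -> float:
    """Fast-compartment degradation rate (per day) under a storage condition.

    Gaussian response in each factor::

        k_f = k_base * exp(-(T - T_opt)^2 / (2 sigma_T^2))
                     * exp(-(H - H_opt)^2 / (2 sigma_H^2))

    so the rate rises with temperature (and humidity) up to the critical
    point ``(T_opt, H_opt)`` and falls beyond it.
    """
    dT = (condition.temperature_C - profile.T_opt) / profile.sigma_T
    dH = (condition.rh_pct - profile.H_opt) / profile.sigma_H
    return float(profile.k_base * np.exp(-0.5 * dT * dT) * np.exp(-0.5 * dH * dH))


def decay_curve(profile: PesticideProfile, condition: StorageCondition,
                t: np.ndarray) -> np.ndarray:
    """Noiseless bi-exponential mean concentration at times *t* (days)."""
    k_f = degradation_rate(profile, condition)
    f = profile.fast_fraction
    t = np.asarray(t, dtype=float)
    return profile.C0 * (f * np.exp(-k_f * t) + (1.0 - f) * np.exp(-profile.k_slow * t))


def _series_seed(root_seed: int, pesticide: str, condition: StorageCondition) -> int:
    """Deterministic per-series sub-seed so subsets reproduce bit-exactly."""
    tag = f"{root_seed}|{pesticide}|{condition.temperature_C:.6f}|{condition.rh_pct:.6f}"
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def simulate_series(profile: PesticideProfile, condition: StorageCondition,
                    days: int = 30, seed: int = 0) -> ResidueSeries:
    """Simulate one observed residue series of length *days* (days 0..days-1).

    Observations are the noiseless curve times lognormal(0, noise_sd) noise,
    clipped at zero.  Identical seeds give bit-identical output.
    """
    if days < 2:
        raise ValueError("days must be >= 2")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    t = np.arange(days)
    mean = decay_curve(profile, condition, t)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        obs = mean * rng.lognormal(0.0, profile.noise_sd, size=days)
    else:
        obs = mean.copy()
    return ResidueSeries(profile.name, condition, t, np.clip(obs, 0.0, None))


def generate_study_dataset(design: StudyDesign | None = None,
                           seed: int = 0) -> list[ResidueSeries]:
    """Generate every (pesticide, condition) series of the study design.

    The default design yields 5 pesticides x 8 condition series x 30 days
    = 1200 records.
    """
    design = design or StudyDesign()
    if not design.pesticides:
        raise ValueError("design has no pesticides")
    conditions = design.conditions()
    if not conditions:
        raise ValueError("design has no storage conditions")
    out = []
    for profile in design.pesticides:
        for cond in conditions:
            sub = _series_seed(seed, profile.name, cond)
            out.append(simulate_series(profile, cond, design.days, sub))
    return out


def generate_tiered_m_samples(tier_centers, tier_sd: float, n_per_tier: int,
                              seed: int = 0):
    """Draw (d_current, d_predicted) pairs around residue tiers.

    Fixture generator for the grading stage: ``d_current`` is Gaussian around
    each tier center (clipped at 0), ``d_predicted = d_current * U(0.85, 1.0)``
    so the forecast never exceeds the current residue (decay).  Returns
    ``(points, labels)`` with points of shape (n_tiers * n_per_tier, 2).
    """
    centers = np.asarray(tier_centers, dtype=float)
    if len(np.unique(centers)) != len(centers):
        raise ValueError("tier_centers must be distinct")
    if tier_sd <= 0:
        raise ValueError("tier_sd must be positive")
    if n_per_tier < 1:
        raise ValueError("n_per_tier must be >= 1")
    rng = np.random.default_rng(seed)
    points = np.empty((len(centers) * n_per_tier, 2))
    labels = np.repeat(np.arange(len(centers)), n_per_tier)
    for i, c in enumerate(centers):
        cur = np.clip(rng.normal(c, tier_sd, size=n_per_tier), 0.0, None)
        pred = cur * rng.uniform(0.85, 1.0, size=n_per_tier)
        points[i * n_per_tier:(i + 1) * n_per_tier, 0] = cur
        points[i * n_per_tier:(i + 1) * n_per_tier, 1] = pred
    return points, labels
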