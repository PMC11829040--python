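"""Synthetic data generation for every stage of the pipeline.

Emulates the statistical structure the analysis assumes, so that digestion,
ladder matching and quantification are testable without instrument data:

* treated-molecule populations — each reactive residue of each molecule
  converts independently (Bernoulli) with its dose-response probability;
* peak lists — theoretical m/z plus Gaussian jitter (additive in ppm for
  ESI/HRMS, in Da for MALDI), log-normal multiplicative intensity noise and
  Poisson-distributed noise peaks over the scan range;
* calibration series — 1:1 serial dilutions with multiplicative response
  noise, using the standard maxima (100 pmol canonicals, 20 pmol for
  pseudouridine and dihydrouridine, 5 pmol other modifications);
* hydrazine concentration series of remaining fractions.

Randomness policy: one master seed per run; each stage derives its own
sub-stream, so stages are independently reproducible and identical configs
give identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import MassKind
from .digest import Fragment, Oligo
from .ladder import ConversionSpecies, Peak, conversion_ladder, theoretical_peaks
from .quant import CalibrationSeries, calibration_maximum
from .registry import Registry, TreatmentCondition

__all__ = [
    "InstrumentProfile",
    "SimulationConfig",
    "stage_rng",
    "simulate_treatment",
    "simulate_peaklist",
    "simulate_calibration",
    "simulate_concentration_series",
    "degradation_flag",
    "DegradingConditionError",
]


class DegradingConditionError(RuntimeError):
    """Raised when quantitative simulation is requested for conditions that degrade RNA."""


@dataclass(frozen=True)
class InstrumentProfile:
    """Noise characteristics of the simulated mass spectrometer."""

    ppm_sigma: float = 5.0          # ESI m/z jitter, Gaussian in ppm
    maldi_da_sigma: float = 0.15    # MALDI m/z jitter, Gaussian in Da
    noise_peak_rate: float = 5.0    # expected Poisson noise peaks per spectrum
    intensity_dispersion: float = 0.3  # sigma of the log-normal intensity factor
    maldi: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_molecules: int = 10_000
    condition: TreatmentCondition = field(
        default_factory=lambda: TreatmentCondition(30.0, 0.0, 1.0)
    )
    instrument: InstrumentProfile = field(default_factory=InstrumentProfile)
    allow_degradation: bool = False

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage sub-stream of a master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


def degradation_flag(condition: TreatmentCondition) -> Tuple[bool, str]:
    """Whether RNA degrades under a condition, with severity.

    RNA stays intact on ice or at 10 degC even for 24 h; 20 degC is
    tolerated for short incubations but fragments by 6 h; 30 degC and above
    degrade the RNA outright and 50 degC destroys it.
    """
    t_c, hours = condition.temperature_c, condition.time_h
    if t_c >= 50:
        return True, "severe"
    if t_c >= 30:
        return True, "degraded"
    if t_c > 10:
        return (True, "degraded") if hours >= 6 else (False, "warning")
    return (False, "none") if hours <= 24 else (False, "untested-beyond-24h")


def simulate_treatment(
    fragment: Fragment | Oligo,
    registry: Registry,
    condition: TreatmentCondition,
    n_molecules: int,
    rng: np.random.Generator,
    allow_degradation: bool = False,
) -> Dict[ConversionSpecies, int]:
    """Hydrazine-treat a population of molecules; count conversion species.

    Each reactive position of each molecule converts independently with its
    dose-response probability (a per-molecule Bernoulli process, *not* a draw
    from the analytic ladder probabilities, so the two routes can be checked
    against each other).  Residues with unknown-loss rules are excluded from
    mass states, mirroring the ladder.
    """
    degraded, severity = degradation_flag(condition)
    if degraded and not allow_degradation:
        raise DegradingConditionError(
            f"condition {condition} degrades RNA ({severity}); quantitative "
            "simulation refused (pass allow_degradation=True to override)"
        )
    if isinstance(fragment, Oligo):
        fragment = Fragment(fragment, fragment.name, fragment.offset,
                            fragment.offset + len(fragment) - 1)
    species = conversion_ladder(fragment, registry, condition)
    by_key = {tuple(sorted(sp.delta.counts.items())): sp for sp in species}

    # Reactive positions with mass rules and their conversion probabilities.
    positions: List[Tuple[int, object, float]] = []
    scale = min(condition.time_h, 6.0) / 1.0
    for i, token in enumerate(fragment.tokens):
        rules = registry.mass_rules(token)
        if not rules:
            continue
        rule = rules[0]
        p = rule.dose_response.converted_fraction(condition.concentration * scale)
        positions.append((i, rule, p))

    counts: Dict[ConversionSpecies, int] = {sp: 0 for sp in species}
    if not positions:
        counts[by_key[()]] = n_molecules
        return counts
    probs = np.array([p for _, _, p in positions])
    converted = rng.random((n_molecules, len(positions))) < probs
    for row in converted:
        delta = None
        for (i, rule, _), hit in zip(positions, row):
            if hit:
                delta = rule.delta if delta is None else delta + rule.delta
        key = () if delta is None else tuple(sorted(delta.counts.items()))
        counts[by_key[key]] += 1
    return counts


def simulate_peaklist(
    species_counts: Dict[ConversionSpecies, int],
    profile: InstrumentProfile,
    rng: np.random.Generator,
    charges: Iterable[int] = (1,),
    mass_kind: MassKind = MassKind.MONOISOTOPIC,
    adduct_profiles: Optional[Sequence[Dict[str, int]]] = None,
) -> List[Peak]:
    """Turn species counts into a noisy peak list."""
    if not species_counts:
        raise ValueError("no species to simulate")
    present = [sp for sp, n in species_counts.items() if n > 0]
    theo = theoretical_peaks(present, charges=charges,
                             adduct_profiles=adduct_profiles, mass_kind=mass_kind)
    peaks: List[Peak] = []
    for tp in theo:
        count = species_counts[tp.species]
        if profile.maldi:
            mz = tp.mz + rng.normal(0.0, profile.maldi_da_sigma)
        else:
            mz = tp.mz * (1.0 + rng.normal(0.0, profile.ppm_sigma) * 1e-6)
        intensity = count * float(
            np.exp(rng.normal(0.0, profile.intensity_dispersion))
        )
        peaks.append(Peak(mz=mz, intensity=intensity, charge=tp.ion.charge))
    if profile.noise_peak_rate > 0 and peaks:
        lo = min(p.mz for p in peaks) * 0.9
        hi = max(p.mz for p in peaks) * 1.1
        base = np.median([p.intensity for p in peaks])
        for _ in range(rng.poisson(profile.noise_peak_rate)):
            peaks.append(
                Peak(
                    mz=float(rng.uniform(lo, hi)),
                    intensity=0.02 * base * float(
                        np.exp(rng.normal(0.0, profile.intensity_dispersion))
                    ),
                )
            )
    return sorted(peaks, key=lambda p: p.mz)


def simulate_calibration(
    code: str,
    rng: np.random.Generator,
    max_pmol: Optional[float] = None,
    points: int = 12,
    noise: float = 0.05,
    slope: float = 0.02,
    intercept: float = 0.0,
) -> CalibrationSeries:
    """A 1:1 serial-dilution calibration series with multiplicative noise."""
    top = calibration_maximum(code) if max_pmol is None else float(max_pmol)
    amounts = np.array([top / 2**i for i in range(points)])
    eps = rng.normal(0.0, noise, size=points) if noise > 0 else np.zeros(points)
    responses = (slope * amounts + intercept) * (1.0 + eps)
    return CalibrationSeries(code, tuple(zip(amounts, responses)))


def simulate_concentration_series(
    codes: Sequence[str],
    concentrations: Sequence[float],
    registry: Registry,
    rng: np.random.Generator,
    noise: float = 0.03,
    temperature_c: float = 0.0,
    time_h: float = 1.0,
) -> pd.DataFrame:
    """Remaining-fraction table over a hydrazine concentration series.

    The 0% column is the normalisation control and is exactly 1; other
    entries are (1 - reactivity) with multiplicative Gaussian noise, floored
    at 0.
    """
    concentrations = list(concentrations)
    if 0.0 not in concentrations:
        raise ValueError("concentration series must include the 0% control")
    rows = {}
    for code in codes:
        vals = []
        for c in concentrations:
            if c == 0:
                vals.append(1.0)
                continue
            remaining = 1.0 - registry.reactivity(
                code, TreatmentCondition(c, temperature_c, time_h)
            )
            if noise > 0:
                remaining *= 1.0 + rng.normal(0.0, noise)
            vals.append(max(remaining, 0.0))
        rows[code] = vals
    return pd.DataFrame(rows, index=pd.Index(concentrations, name="hydrazine_pct")).T
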