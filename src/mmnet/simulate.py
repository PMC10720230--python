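"""Synthetic inpatient cohorts with planted pairwise odds ratios.

Each disease is a Bernoulli indicator at a configured marginal prevalence.
Comorbid structure is planted on vertex-disjoint pairs: for a pair with
odds ratio ``psi`` the per-patient joint law is the bivariate Bernoulli
whose 2x2 cell probabilities have cross-product ratio exactly ``psi`` and
the requested marginals (the Plackett construction).  All other diseases
are mutually independent, so the screening stage can be validated by
parameter recovery against a known truth.

The generator keeps every simulated patient, including patients who drew
no disease at all, so that the per-patient denominators of prevalences and
odds ratios match the configured values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml

from . import icd10
from .cohort import Cohort, InpatientRecord

__all__ = [
    "ConfigurationError",
    "PlantedTruth",
    "SyntheticCohortConfig",
    "example_catalog",
    "generate_cohort",
    "null_cohort",
    "solve_joint_prevalence",
]

_BASELINE_DATE = date(2010, 1, 1)  # all synthetic admissions share one date


class ConfigurationError(ValueError):
    """The cohort configuration is inconsistent or infeasible."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Disease catalog, planted association structure, and population strata.

    Parameters
    ----------
    n_patients
        Cohort size.
    diseases
        ``(code, marginal prevalence)`` pairs; prevalences in (0, 1).
    planted_pairs
        ``(code_i, code_j, psi)`` triples with odds ratio ``psi > 0``.
        Pairs must be vertex-disjoint so the joint law stays exact.
    sex_fraction_female
        Expected proportion of female patients.
    age_range
        Inclusive integer bounds; ages drawn uniformly.
    seed
        Seed of the single pseudo-random stream; generation is a pure
        function of the configuration.
    """

    n_patients: int
    diseases: tuple[tuple[str, float], ...]
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    sex_fraction_female: float = 0.5
    age_range: tuple[int, int] = (40, 59)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not self.diseases:
            raise ConfigurationError("disease catalog is empty")
        catalog = dict(self.diseases)
        if len(catalog) != len(self.diseases):
            raise ConfigurationError("duplicate disease code in catalog")
        for code, p in self.diseases:
            icd10.normalize_code(code)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"prevalence of {code} not in (0,1): {p}")
        seen: set[str] = set()
        for ci, cj, psi in self.planted_pairs:
            if ci not in catalog or cj not in catalog:
                raise ConfigurationError(f"planted pair ({ci},{cj}) not in catalog")
            if ci == cj or ci in seen or cj in seen:
                raise ConfigurationError(
                    f"planted pairs must be vertex-disjoint; ({ci},{cj}) reuses a disease")
            seen.update((ci, cj))
            p11 = solve_joint_prevalence(catalog[ci], catalog[cj], psi)
            cells = (p11, catalog[ci] - p11, catalog[cj] - p11,
                     1.0 - catalog[ci] - catalog[cj] + p11)
            if min(cells) < -1e-12:
                raise ConfigurationError(
                    f"pair ({ci},{cj}) with psi={psi} implies a negative cell")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for each planted pair: (code_i, code_j, psi, p11)."""

    pairs: tuple[tuple[str, str, float, float], ...] = ()

    def to_csv(self, path: str | Path) -> None:
        lines = ["code_i,code_j,psi,p11"]
        lines += [f"{a},{b},{psi},{p11}" for a, b, psi, p11 in self.pairs]
        Path(path).write_text("\n".join(lines) + "\n")


def solve_joint_prevalence(p_i: float, p_j: float, psi: float) -> float:
    """Joint prevalence p11 of a bivariate Bernoulli with odds ratio ``psi``.

    For psi = 1 this is the independence product.  Otherwise p11 is the
    admissible root of ``(psi-1) p11^2 - S p11 + psi p_i p_j = 0`` with
    ``S = 1 + (p_i + p_j)(psi - 1)``; the smaller root is the one inside
    the Frechet bounds ``[max(0, p_i+p_j-1), min(p_i, p_j)]``.
    """
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise ValueError("marginal prevalences must lie in (0,1)")
    if psi <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {psi}")
    if psi == 1.0:
        return p_i * p_j
    a = psi - 1.0
    s = 1.0 + (p_i + p_j) * a
    disc = s * s - 4.0 * a * psi * p_i * p_j
    p11 = (s - math.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, p_i + p_j - 1.0), min(p_i, p_j)
    return min(max(p11, lo), hi)


def example_catalog(n_diseases: int, prevalence: float = 0.05
                    ) -> tuple[tuple[str, float], ...]:
    """A catalog of ``n_diseases`` in-scope codes at a common prevalence.

    Codes cycle through the chapter-1..14 letters (A, C, D, E, F, G, H, I,
    J, K, L, M, N) so synthetic cohorts exercise the chapter machinery.
    """
    letters = "ACDEFGHIJKLMN"
    codes = []
    idx = 0
    while len(codes) < n_diseases:
        letter = letters[idx % len(letters)]
        num = 10 + idx // len(letters)  # start at X10: inside every chapter block
        code = f"{letter}{num:02d}"
        if num > 99:
            raise ConfigurationError("catalog request too large")
        if icd10.in_scope(code):
            codes.append(code)
        idx += 1
    return tuple((c, prevalence) for c in codes)


def generate_cohort(config: SyntheticCohortConfig) -> tuple[Cohort, PlantedTruth]:
    """Draw a cohort from the configured joint law.

    The random stream order is fixed — sex, age, planted pairs in config
    order, then remaining diseases in catalog order — so the same seed
    yields byte-identical cohorts on any platform.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    sexes = np.where(rng.random(n) < config.sex_fraction_female, "female", "male")
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)

    catalog = dict(config.diseases)
    indicator: dict[str, np.ndarray] = {}
    truth = []
    for ci, cj, psi in config.planted_pairs:
        p11 = solve_joint_prevalence(catalog[ci], catalog[cj], psi)
        p10 = catalog[ci] - p11
        p01 = catalog[cj] - p11
        u = rng.random(n)
        cell = np.searchsorted(np.cumsum([p11, p10, p01]), u, side="right")
        indicator[ci] = cell <= 1  # cells 0 (both) and 1 (i only)
        indicator[cj] = (cell == 0) | (cell == 2)
        truth.append((ci, cj, psi, p11))
    planted_codes = set(indicator)
    for code, p in config.diseases:
        if code not in planted_codes:
            indicator[code] = rng.random(n) < p

    codes_in_order = [c for c, _ in config.diseases]
    matrix = np.column_stack([indicator[c] for c in codes_in_order])
    records = []
    for i in range(n):
        present = frozenset(codes_in_order[j] for j in np.nonzero(matrix[i])[0])
        records.append(InpatientRecord(
            patient_id=f"S{i:07d}", admission_date=_BASELINE_DATE,
            age=int(ages[i]), sex=str(sexes[i]), codes=present))
    cohort = Cohort(records=records, label=f"synthetic_seed{config.seed}")
    return cohort, PlantedTruth(pairs=tuple(truth))


def null_cohort(n_patients: int, diseases: tuple[tuple[str, float], ...],
                seed: int = 0) -> Cohort:
    """Cohort with all diseases mutually independent (no planted pairs)."""
    config = SyntheticCohortConfig(n_patients=n_patients,
                                   diseases=tuple(diseases), seed=seed)
    cohort, _ = generate_cohort(config)
    return cohort


def config_from_yaml(path: str | Path) -> SyntheticCohortConfig:
    """Load a cohort configuration from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text())
    return SyntheticCohortConfig(
        n_patients=int(raw["n_patients"]),
        diseases=tuple((str(c), float(p)) for c, p in raw["diseases"]),
        planted_pairs=tuple((str(a), str(b), float(psi))
                            for a, b, psi in raw.get("planted_pairs", ())),
        sex_fraction_female=float(raw.get("sex_fraction_female", 0.5)),
        age_range=tuple(raw.get("age_range", (40, 59))),
        seed=int(raw.get("seed", 0)),
    )
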