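"""Synthetic mating-assay generator.

Emulates the two-assay competitive design: each focal male shares an arena
with one competitor male and two partner females; each focal female is
assayed against a competitor female with two partner males and her own
clutch is the outcome. Counts are overdispersed (negative binomial — the
generative stand-in for a quasi-Poisson mean-variance relationship),
mating can fail, and paternity within a partner's clutch is beta-binomial
around the focal's competitive weight share.

Assay rules for the focal male's partners:

* ``focal_only``  — partners (and competitor) are reared on control diet;
* ``whole_group`` — everyone carries the cell's flour/yeast treatment.

Defaults are calibrated to roughly mimic the magnitudes of a wheat /
whole-wheat yeast-deprivation experiment (selection coefficient near 0.9 in
the stressed wheat cell, opportunity for selection around 0.2-0.3 in control
cells); they are plausibility calibrations, not ground truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

from .datamodel import ASSAYS, CONTROL_YEAST, Dataset, FitnessRecord
from .errors import DesignError
from .resampling import SeedLike, _seed_sequence

Cell = tuple[str, str]  # (flour, yeast)

DEFAULT_MU: dict[Cell, float] = {
    ("wheat", "control_5pct"): 20.0,
    ("wheat", "none"): 2.0,
    ("whole_wheat", "control_5pct"): 22.0,
    ("whole_wheat", "low_1pct"): 20.5,
    ("whole_wheat", "none"): 18.5,
}

DEFAULT_P_MATE: dict[Cell, float] = {
    ("wheat", "control_5pct"): 0.95,
    ("wheat", "none"): 0.66,
    ("whole_wheat", "control_5pct"): 0.95,
    ("whole_wheat", "low_1pct"): 0.90,
    ("whole_wheat", "none"): 0.85,
}

DEFAULT_MORTALITY: dict[Cell, float] = {
    ("wheat", "control_5pct"): 0.04,
    ("wheat", "none"): 0.19,
    ("whole_wheat", "control_5pct"): 0.0,
    ("whole_wheat", "low_1pct"): 0.005,
    ("whole_wheat", "none"): 0.011,
}

DEFAULT_BODY_MASS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("female", "wheat", "control_5pct"): (2.30, 0.12),
    ("female", "wheat", "none"): (2.09, 0.12),
    ("male", "wheat", "control_5pct"): (2.00, 0.10),
    ("male", "wheat", "none"): (1.92, 0.10),
    ("female", "whole_wheat", "control_5pct"): (2.32, 0.12),
    ("female", "whole_wheat", "low_1pct"): (2.31, 0.12),
    ("female", "whole_wheat", "none"): (2.30, 0.12),
    ("male", "whole_wheat", "control_5pct"): (2.02, 0.10),
    ("male", "whole_wheat", "low_1pct"): (2.01, 0.10),
    ("male", "whole_wheat", "none"): (2.00, 0.10),
}


@dataclass
class SimulationParams:
    """Generative parameters of the synthetic mating-group experiment."""

    n_focal: int = 50  # per (flour, yeast, sex) cell
    mu: Mapping[Cell, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    theta: float = 5.0  # negative-binomial size (inf = Poisson)
    p_mate: Mapping[Cell, float] = field(default_factory=lambda: dict(DEFAULT_P_MATE))
    w_focal: float = 1.0
    w_competitor: float = 0.35
    kappa: float = 8.0  # beta-binomial concentration (inf = fixed share)
    mortality: Mapping[Cell, float] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY)
    )
    body_mass: Mapping[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BODY_MASS)
    )
    female_focal_stress_factor: float = 1.0  # extra multiplier, focal_only assay
    seed: int = 0

    def validate(self) -> None:
        if self.n_focal < 1:
            raise ValueError("n_focal must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.w_focal <= 0 or self.w_competitor < 0:
            raise ValueError("competitive weights must be positive (w_competitor >= 0)")
        for cell, m in self.mu.items():
            if m <= 0:
                raise ValueError(f"mu{cell} must be positive")
        for mapping, name in ((self.p_mate, "p_mate"), (self.mortality, "mortality")):
            for cell, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}{cell} must lie in [0, 1]")
        for cell, (mean, sd) in self.body_mass.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"body_mass{cell} needs positive mean, sd >= 0")

    @property
    def cells(self) -> list[Cell]:
        return sorted(self.mu)

    @property
    def mean_share(self) -> float:
        return self.w_focal / (self.w_focal + self.w_competitor)


def params_from_yaml(path: str) -> SimulationParams:
    """Load :class:`SimulationParams` from a nested YAML mapping."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}

    def nested_to_cells(block: Mapping | None, default: Mapping) -> dict:
        if block is None:
            return dict(default)
        return {
            (flour, yeast): float(v)
            for flour, sub in block.items()
            for yeast, v in sub.items()
        }

    body = raw.get("body_mass")
    if body is not None:
        body = {
            (sex, flour, yeast): (float(ms[0]), float(ms[1]))
            for sex, b1 in body.items()
            for flour, b2 in b1.items()
            for yeast, ms in b2.items()
        }
    params = SimulationParams(
        n_focal=int(raw.get("n_focal", 50)),
        mu=nested_to_cells(raw.get("mu"), DEFAULT_MU),
        theta=float(raw.get("theta", 5.0)),
        p_mate=nested_to_cells(raw.get("p_mate"), DEFAULT_P_MATE),
        w_focal=float(raw.get("w_focal", 1.0)),
        w_competitor=float(raw.get("w_competitor", 0.35)),
        kappa=float(raw.get("kappa", 8.0)),
        mortality=nested_to_cells(raw.get("mortality"), DEFAULT_MORTALITY),
        body_mass=body if body is not None else dict(DEFAULT_BODY_MASS),
        female_focal_stress_factor=float(raw.get("female_focal_stress_factor", 1.0)),
        seed=int(raw.get("seed", 0)),
    )
    params.validate()
    return params


def _negbin(rng: np.random.Generator, mu: float, theta: float, size: int | None = None):
    """Negative binomial with mean mu, variance mu + mu^2/theta."""
    if math.isinf(theta):
        return rng.poisson(mu, size)
    return rng.negative_binomial(theta, theta / (theta + mu), size)


def _sired(rng: np.random.Generator, clutch: int, share: float, kappa: float) -> int:
    """Beta-binomial focal-sired count within one partner's clutch."""
    if clutch == 0:
        return 0
    if share >= 1.0:
        return clutch
    if share <= 0.0:
        return 0
    q = share if math.isinf(kappa) else rng.beta(share * kappa, (1.0 - share) * kappa)
    return int(rng.binomial(clutch, q))


def simulate_experiment(
    params: SimulationParams,
    assay: str,
    cells: Iterable[tuple[str, str, str]] | None = None,
    seed: SeedLike | None = None,
) -> Dataset:
    """Simulate one assay and return a Dataset passing all model invariants.

    ``cells`` optionally restricts generation to specific
    ``(flour, yeast, sex)`` cells. Fully deterministic given the seed; each
    cell draws from its own labelled substream, so restricting or reordering
    cells never changes another cell's records.
    """
    if assay not in ASSAYS:
        raise DesignError(f"unknown assay {assay!r}")
    params.validate()
    base = _seed_sequence(params.seed if seed is None else seed)
    wanted = (
        [(f, y, s) for f, y in params.cells for s in ("female", "male")]
        if cells is None
        else list(cells)
    )
    records: list[FitnessRecord] = []
    for flour, yeast, sex in wanted:
        if (flour, yeast) not in params.mu:
            raise DesignError(f"no parameters for cell {(flour, yeast)}")
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=base.entropy,
                spawn_key=(zlib.crc32(f"{assay}|{flour}|{yeast}|{sex}".encode()),),
            )
        )
        mass_mean, mass_sd = params.body_mass.get((sex, flour, yeast), (2.0, 0.1))
        for i in range(params.n_focal):
            focal_id = f"{assay[:2]}-{flour[:2]}-{yeast[:4]}-{sex[0]}{i:04d}"
            mass = float(max(rng.normal(mass_mean, mass_sd), 0.01))
            if sex == "female":
                mu = params.mu[flour, yeast]
                if assay == "focal_only":
                    mu *= params.female_focal_stress_factor
                clutch = int(_negbin(rng, mu, params.theta))
                died = rng.random() < params.mortality[flour, yeast]
                if died:
                    # death truncates the laying window at a uniform fraction
                    clutch = int(math.floor(clutch * rng.random()))
                records.append(
                    FitnessRecord(
                        focal_id=focal_id,
                        sex="female",
                        flour=flour,
                        yeast=yeast,
                        assay=assay,
                        body_mass_mg=round(mass, 3),
                        survived=not died,
                        partner_total=(clutch, None),
                        partner_sired=(clutch, None),
                        laying_week="combined",
                    )
                )
            else:
                partner_yeast = CONTROL_YEAST if assay == "focal_only" else yeast
                mu_partner = params.mu[flour, partner_yeast]
                p_mate = params.p_mate[flour, yeast]
                totals, sired = [], []
                for _ in range(2):
                    clutch = int(_negbin(rng, mu_partner, params.theta))
                    mated = rng.random() < p_mate
                    totals.append(clutch)
                    sired.append(
                        _sired(rng, clutch, params.mean_share, params.kappa)
                        if mated
                        else 0
                    )
                records.append(
                    FitnessRecord(
                        focal_id=focal_id,
                        sex="male",
                        flour=flour,
                        yeast=yeast,
                        assay=assay,
                        body_mass_mg=round(mass, 3),
                        survived=True,
                        partner_total=tuple(totals),
                        partner_sired=tuple(sired),
                    )
                )
    return Dataset(records=records, provenance=f"simulated:{assay}")


def simulate_both_assays(params: SimulationParams, seed: SeedLike | None = None) -> Dataset:
    """Both assays in one Dataset (substreams keep them independent)."""
    focal = simulate_experiment(params, "focal_only", seed=seed)
    whole = simulate_experiment(params, "whole_group", seed=seed)
    return Dataset(
        records=focal.records + whole.records,
        provenance="simulated:both",
    )


def expected_female_opportunity(mu: float, theta: float) -> float:
    """Closed-form E[I] for negative-binomial clutches without mortality.

    var/mean^2 = (mu + mu^2/theta) / mu^2 = 1/mu + 1/theta.
    """
    return 1.0 / mu + 1.0 / theta


def ground_truth(params: SimulationParams, assay: str) -> dict:
    """Closed-form expectations implied by the generative model.

    Returns, per (flour, stressed-yeast) pair, the true selection
    coefficient for females and males, and per cell the expected female
    opportunity for selection (exact only without mortality; cells with
    mortality report None), plus expected male component means.
    """
    params.validate()
    out: dict = {"s": {}, "I_female": {}, "male_means": {}}

    def female_mean(flour: str, yeast: str) -> float:
        mu = params.mu[flour, yeast]
        if assay == "focal_only":
            mu *= params.female_focal_stress_factor
        q = params.mortality[flour, yeast]
        return mu * (1.0 - q / 2.0)  # uniform truncation halves a victim's clutch

    def male_mean(flour: str, yeast: str) -> float:
        partner_yeast = CONTROL_YEAST if assay == "focal_only" else yeast
        return 2.0 * params.p_mate[flour, yeast] * params.mean_share * params.mu[
            flour, partner_yeast
        ]

    flours = sorted({flour for flour, _ in params.mu})
    for flour in flours:
        yeasts = sorted(y for f, y in params.mu if f == flour)
        for yeast in yeasts:
            q = params.mortality[flour, yeast]
            out["I_female"][flour, yeast] = (
                expected_female_opportunity(
                    params.mu[flour, yeast]
                    * (params.female_focal_stress_factor if assay == "focal_only" else 1.0),
                    params.theta,
                )
                if q == 0.0
                else None
            )
            out["male_means"][flour, yeast] = {
                "T": male_mean(flour, yeast),
                # expected mated partners; MS itself is lower because a mated
                # partner can still yield zero focal-sired offspring
                "matings": 2.0 * params.p_mate[flour, yeast],
            }
            if yeast == CONTROL_YEAST:
                continue
            out["s"][flour, yeast, "female"] = 1.0 - female_mean(flour, yeast) / female_mean(
                flour, CONTROL_YEAST
            )
            out["s"][flour, yeast, "male"] = 1.0 - male_mean(flour, yeast) / male_mean(
                flour, CONTROL_YEAST
            )
    return out


def with_overrides(params: SimulationParams, **changes) -> SimulationParams:
    """Copy params with field overrides (convenience for tests/CLI)."""
    new = replace(params, **changes)
    new.validate()
    return new
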