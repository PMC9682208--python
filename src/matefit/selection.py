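"""Selection coefficients and the opportunity for selection.

The selection coefficient against a stressed class is

    s = 1 - mean(W_stressed) / mean(W_control)

and the opportunity for selection is the sample variance of relativized
fitness (each value divided by its group mean), equivalently
var(W) / mean(W)^2. Both are invariant to rescaling all fitness values by a
common positive constant. Interval estimates come from the shared
percentile-bootstrap engine; the sex contrast in s additionally gets a
stratified label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import resampling
from .datamodel import CONTROL_YEAST, Dataset, reproductive_success
from .errors import DegenerateGroupError, InsufficientDataError
from .resampling import SeedLike


def relativize(values: Sequence[float]) -> np.ndarray:
    """Divide fitness values by their mean so the output mean is exactly 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"need >= 2 values to relativize, got {v.size}")
    if np.any(v < 0):
        raise ValueError("fitness values must be nonnegative")
    mean = v.mean()
    if mean <= 0:
        raise DegenerateGroupError("cannot relativize: group mean is zero")
    return v / mean


def selection_coefficient(
    control_w: Sequence[float], stressed_w: Sequence[float]
) -> float:
    """Proportional fitness deficit of the stressed class vs. the control."""
    c = np.asarray(control_w, dtype=float)
    s = np.asarray(stressed_w, dtype=float)
    if c.size == 0 or s.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    mc = c.mean()
    if mc <= 0:
        raise DegenerateGroupError("control group mean is zero")
    return float(1.0 - s.mean() / mc)


def opportunity_for_selection(values: Sequence[float]) -> float:
    """Sample variance (n-1 denominator) of relativized fitness."""
    rel = relativize(values)
    return float(np.var(rel, ddof=1))


@dataclass
class SelectionEstimate:
    """Selection coefficient with percentile-bootstrap interval."""

    s_point: float
    s_boot_mean: float | None
    ci_low: float | None
    ci_high: float | None
    n_control: int
    n_stressed: int
    n_boot: int
    seed: SeedLike
    warning: str | None = None


@dataclass
class OpportunityEstimate:
    """Opportunity for selection with percentile-bootstrap interval."""

    i_point: float
    i_boot_mean: float | None
    ci_low: float | None
    ci_high: float | None
    n: int
    n_boot: int
    seed: SeedLike
    warning: str | None = None


@dataclass
class SexDifferenceResult:
    """Sex contrast in s with bootstrap CI and permutation p-value."""

    delta: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    s_male: float
    s_female: float
    n_boot: int
    n_perm: int
    seed: SeedLike


def cell_fitness(
    dataset: Dataset,
    assay: str,
    sex: str,
    flour: str,
    yeast: str,
    exclude_dead: bool = False,
) -> np.ndarray:
    """Reproductive-success vector of one (assay, sex, flour, yeast) cell.

    Dead females are retained by default: mortality is part of realized
    fitness. Pass ``exclude_dead=True`` to restrict to survivors.
    """
    records = dataset.select(assay=assay, sex=sex, flour=flour, yeast=yeast)
    if exclude_dead:
        records = [r for r in records if r.survived]
    return np.asarray([reproductive_success(r) for r in records], dtype=float)


def estimate_selection(
    dataset: Dataset,
    assay: str,
    sex: str,
    flour: str,
    stressed_yeast: str,
    control_yeast: str = CONTROL_YEAST,
    n_boot: int = resampling.DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
    exclude_dead: bool = False,
) -> SelectionEstimate:
    """Selection coefficient of one treated cell against its control cell.

    Both groups are resampled independently with replacement at their
    original sizes; replicates with a zero-mean control group are redrawn
    (and counted). ``n_boot=0`` returns the plug-in estimate only.
    """
    control = cell_fitness(dataset, assay, sex, flour, control_yeast, exclude_dead)
    stressed = cell_fitness(dataset, assay, sex, flour, stressed_yeast, exclude_dead)
    res = resampling.bootstrap(
        [control, stressed],
        selection_coefficient,
        n=n_boot,
        level=level,
        seed=seed,
    )
    return SelectionEstimate(
        s_point=float(res.point),
        s_boot_mean=res.boot_mean,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        n_control=control.size,
        n_stressed=stressed.size,
        n_boot=n_boot,
        seed=seed,
        warning=res.warning,
    )


def estimate_opportunity(
    dataset: Dataset,
    assay: str,
    sex: str,
    flour: str,
    yeast: str,
    n_boot: int = resampling.DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
    exclude_dead: bool = False,
) -> OpportunityEstimate:
    """Opportunity for selection of one design cell with bootstrap CI."""
    values = cell_fitness(dataset, assay, sex, flour, yeast, exclude_dead)
    if values.size < 2:
        raise InsufficientDataError(
            f"cell ({assay}, {sex}, {flour}, {yeast}) has {values.size} record(s)"
        )
    res = resampling.bootstrap(
        [values], opportunity_for_selection, n=n_boot, level=level, seed=seed
    )
    return OpportunityEstimate(
        i_point=float(res.point),
        i_boot_mean=res.boot_mean,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        n=values.size,
        n_boot=n_boot,
        seed=seed,
        warning=res.warning,
    )


def sex_difference_in_s(
    dataset: Dataset,
    assay: str,
    flour: str,
    stressed_yeast: str,
    control_yeast: str = CONTROL_YEAST,
    n_boot: int = resampling.DEFAULT_N_RESAMPLES,
    n_perm: int = resampling.DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
    exclude_dead: bool = False,
) -> SexDifferenceResult:
    """Male-minus-female contrast in s for one (flour, treatment) pair.

    CI: paired bootstrap resampling all four groups (male/female x
    control/stressed) independently. p-value: sex labels are shuffled among
    focal individuals within each treatment stratum (control and stressed
    separately, preserving group sizes), s is recomputed per pseudo-sex and
    the two-sided add-one-smoothed p returned. Replicates or permutations
    with a zero-mean pseudo-control group are redrawn.
    """
    groups = {}
    for sex in ("male", "female"):
        groups[sex, "control"] = cell_fitness(
            dataset, assay, sex, flour, control_yeast, exclude_dead
        )
        groups[sex, "stressed"] = cell_fitness(
            dataset, assay, sex, flour, stressed_yeast, exclude_dead
        )

    def delta_stat(mc: np.ndarray, ms: np.ndarray, fc: np.ndarray, fs: np.ndarray) -> float:
        return selection_coefficient(mc, ms) - selection_coefficient(fc, fs)

    ordered = [
        groups["male", "control"],
        groups["male", "stressed"],
        groups["female", "control"],
        groups["female", "stressed"],
    ]
    boot = resampling.bootstrap(ordered, delta_stat, n=n_boot, level=level, seed=seed)
    delta_obs = float(boot.point)

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(resampling.spawn_seed(seed, "sex-permutation"))
        strata = [
            (groups["male", "control"], groups["female", "control"]),
            (groups["male", "stressed"], groups["female", "stressed"]),
        ]
        n_extreme = 0
        done = 0
        attempts = 0
        while done < n_perm:
            attempts += 1
            if attempts > n_perm * 100:
                raise DegenerateGroupError("too many degenerate permutations")
            (pmc, pfc), (pms, pfs) = resampling.permute_within_strata(rng, strata)
            try:
                stat = delta_stat(pmc, pms, pfc, pfs)
            except DegenerateGroupError:
                continue
            if abs(stat) >= abs(delta_obs) - 1e-12:
                n_extreme += 1
            done += 1
        p_value = (1 + n_extreme) / (n_perm + 1)

    return SexDifferenceResult(
        delta=delta_obs,
        ci_low=boot.ci_low,
        ci_high=boot.ci_high,
        p_value=p_value,
        s_male=selection_coefficient(groups["male", "control"], groups["male", "stressed"]),
        s_female=selection_coefficient(
            groups["female", "control"], groups["female", "stressed"]
        ),
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
    )
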