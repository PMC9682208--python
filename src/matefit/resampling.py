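"""Reproducible bootstrap and permutation engine.

Seeding policy: an integer master seed is expanded through
``numpy.random.SeedSequence``; each resampled group receives its own child
stream so the draws for one group never depend on the content or length of
another (and, at the pipeline level, adding an analysis cell never perturbs
the draws of existing cells).

Percentile intervals use ``numpy.quantile`` with its default linear
interpolation between order statistics (type-7 in Hyndman–Fan terms).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import DegenerateGroupError

DEFAULT_N_RESAMPLES = 10_000

SeedLike = int | np.random.SeedSequence


def _seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def spawn_seed(seed: SeedLike, *key: str) -> np.random.SeedSequence:
    """Derive a deterministic sub-stream seed from a master seed and a label.

    The label is hashed with crc32 (stable across processes, unlike ``hash``)
    so each labelled analysis cell gets an independent, order-free stream.
    """
    import zlib

    base = _seed_sequence(seed)
    digest = [zlib.crc32(part.encode("utf-8")) for part in key]
    return np.random.SeedSequence(entropy=base.entropy, spawn_key=tuple(digest))


@dataclass
class ResampleResult:
    """Point estimate plus bootstrap replicates and percentile interval."""

    point: float | np.ndarray
    replicates: np.ndarray
    boot_mean: float | np.ndarray | None
    ci_low: float | np.ndarray | None
    ci_high: float | np.ndarray | None
    level: float
    n_resamples: int
    n_degenerate: int
    seed: SeedLike
    warning: str | None = None


def bootstrap(
    groups: Sequence[Sequence[float]],
    statistic: Callable[..., float | np.ndarray],
    n: int = DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
    max_attempts_factor: int = 100,
) -> ResampleResult:
    """Nonparametric bootstrap of ``statistic(*groups)``.

    Each group is resampled independently with replacement at its original
    size. Replicates in which the statistic raises
    :class:`DegenerateGroupError` are redrawn and counted; if more than 1%
    of replicates were degenerate a warning is attached to the result.
    The statistic may return a scalar or a 1-d vector of terms.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    arrays = [np.asarray(g) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise DegenerateGroupError("bootstrap requires nonempty groups")
    point = statistic(*arrays)

    if n == 0:
        return ResampleResult(
            point=point,
            replicates=np.empty(0),
            boot_mean=None,
            ci_low=None,
            ci_high=None,
            level=level,
            n_resamples=0,
            n_degenerate=0,
            seed=seed,
        )

    ss = _seed_sequence(seed)
    rngs = [np.random.default_rng(child) for child in ss.spawn(len(arrays))]
    reps: list[np.ndarray] = []
    n_degenerate = 0
    attempts = 0
    max_attempts = n * max_attempts_factor
    while len(reps) < n:
        attempts += 1
        if attempts > max_attempts:
            raise DegenerateGroupError(
                f"more than {max_attempts} bootstrap attempts needed for {n} replicates"
            )
        samples = [
            g[rng.integers(0, g.size, g.size)] for g, rng in zip(arrays, rngs)
        ]
        try:
            reps.append(np.asarray(statistic(*samples), dtype=float))
        except DegenerateGroupError:
            n_degenerate += 1
    replicates = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha], axis=0)
    boot_mean = replicates.mean(axis=0)
    if replicates.ndim == 1:
        lo, hi, boot_mean = float(lo), float(hi), float(boot_mean)
    warning = None
    if n_degenerate > 0.01 * n:
        warning = f"{n_degenerate} degenerate replicates redrawn ({n_degenerate / n:.1%} of n)"
    return ResampleResult(
        point=point,
        replicates=replicates,
        boot_mean=boot_mean,
        ci_low=lo,
        ci_high=hi,
        level=level,
        n_resamples=n,
        n_degenerate=n_degenerate,
        seed=seed,
        warning=warning,
    )


_TIE_ATOL = 1e-12  # float-noise guard so exact ties count as extreme


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n: int = DEFAULT_N_RESAMPLES,
    alternative: str = "two_sided",
    seed: SeedLike = 0,
) -> float:
    """Label-permutation p-value for a two-group statistic.

    Pools both groups, reshuffles preserving group sizes, and returns the
    add-one-smoothed p-value ``(1 + #extreme) / (n + 1)`` (never zero).
    """
    if n < 1:
        raise ValueError("number of permutations must be >= 1")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateGroupError("permutation test requires nonempty groups")
    observed = float(statistic(a, b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(_seed_sequence(seed))
    n_extreme = 0
    for _ in range(n):
        perm = rng.permutation(pooled)
        stat = float(statistic(perm[: a.size], perm[a.size :]))
        if alternative == "two_sided":
            extreme = abs(stat) >= abs(observed) - _TIE_ATOL
        elif alternative == "greater":
            extreme = stat >= observed - _TIE_ATOL
        else:
            extreme = stat <= observed + _TIE_ATOL
        n_extreme += bool(extreme)
    return (1 + n_extreme) / (n + 1)


def permute_within_strata(
    rng: np.random.Generator,
    strata: Sequence[tuple[np.ndarray, np.ndarray]],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffle two-group labels independently within each stratum.

    Each stratum is a ``(group_a, group_b)`` pair; values are pooled within
    the stratum and reassigned preserving the original group sizes.
    """
    out = []
    for a, b in strata:
        pooled = np.concatenate([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
        perm = rng.permutation(pooled)
        out.append((perm[: len(a)], perm[len(a) :]))
    return out
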