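"""Variance decomposition of male reproductive success.

Male reproductive success T is modeled as the product of three components:

* MS  — genetic mating success: number of partner females with at least one
        focal-sired offspring;
* Fec — mean total offspring of those fertilized partners;
* PS  — pooled paternity share: focal-sired offspring divided by the total
        offspring of the fertilized partners.

With the pooled definitions T = MS * Fec * PS holds exactly for every male
(convention: MS = 0 implies Fec = PS = 0, keeping zero-fitness males in the
variance). The opportunity for selection of T is then split into the
variances of the mean-relativized components, twice their pairwise
covariances, and an explicit higher-order remainder defined by difference,
so the terms sum to I_total to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import resampling
from .datamodel import FitnessRecord
from .errors import CapabilityError, DegenerateGroupError, InsufficientDataError
from .resampling import SeedLike

TERM_NAMES = (
    "I_MS",
    "I_Fec",
    "I_PS",
    "cov_MS_Fec",
    "cov_MS_PS",
    "cov_Fec_PS",
    "remainder",
    "I_total",
)


@dataclass
class MaleFitnessComponents:
    """Multiplicative fitness components of one focal male."""

    focal_id: str
    ms: int
    fec: float
    ps: float
    total: int


def components_from_record(
    record: FitnessRecord, paternity_share: str = "pooled"
) -> MaleFitnessComponents:
    """Split a male record into mating success, fecundity and paternity share.

    ``paternity_share="pooled"`` (default) uses the ratio of summed sired to
    summed totals over fertilized partners, which makes T = MS * Fec * PS an
    exact identity. ``"per_partner_mean"`` averages the per-partner ratios
    instead; that variant matches an alternative reading of the component
    definitions but leaves a nonzero identity residual.
    """
    if record.sex != "male":
        raise ValueError("fitness components are defined for male records")
    if not record.has_partner_detail:
        raise CapabilityError(
            f"{record.focal_id}: per-partner counts unavailable (totals-only "
            "dialect); disable the decomposition for this dataset"
        )
    if paternity_share not in ("pooled", "per_partner_mean"):
        raise ValueError(f"unknown paternity_share method {paternity_share!r}")
    totals = np.asarray([t for t in record.partner_total if t is not None], dtype=float)
    sired = np.asarray([s for s in record.partner_sired if s is not None], dtype=float)
    fertilized = sired > 0
    ms = int(fertilized.sum())
    if ms == 0:
        fec, ps = 0.0, 0.0
    else:
        fec = float(totals[fertilized].sum() / ms)
        if paternity_share == "pooled":
            ps = float(sired[fertilized].sum() / totals[fertilized].sum())
        else:
            ps = float(np.mean(sired[fertilized] / totals[fertilized]))
    return MaleFitnessComponents(
        focal_id=record.focal_id,
        ms=ms,
        fec=fec,
        ps=ps,
        total=int(sired.sum()),
    )


@dataclass
class DecompositionResult:
    """Variance/covariance terms summing exactly to the male I_total."""

    terms: dict[str, float]
    boot_mean: dict[str, float] | None
    ci_low: dict[str, float] | None
    ci_high: dict[str, float] | None
    n: int
    n_boot: int
    seed: SeedLike
    paternity_share: str = "pooled"
    identity_residual: float = 0.0
    warning: str | None = None

    @property
    def i_total(self) -> float:
        return self.terms["I_total"]


def _terms_vector(ms: np.ndarray, fec: np.ndarray, ps: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Decomposition terms of one (sub)sample, in TERM_NAMES order."""
    means = [arr.mean() for arr in (ms, fec, ps, t)]
    if any(m <= 0 for m in means):
        raise DegenerateGroupError("a component mean is zero in this cell")
    rel = [arr / m for arr, m in zip((ms, fec, ps, t), means)]
    r_ms, r_fec, r_ps, r_t = rel
    i_total = float(np.var(r_t, ddof=1))
    i_ms = float(np.var(r_ms, ddof=1))
    i_fec = float(np.var(r_fec, ddof=1))
    i_ps = float(np.var(r_ps, ddof=1))
    cov_ms_fec = float(np.cov(r_ms, r_fec, ddof=1)[0, 1])
    cov_ms_ps = float(np.cov(r_ms, r_ps, ddof=1)[0, 1])
    cov_fec_ps = float(np.cov(r_fec, r_ps, ddof=1)[0, 1])
    remainder = i_total - (
        i_ms + i_fec + i_ps + 2.0 * (cov_ms_fec + cov_ms_ps + cov_fec_ps)
    )
    return np.array(
        [i_ms, i_fec, i_ps, cov_ms_fec, cov_ms_ps, cov_fec_ps, remainder, i_total]
    )


def decompose_components(
    ms: Sequence[float],
    fec: Sequence[float],
    ps: Sequence[float],
    total: Sequence[float] | None = None,
    n_boot: int = resampling.DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
) -> DecompositionResult:
    """Decompose I_total over arrays of per-male components.

    If ``total`` is omitted it is reconstructed as MS * Fec * PS. Bootstrap
    resampling keeps each male's component triple together (rows are
    resampled jointly).
    """
    ms = np.asarray(ms, dtype=float)
    fec = np.asarray(fec, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if not (ms.shape == fec.shape == ps.shape):
        raise ValueError("component arrays must have equal length")
    if ms.size < 2:
        raise InsufficientDataError(f"need >= 2 males, got {ms.size}")
    t = ms * fec * ps if total is None else np.asarray(total, dtype=float)

    idx = np.arange(ms.size)
    res = resampling.bootstrap(
        [idx],
        lambda i: _terms_vector(ms[i], fec[i], ps[i], t[i]),
        n=n_boot,
        level=level,
        seed=seed,
    )
    point = dict(zip(TERM_NAMES, (float(x) for x in np.asarray(res.point))))
    # conservation is exact by construction; assert defensively anyway
    listed = (
        point["I_MS"]
        + point["I_Fec"]
        + point["I_PS"]
        + 2.0 * (point["cov_MS_Fec"] + point["cov_MS_PS"] + point["cov_Fec_PS"])
        + point["remainder"]
    )
    assert abs(listed - point["I_total"]) <= 1e-12 * max(1.0, abs(point["I_total"]))

    def as_dict(vec: np.ndarray | float | None) -> dict[str, float] | None:
        if vec is None:
            return None
        return dict(zip(TERM_NAMES, (float(x) for x in np.asarray(vec))))

    return DecompositionResult(
        terms=point,
        boot_mean=as_dict(res.boot_mean),
        ci_low=as_dict(res.ci_low),
        ci_high=as_dict(res.ci_high),
        n=ms.size,
        n_boot=n_boot,
        seed=seed,
        warning=res.warning,
    )


def decompose(
    records: Iterable[FitnessRecord],
    n_boot: int = resampling.DEFAULT_N_RESAMPLES,
    level: float = 0.95,
    seed: SeedLike = 0,
    paternity_share: str = "pooled",
    include_unmated: bool = True,
) -> DecompositionResult:
    """Decompose the opportunity for selection of one cell of male records.

    ``include_unmated=False`` drops MS = 0 males before decomposing (an
    alternative convention; the default keeps them, as zero-fitness males
    contribute to the variance). With the per-partner-mean paternity share
    the identity T = MS * Fec * PS is inexact; the mean absolute residual is
    reported on the result.
    """
    comps = [components_from_record(r, paternity_share) for r in records]
    if not include_unmated:
        comps = [c for c in comps if c.ms > 0]
    if len(comps) < 2:
        raise InsufficientDataError(f"need >= 2 males, got {len(comps)}")
    ms = np.array([c.ms for c in comps], dtype=float)
    fec = np.array([c.fec for c in comps], dtype=float)
    ps = np.array([c.ps for c in comps], dtype=float)
    t = np.array([c.total for c in comps], dtype=float)
    residual = float(np.mean(np.abs(ms * fec * ps - t)))
    if paternity_share == "pooled":
        assert residual <= 1e-9, "pooled components must satisfy T = MS*Fec*PS"
    result = decompose_components(
        ms, fec, ps, total=t, n_boot=n_boot, level=level, seed=seed
    )
    result.paternity_share = paternity_share
    result.identity_residual = residual
    return result
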