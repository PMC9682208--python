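"""Male fitness-component decomposition: identities, oracle, conservation."""

from __future__ import annotations

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matefit.decomposition import (
    TERM_NAMES,
    components_from_record,
    decompose,
    decompose_components,
)
from matefit.errors import CapabilityError, DegenerateGroupError, InsufficientDataError
from matefit.datamodel import FitnessRecord

from conftest import male_record


# ------------------------------------------------------------------- components


def test_components_hand_example():
    c = components_from_record(male_record((20, 10), (10, 5)))
    assert (c.ms, c.fec, c.ps, c.total) == (2, 15.0, 0.5, 15)
    assert c.ms * c.fec * c.ps == pytest.approx(c.total)


def test_components_zero_convention():
    c = components_from_record(male_record((20, 10), (0, 0)))
    assert (c.ms, c.fec, c.ps, c.total) == (0, 0.0, 0.0, 0)


def test_components_single_partner():
    c = components_from_record(male_record((8, 12), (8, 0)))
    assert (c.ms, c.fec, c.ps, c.total) == (1, 8.0, 1.0, 8)


def test_components_totals_only_capability_error():
    rec = FitnessRecord(
        focal_id="m-x",
        sex="male",
        flour="wheat",
        yeast="none",
        assay="whole_group",
        partner_total=(None, None),
        partner_sired=(7, None),
    )
    with pytest.raises(CapabilityError, match="per-partner"):
        components_from_record(rec)


def test_components_female_rejected(tiny_dataset):
    female = [r for r in tiny_dataset if r.sex == "female"][0]
    with pytest.raises(ValueError):
        components_from_record(female)


@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)).map(
            lambda ts: (max(ts), min(ts))
        ),
        min_size=2,
        max_size=2,
    )
)
def test_identity_exact_for_pooled_components(pairs):
    rec = male_record(tuple(t for t, _ in pairs), tuple(s for _, s in pairs))
    c = components_from_record(rec)
    assert c.ms * c.fec * c.ps == pytest.approx(c.total, abs=1e-9)


def test_per_partner_mean_variant_has_residual():
    rec = male_record((20, 10), (10, 9))  # shares 0.5 and 0.9 differ
    pooled = components_from_record(rec, "pooled")
    variant = components_from_record(rec, "per_partner_mean")
    assert pooled.ms * pooled.fec * pooled.ps == pytest.approx(pooled.total)
    assert variant.ps == pytest.approx((10 / 20 + 9 / 10) / 2)
    assert variant.ms * variant.fec * variant.ps != pytest.approx(variant.total)


# ------------------------------------------------------------------- decompose


def brute_force_terms(ms, fec, ps, t):
    """Direct computation from the definitions, stdlib only."""
    rel = {}
    for name, vals in (("ms", ms), ("fec", fec), ("ps", ps), ("t", t)):
        mean = sum(vals) / len(vals)
        rel[name] = [v / mean for v in vals]

    def var(v):
        return statistics.variance(v)

    def cov(a, b):
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        return sum((x - ma) * (y - mb) for x, y in zip(a, b)) / (len(a) - 1)

    i_total = var(rel["t"])
    terms = {
        "I_MS": var(rel["ms"]),
        "I_Fec": var(rel["fec"]),
        "I_PS": var(rel["ps"]),
        "cov_MS_Fec": cov(rel["ms"], rel["fec"]),
        "cov_MS_PS": cov(rel["ms"], rel["ps"]),
        "cov_Fec_PS": cov(rel["fec"], rel["ps"]),
        "I_total": i_total,
    }
    terms["remainder"] = i_total - (
        terms["I_MS"]
        + terms["I_Fec"]
        + terms["I_PS"]
        + 2 * (terms["cov_MS_Fec"] + terms["cov_MS_PS"] + terms["cov_Fec_PS"])
    )
    return terms


def test_matches_brute_force_oracle_small_n():
    records = [
        male_record((20, 10), (10, 5)),
        male_record((8, 12), (8, 0)),
        male_record((15, 15), (3, 12)),
        male_record((30, 5), (30, 5)),
        male_record((9, 9), (1, 1)),
        male_record((22, 11), (0, 11)),
    ]
    comps = [components_from_record(r) for r in records]
    oracle = brute_force_terms(
        [c.ms for c in comps],
        [c.fec for c in comps],
        [c.ps for c in comps],
        [c.total for c in comps],
    )
    result = decompose(records, n_boot=0)
    for name in TERM_NAMES:
        assert result.terms[name] == pytest.approx(oracle[name], rel=1e-12, abs=1e-12)


def test_all_identical_males_all_terms_zero():
    records = [male_record((20, 10), (10, 5)) for _ in range(5)]
    res = decompose(records, n_boot=0)
    for name in TERM_NAMES:
        assert res.terms[name] == pytest.approx(0.0, abs=1e-14)


@given(
    data=st.lists(
        st.tuples(
            st.integers(1, 2),
            st.floats(0.5, 30.0),
            st.floats(0.05, 1.0),
        ),
        min_size=2,
        max_size=25,
    )
)
@settings(max_examples=100)
def test_conservation_identity(data):
    ms = np.array([d[0] for d in data], dtype=float)
    fec = np.array([d[1] for d in data], dtype=float)
    ps = np.array([d[2] for d in data], dtype=float)
    res = decompose_components(ms, fec, ps, n_boot=0)
    total = (
        res.terms["I_MS"]
        + res.terms["I_Fec"]
        + res.terms["I_PS"]
        + 2
        * (res.terms["cov_MS_Fec"] + res.terms["cov_MS_PS"] + res.terms["cov_Fec_PS"])
        + res.terms["remainder"]
    )
    assert total == pytest.approx(res.terms["I_total"], abs=1e-12)


def test_independent_components_closed_form():
    rng = np.random.default_rng(8)
    n = 40_000
    ms = rng.gamma(10.0, 1 / 10.0, n)  # mean 1, I = 0.1
    fec = rng.gamma(5.0, 1 / 5.0, n)  # mean 1, I = 0.2
    ps = rng.gamma(20.0, 1 / 20.0, n)  # mean 1, I = 0.05
    res = decompose_components(ms, fec, ps, n_boot=0)
    i_ms, i_fec, i_ps = res.terms["I_MS"], res.terms["I_Fec"], res.terms["I_PS"]
    closed = (1 + i_ms) * (1 + i_fec) * (1 + i_ps) - 1 - (i_ms + i_fec + i_ps)
    assert res.terms["cov_MS_Fec"] == pytest.approx(0.0, abs=0.01)
    assert res.terms["cov_MS_PS"] == pytest.approx(0.0, abs=0.01)
    assert res.terms["cov_Fec_PS"] == pytest.approx(0.0, abs=0.01)
    assert res.terms["remainder"] + 2 * (
        res.terms["cov_MS_Fec"] + res.terms["cov_MS_PS"] + res.terms["cov_Fec_PS"]
    ) == pytest.approx(closed, abs=0.05)


def test_constant_ms_full_paternity_collapses_to_fecundity():
    # MS constant, PS = 1: T is proportional to Fec, so I_total = I_Fec exactly
    records = [
        male_record((t1, t2), (t1, t2))
        for t1, t2 in [(20, 10), (5, 25), (12, 12), (30, 3), (9, 14)]
    ]
    res = decompose(records, n_boot=0)
    assert res.terms["I_MS"] == pytest.approx(0.0, abs=1e-14)
    assert res.terms["I_PS"] == pytest.approx(0.0, abs=1e-14)
    assert res.terms["cov_MS_Fec"] == pytest.approx(0.0, abs=1e-14)
    assert res.terms["I_total"] == pytest.approx(res.terms["I_Fec"], abs=1e-12)
    assert res.terms["remainder"] == pytest.approx(0.0, abs=1e-12)


def test_decompose_bootstrap_deterministic_with_cis():
    rng = np.random.default_rng(4)
    records = [
        male_record(
            (int(rng.integers(5, 30)), int(rng.integers(5, 30))),
            (0, 0),
        )
        for _ in range(12)
    ]
    # give everyone some paternity so means are positive
    records = [
        male_record(r.partner_total, (r.partner_total[0] // 2, r.partner_total[1] // 3))
        for r in records
    ]
    r1 = decompose(records, n_boot=150, seed=6)
    r2 = decompose(records, n_boot=150, seed=6)
    assert r1.terms == r2.terms and r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high
    for name in TERM_NAMES:
        assert r1.ci_low[name] <= r1.boot_mean[name] <= r1.ci_high[name]


def test_decompose_errors():
    with pytest.raises(InsufficientDataError):
        decompose([male_record((5, 5), (2, 2))], n_boot=0)
    unmated = [male_record((5, 5), (0, 0)) for _ in range(4)]
    with pytest.raises(DegenerateGroupError):
        decompose(unmated, n_boot=0)


def test_include_unmated_switch():
    records = [
        male_record((10, 10), (5, 5)),
        male_record((10, 10), (0, 0)),
        male_record((20, 10), (10, 0)),
    ]
    full = decompose(records, n_boot=0)
    mated_only = decompose(records, n_boot=0, include_unmated=False)
    assert full.n == 3 and mated_only.n == 2
    assert full.terms["I_total"] > mated_only.terms["I_total"]
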