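"""Shared fixtures and dataset builders."""

from __future__ import annotations

import itertools

import pytest

from matefit.datamodel import Dataset, FitnessRecord

_counter = itertools.count()


def female_record(
    clutch: int,
    assay: str = "focal_only",
    flour: str = "wheat",
    yeast: str = "control_5pct",
    survived: bool = True,
    body_mass: float | None = 2.2,
    laying_week: str | None = None,
) -> FitnessRecord:
    return FitnessRecord(
        focal_id=f"f{next(_counter):05d}",
        sex="female",
        flour=flour,
        yeast=yeast,
        assay=assay,
        body_mass_mg=body_mass,
        survived=survived,
        partner_total=(clutch, None),
        partner_sired=(clutch, None),
        laying_week=laying_week,
    )


def male_record(
    totals: tuple[int, int],
    sired: tuple[int, int],
    assay: str = "focal_only",
    flour: str = "wheat",
    yeast: str = "control_5pct",
    body_mass: float | None = 2.0,
) -> FitnessRecord:
    return FitnessRecord(
        focal_id=f"m{next(_counter):05d}",
        sex="male",
        flour=flour,
        yeast=yeast,
        assay=assay,
        body_mass_mg=body_mass,
        partner_total=totals,
        partner_sired=sired,
    )


def females_dataset(values, **kw) -> Dataset:
    """Dataset of female records with the given clutch sizes."""
    return Dataset(records=[female_record(v, **kw) for v in values])


def two_sex_dataset(
    male_control,
    male_stressed,
    female_control,
    female_stressed,
    assay: str = "focal_only",
    flour: str = "wheat",
    stressed_yeast: str = "none",
) -> Dataset:
    """Control/stressed cells for both sexes; males get totals-only-free
    records with all offspring on partner 1 so W equals the given value."""
    records = []
    for w in male_control:
        records.append(male_record((w, 0), (w, 0), assay=assay, flour=flour))
    for w in male_stressed:
        records.append(
            male_record((w, 0), (w, 0), assay=assay, flour=flour, yeast=stressed_yeast)
        )
    records += [female_record(w, assay=assay, flour=flour) for w in female_control]
    records += [
        female_record(w, assay=assay, flour=flour, yeast=stressed_yeast)
        for w in female_stressed
    ]
    return Dataset(records=records)


@pytest.fixture
def tiny_dataset() -> Dataset:
    return Dataset(
        records=[
            male_record((20, 10), (10, 5)),
            male_record((8, 12), (8, 0)),
            female_record(12),
            female_record(0, survived=False),
        ]
    )
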