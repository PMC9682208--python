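"""Tidy data model for competitive mating-assay fitness tables.

One row per focal individual. A focal male is assayed in a group with one
competitor male and two partner females; his reproductive success is the
number of offspring assigned to him by the dominant visible marker, split
per partner female. A focal female's reproductive success is her own clutch,
stored in the first partner slot with ``sired == total``.

CSV schema (UTF-8, comma separated, header required)::

    focal_id, sex, flour, yeast, assay, genotype, body_mass_mg, survived,
    p1_total, p1_sired, p2_total, p2_sired, laying_week

Missing values are empty fields. Two male dialects are supported:

* full detail — both ``(p{j}_total, p{j}_sired)`` pairs present, enabling
  the fitness-component decomposition;
* totals-only — ``p1_sired`` holds the male's total sired offspring and all
  ``p*_total`` fields are empty; the decomposition is unavailable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, ValidationError

SEXES = ("male", "female")
FLOURS = ("wheat", "whole_wheat")
YEASTS = ("control_5pct", "low_1pct", "none")
ASSAYS = ("focal_only", "whole_group")
GENOTYPES = ("wildtype", "Rd")
LAYING_WEEKS = ("week1", "week2", "combined")

CONTROL_YEAST = "control_5pct"

COLUMNS = (
    "focal_id",
    "sex",
    "flour",
    "yeast",
    "assay",
    "genotype",
    "body_mass_mg",
    "survived",
    "p1_total",
    "p1_sired",
    "p2_total",
    "p2_sired",
    "laying_week",
)


@dataclass
class FitnessRecord:
    """Design cell, condition proxy and reproductive outcome of one focal."""

    focal_id: str
    sex: str
    flour: str
    yeast: str
    assay: str
    genotype: str = "wildtype"
    body_mass_mg: float | None = None
    survived: bool = True
    partner_total: tuple[int | None, ...] = (None, None)
    partner_sired: tuple[int | None, ...] = (None, None)
    laying_week: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def cell(self) -> tuple[str, str, str, str]:
        """(assay, sex, flour, yeast) design-cell key."""
        return (self.assay, self.sex, self.flour, self.yeast)

    @property
    def has_partner_detail(self) -> bool:
        """True when per-partner (total, sired) pairs are fully populated."""
        if self.sex == "female":
            return False
        return all(
            t is not None and s is not None
            for t, s in zip(self.partner_total, self.partner_sired)
        )


@dataclass
class Dataset:
    """A validated collection of :class:`FitnessRecord`."""

    records: list[FitnessRecord] = field(default_factory=list)
    provenance: str = ""
    validation_report: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FitnessRecord]:
        return iter(self.records)

    @property
    def has_partner_detail(self) -> bool:
        """True when every male record carries per-partner detail."""
        males = [r for r in self.records if r.sex == "male"]
        return bool(males) and all(r.has_partner_detail for r in males)

    def select(self, **criteria: object) -> list[FitnessRecord]:
        """Records whose attributes match all keyword criteria."""
        out = self.records
        for key, value in criteria.items():
            out = [r for r in out if getattr(r, key) == value]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat per-focal frame with derived fitness columns.

        Adds ``offspring`` (reproductive success) and, for full-detail
        males, ``mating_success`` (number of partners with >=1 sired).
        """
        rows = []
        for r in self.records:
            ms = None
            if r.sex == "male" and r.has_partner_detail:
                ms = sum(1 for s in r.partner_sired if s is not None and s > 0)
            rows.append(
                {
                    "focal_id": r.focal_id,
                    "sex": r.sex,
                    "flour": r.flour,
                    "yeast": r.yeast,
                    "assay": r.assay,
                    "genotype": r.genotype,
                    "body_mass_mg": r.body_mass_mg,
                    "survived": r.survived,
                    "laying_week": r.laying_week,
                    "offspring": reproductive_success(r),
                    "mating_success": ms,
                }
            )
        return pd.DataFrame(rows)


def reproductive_success(record: FitnessRecord) -> int:
    """Total offspring sired by (males) or produced by (females) the focal.

    Sum over partners of the focal-sired count; invariant to partner order.
    For females this equals the clutch total by construction.
    """
    return int(sum(s for s in record.partner_sired if s is not None))


def per_female_scaled_success(record: FitnessRecord, n_partners: int = 2) -> float:
    """Male reproductive success divided by the number of partner females.

    Display/comparison convenience only: selection coefficients and the
    opportunity for selection are invariant to this common rescaling.
    """
    if n_partners < 1:
        raise ValueError("n_partners must be >= 1")
    if record.sex != "male":
        raise ValueError("per-female scaling applies to male records")
    return reproductive_success(record) / n_partners


# ---------------------------------------------------------------------------
# validation


def validate_record(record: FitnessRecord) -> list[str]:
    """Return invariant violations for one record (empty list = valid)."""
    v: list[str] = []
    rid = record.focal_id

    def bad(rule: str, detail: str) -> None:
        v.append(f"{rid}: [{rule}] {detail}")

    if record.sex not in SEXES:
        bad("enum", f"unknown sex {record.sex!r}")
    if record.flour not in FLOURS:
        bad("enum", f"unknown flour {record.flour!r}")
    if record.yeast not in YEASTS:
        bad("enum", f"unknown yeast {record.yeast!r}")
    if record.assay not in ASSAYS:
        bad("enum", f"unknown assay {record.assay!r}")
    if record.genotype not in GENOTYPES:
        bad("enum", f"unknown genotype {record.genotype!r}")
    if record.laying_week is not None and record.laying_week not in LAYING_WEEKS:
        bad("enum", f"unknown laying_week {record.laying_week!r}")

    if record.yeast == "low_1pct" and record.flour != "whole_wheat":
        bad("design", "low_1pct yeast occurs only with whole_wheat flour")

    if record.body_mass_mg is not None and record.body_mass_mg < 0:
        bad("range", f"negative body mass {record.body_mass_mg}")

    for j, (t, s) in enumerate(zip(record.partner_total, record.partner_sired), 1):
        if t is not None and t < 0:
            bad("range", f"negative p{j}_total {t}")
        if s is not None and s < 0:
            bad("range", f"negative p{j}_sired {s}")
        if t is not None and s is not None and s > t:
            bad("sired<=total", f"p{j}_sired {s} exceeds p{j}_total {t}")

    if record.sex == "female":
        if record.partner_total[1:] != (None,) * len(record.partner_total[1:]) or (
            record.partner_sired[1:] != (None,) * len(record.partner_sired[1:])
        ):
            bad("female-single-clutch", "female rows must leave p2_* empty")
        t0, s0 = record.partner_total[0], record.partner_sired[0]
        if t0 is None or s0 is None:
            bad("female-single-clutch", "female rows need p1_total = p1_sired = clutch")
        elif t0 != s0:
            bad("female-single-clutch", f"p1_sired {s0} != p1_total {t0}")
    else:
        sired_present = [s is not None for s in record.partner_sired]
        totals_present = [t is not None for t in record.partner_total]
        if not any(sired_present):
            bad("male-counts", "male rows need sired counts (p1_sired at least)")
        elif any(totals_present) and not all(
            totals_present[j] == sired_present[j] for j in range(len(sired_present))
        ):
            bad("male-counts", "partner (total, sired) pairs must be jointly present")

    return v


def validate_dataset(records: Iterable[FitnessRecord]) -> list[str]:
    """Record-level violations plus focal_id uniqueness within design cells."""
    records = list(records)
    report: list[str] = []
    for r in records:
        report.extend(validate_record(r))
    seen: dict[tuple, str] = {}
    for r in records:
        key = (*r.cell, r.focal_id, r.laying_week)
        if key in seen:
            report.append(
                f"{r.focal_id}: [unique-id] duplicate focal_id within cell {r.cell}"
            )
        seen[key] = r.focal_id
    return report


# ---------------------------------------------------------------------------
# CSV reader / writer


def _parse_int(raw: str, column: str, rid: str, errors: list[str]) -> int | None:
    if raw == "":
        return None
    try:
        val = int(raw)
    except ValueError:
        errors.append(f"{rid}: [parse] non-integer {column}={raw!r}")
        return None
    return val


def _parse_bool(raw: str, rid: str, errors: list[str]) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes"):
        return True
    if low in ("false", "0", "no"):
        return False
    errors.append(f"{rid}: [parse] non-boolean survived={raw!r}")
    return True


def read_fitness_table(path: str | Path, strict: bool = True) -> Dataset:
    """Read and validate a fitness-table CSV.

    In strict mode any violation raises :class:`ValidationError`; in lenient
    mode offending records are flagged (never silently dropped) and the
    violations collected in ``Dataset.validation_report``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        records: list[FitnessRecord] = []
        parse_errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            rid = (row.get("focal_id") or f"<line {lineno}>").strip()
            rec = FitnessRecord(
                focal_id=rid,
                sex=(row.get("sex") or "").strip(),
                flour=(row.get("flour") or "").strip(),
                yeast=(row.get("yeast") or "").strip(),
                assay=(row.get("assay") or "").strip(),
                genotype=(row.get("genotype") or "wildtype").strip() or "wildtype",
                body_mass_mg=(
                    float(row["body_mass_mg"]) if (row.get("body_mass_mg") or "").strip() else None
                ),
                survived=_parse_bool(row.get("survived") or "true", rid, parse_errors),
                partner_total=(
                    _parse_int((row.get("p1_total") or "").strip(), "p1_total", rid, parse_errors),
                    _parse_int((row.get("p2_total") or "").strip(), "p2_total", rid, parse_errors),
                ),
                partner_sired=(
                    _parse_int((row.get("p1_sired") or "").strip(), "p1_sired", rid, parse_errors),
                    _parse_int((row.get("p2_sired") or "").strip(), "p2_sired", rid, parse_errors),
                ),
                laying_week=((row.get("laying_week") or "").strip() or None),
            )
            records.append(rec)

    report = parse_errors + validate_dataset(records)
    if report and strict:
        raise ValidationError(report)
    if report:
        flagged = {line.split(":", 1)[0] for line in report}
        records = [
            replace(r, flags=tuple(l for l in report if l.startswith(f"{r.focal_id}:")))
            if r.focal_id in flagged
            else r
            for r in records
        ]
    return Dataset(records=records, provenance=str(path), validation_report=report)


def write_fitness_table(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset back to the documented CSV schema (lossless)."""
    path = Path(path)

    def fmt(x: object) -> str:
        if x is None:
            return ""
        if isinstance(x, bool):
            return "true" if x else "false"
        return repr(x) if isinstance(x, float) else str(x)

    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for r in dataset.records:
            writer.writerow(
                [
                    r.focal_id,
                    r.sex,
                    r.flour,
                    r.yeast,
                    r.assay,
                    r.genotype,
                    fmt(r.body_mass_mg),
                    fmt(r.survived),
                    fmt(r.partner_total[0]),
                    fmt(r.partner_sired[0]),
                    fmt(r.partner_total[1]),
                    fmt(r.partner_sired[1]),
                    fmt(r.laying_week),
                ]
            )
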