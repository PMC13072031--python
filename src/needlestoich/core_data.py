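"""Typed data model and CSV I/O for needle and soil elemental samples.

The study design this package targets is a within-branch contrast in a
conifer plantation: per tree, one composite needle sample from the apical
(green) section and one from the basal (chlorotic or comparable) section of
the crown, plus one composite soil sample per 20 cm depth layer down to
100 cm. Concentrations are total C, N and P in mg per g dry mass.

All downstream modules consume :class:`StudyDataset`; all validation lives
here so ratios and indices can assume strictly positive concentrations and
a unique (tree, position-or-layer) key.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

Condition = Literal["healthy", "chlorotic"]
Compartment = Literal["needle", "soil"]
Position = Literal["apical", "basal"]
SoilLayer = Literal["0-20", "20-40", "40-60", "60-80", "80-100"]

SOIL_LAYERS: tuple[str, ...] = ("0-20", "20-40", "40-60", "60-80", "80-100")
CONDITIONS: tuple[str, ...] = ("healthy", "chlorotic")
POSITIONS: tuple[str, ...] = ("apical", "basal")

#: Canonical CSV column order; the one and only dialect (UTF-8, '.', ',').
NEEDLE_COLUMNS = ["sample_id", "tree_id", "condition", "position", "c_mg_g", "n_mg_g", "p_mg_g"]
SOIL_COLUMNS = ["sample_id", "tree_id", "condition", "soil_layer", "c_mg_g", "n_mg_g", "p_mg_g"]

#: Needle group codes used throughout: condition x branch position.
#: AH/BH = apical/basal needles of healthy trees, AC/BC = of chlorotic trees.
GROUP_CODES = ("AH", "BH", "AC", "BC")


class SampleValidationError(ValueError):
    """A sample violates a field-level or dataset-level invariant."""


class SchemaError(ValueError):
    """An input table is missing required columns."""


class ElementalSample(BaseModel):
    """One measured composite specimen (needle or soil) with C/N/P content.

    Concentrations are mass-based, mg per g dry mass; no molar conversion
    is done anywhere in the package.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    tree_id: str
    condition: Condition
    compartment: Compartment
    position: Optional[Position] = None
    soil_layer: Optional[SoilLayer] = None
    c_conc: float = Field(gt=0.0, lt=1000.0)
    n_conc: float = Field(gt=0.0, lt=1000.0)
    p_conc: float = Field(gt=0.0, lt=1000.0)

    @model_validator(mode="after")
    def _compartment_fields(self) -> "ElementalSample":
        if self.compartment == "needle":
            if self.position is None:
                raise ValueError(f"sample {self.sample_id!r}: needle sample requires a position")
            if self.soil_layer is not None:
                raise ValueError(f"sample {self.sample_id!r}: needle sample must not set soil_layer")
        else:
            if self.soil_layer is None:
                raise ValueError(f"sample {self.sample_id!r}: soil sample requires a soil_layer")
            if self.position is not None:
                raise ValueError(f"sample {self.sample_id!r}: soil sample must not set position")
        return self

    @property
    def group(self) -> str:
        """Needle group code (AH/BH/AC/BC); undefined for soil samples."""
        if self.compartment != "needle":
            raise ValueError(f"sample {self.sample_id!r} is not a needle sample")
        return ("A" if self.position == "apical" else "B") + ("H" if self.condition == "healthy" else "C")

    @property
    def key(self) -> tuple:
        return (self.tree_id, self.compartment, self.position or self.soil_layer)


class StudyDataset(BaseModel):
    """All needle and soil samples of one study run, with design invariants.

    Invariants enforced: per-dataset uniqueness of the (tree, position) /
    (tree, layer) key — the design analyses one composite per slot — and
    that every tree contributing a basal needle sample also contributes an
    apical one, since resorption pairing needs both.
    """

    model_config = ConfigDict(frozen=True)

    needles: tuple[ElementalSample, ...]
    soils: tuple[ElementalSample, ...]
    provenance: str = ""

    def __init__(self, **data):
        # surface design-invariant violations as SampleValidationError
        # instead of pydantic's wrapper, so callers can catch one type
        try:
            super().__init__(**data)
        except ValidationError as exc:
            msgs = "; ".join(e["msg"] for e in exc.errors())
            if "apical partner" in msgs or "duplicate key" in msgs:
                raise SampleValidationError(msgs) from None
            raise

    @model_validator(mode="after")
    def _design_invariants(self) -> "StudyDataset":
        for s in self.needles:
            if s.compartment != "needle":
                raise ValueError(f"sample {s.sample_id!r}: non-needle sample in needles")
        for s in self.soils:
            if s.compartment != "soil":
                raise ValueError(f"sample {s.sample_id!r}: non-soil sample in soils")
        _check_unique_keys(self.needles)
        _check_unique_keys(self.soils)
        apical = {s.tree_id for s in self.needles if s.position == "apical"}
        for s in self.needles:
            if s.position == "basal" and s.tree_id not in apical:
                raise SampleValidationError(
                    f"tree {s.tree_id!r} has a basal needle sample but no apical partner"
                )
        return self

    def needle_frame(self) -> pd.DataFrame:
        return samples_to_frame(self.needles)

    def soil_frame(self) -> pd.DataFrame:
        return samples_to_frame(self.soils)


def _check_unique_keys(samples: Sequence[ElementalSample]) -> None:
    seen: dict[tuple, str] = {}
    for s in samples:
        if s.key in seen:
            raise SampleValidationError(
                f"duplicate key {s.key}: samples {seen[s.key]!r} and {s.sample_id!r} "
                "occupy the same (tree, position/layer) slot"
            )
        seen[s.key] = s.sample_id


def samples_to_frame(samples: Iterable[ElementalSample]) -> pd.DataFrame:
    """Tidy DataFrame view of a sample collection in canonical column order."""
    rows = []
    compartment = None
    for s in samples:
        compartment = s.compartment
        row = {
            "sample_id": s.sample_id,
            "tree_id": s.tree_id,
            "condition": s.condition,
            "c_mg_g": s.c_conc,
            "n_mg_g": s.n_conc,
            "p_mg_g": s.p_conc,
        }
        if s.compartment == "needle":
            row["position"] = s.position
        else:
            row["soil_layer"] = s.soil_layer
        rows.append(row)
    cols = NEEDLE_COLUMNS if compartment == "needle" else SOIL_COLUMNS
    return pd.DataFrame(rows, columns=cols if rows else cols)


def read_samples(
    path: str | Path,
    schema: Literal["needle", "soil"],
    columns: Mapping[str, str] | None = None,
) -> list[ElementalSample]:
    """Read and validate a needle or soil CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        ``"needle"`` expects a ``position`` column, ``"soil"`` a
        ``soil_layer`` column (values literally ``0-20`` ... ``80-100``).
    columns
        Optional mapping from canonical column names to the names actually
        present in the file, for external deposits whose headers differ.

    Raises
    ------
    SchemaError
        A required column is missing (the message names it).
    SampleValidationError
        A row fails validation; the message carries the 1-based data row
        number and sample_id, and all bad rows are reported together.
    """
    path = Path(path)
    required = NEEDLE_COLUMNS if schema == "needle" else SOIL_COLUMNS
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if columns:
        rename = {v: k for k, v in columns.items()}
        missing_src = [v for v in columns.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(f"{path}: mapped column(s) not found: {', '.join(missing_src)}")
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    samples: list[ElementalSample] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = {c: getattr(row, c) for c in required}
        sid = rec.get("sample_id", f"<row {i}>")
        try:
            fields = dict(
                sample_id=rec["sample_id"],
                tree_id=rec["tree_id"],
                condition=rec["condition"],
                compartment=schema,
                c_conc=_parse_conc(rec["c_mg_g"], "c_mg_g", sid),
                n_conc=_parse_conc(rec["n_mg_g"], "n_mg_g", sid),
                p_conc=_parse_conc(rec["p_mg_g"], "p_mg_g", sid),
            )
            if schema == "needle":
                fields["position"] = rec["position"]
            else:
                fields["soil_layer"] = rec["soil_layer"]
            samples.append(ElementalSample(**fields))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i} (sample_id={sid!r}): {exc}")
    if problems:
        raise SampleValidationError(f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems))
    _check_unique_keys(samples)
    return samples


def _parse_conc(raw: str, field: str, sample_id: str) -> float:
    if raw == "" or raw is None:
        raise ValueError(f"sample {sample_id!r}: missing value in {field} (missing data are rejected, not imputed)")
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(f"sample {sample_id!r}: non-numeric {field}={raw!r}") from None
    if not value > 0.0:
        raise ValueError(f"sample {sample_id!r}: {field}={value} must be strictly positive")
    if not value < 1000.0:
        raise ValueError(f"sample {sample_id!r}: {field}={value} exceeds 1000 mg/g")
    return value


def write_samples(samples: Sequence[ElementalSample], path: str | Path) -> None:
    """Write samples as CSV in the canonical column order.

    ``read_samples`` inverts this bit-exactly: floats are serialized with
    Python's shortest-roundtrip repr. Writing an empty collection is an
    error rather than an empty file.
    """
    if not samples:
        raise ValueError("refusing to write an empty sample collection")
    compartments = {s.compartment for s in samples}
    if len(compartments) != 1:
        raise ValueError("cannot mix needle and soil samples in one file")
    _check_unique_keys(samples)
    df = samples_to_frame(samples)
    for col in ("c_mg_g", "n_mg_g", "p_mg_g"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False, encoding="utf-8")


def read_study(
    needles_path: str | Path,
    soils_path: str | Path,
    columns_needle: Mapping[str, str] | None = None,
    columns_soil: Mapping[str, str] | None = None,
    provenance: str = "",
) -> StudyDataset:
    """Read the pair of CSVs making up one study into a validated dataset."""
    needles = read_samples(needles_path, "needle", columns=columns_needle)
    soils = read_samples(soils_path, "soil", columns=columns_soil)
    return StudyDataset(
        needles=tuple(needles),
        soils=tuple(soils),
        provenance=provenance or f"{needles_path};{soils_path}",
    )
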