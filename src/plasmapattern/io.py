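"""Cohort and presence/absence data model with TSV readers/writers.

Containers
----------
``Sample`` / ``CohortTable``
    Per-subject demographics (sex, age, height, weight), the derived body
    mass index (BMI, kg/m^2), the BMI group label, and a set of named
    clinical blood parameters (missing values stored as NaN).
``PresenceMatrix``
    Binary sample x protein matrix: entry (i, j) is 1 iff protein j (a
    UniProt accession) was identified in the plasma of sample i.

All on-disk formats are plain UTF-8 TSV with a header row and "." as the
decimal separator; see the functions below for the exact layouts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ParseError

#: BMI group labels in ascending BMI order.
GROUPS: tuple[str, ...] = ("NORM", "OW", "OB1", "OB2", "OB3")

#: Lower edges of the half-open BMI intervals [18.5,25), [25,30), [30,35),
#: [35,40), [40, inf). 18.5 is the study inclusion floor.
GROUP_EDGES: tuple[float, ...] = (18.5, 25.0, 30.0, 35.0, 40.0)

SEXES: tuple[str, str] = ("f", "m")

# UniProt accession shape (release-era canonical patterns, 6 or 10 chars).
UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

_REQUIRED_COHORT_COLUMNS = ("sample_id", "sex", "age", "height", "weight")
_RESERVED_COHORT_COLUMNS = _REQUIRED_COHORT_COLUMNS + ("group", "bmi")


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m^2 from weight in kg and height in cm.

    Accepts scalars or numpy arrays; raises :class:`DomainError` on any
    non-positive input.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise DomainError(
            f"weight and height must be positive (got weight={weight!r}, height={height!r})"
        )
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def assign_group(bmi: float) -> str:
    """Map a BMI to its group label on the half-open intervals.

    NORM [18.5, 25), OW [25, 30), OB1 [30, 35), OB2 [35, 40), OB3 [40, inf).
    BMI below the 18.5 inclusion floor is flagged with :class:`DomainError`
    rather than silently grouped.
    """
    b = float(bmi)
    if not np.isfinite(b):
        raise DomainError(f"BMI must be finite, got {bmi!r}")
    if b < GROUP_EDGES[0]:
        raise DomainError(
            f"BMI {b:.2f} is below the study inclusion floor of {GROUP_EDGES[0]}"
        )
    idx = int(np.searchsorted(GROUP_EDGES, b, side="right")) - 1
    return GROUPS[idx]


def assign_groups(bmi: Iterable[float]) -> list[str]:
    """Vectorised :func:`assign_group`."""
    return [assign_group(b) for b in bmi]


@dataclass
class Sample:
    """One study subject.

    ``clinical`` maps parameter name -> value (NaN marks a missing
    measurement). ``bmi`` is kg/m^2; ``height`` cm; ``weight`` kg.
    """

    sample_id: str
    group: str
    sex: str
    age: float
    height: float
    weight: float
    bmi: float
    clinical: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"sample {self.sample_id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise DataError(f"sample {self.sample_id}: sex must be 'f' or 'm'")
        if self.height <= 0 or self.weight <= 0:
            raise DomainError(
                f"sample {self.sample_id}: non-positive height/weight "
                f"({self.height}, {self.weight})"
            )
        expected = compute_bmi(self.weight, self.height)
        if abs(expected - self.bmi) > 0.5:
            raise DataError(
                f"sample {self.sample_id}: bmi {self.bmi:.2f} inconsistent with "
                f"weight/height (expected {expected:.2f})"
            )


class CohortTable:
    """Ordered collection of :class:`Sample` with a shared clinical panel.

    Every sample carries a value (possibly NaN) for every name in
    ``parameter_names``; sample ids are unique.
    """

    def __init__(
        self,
        samples: Sequence[Sample],
        parameter_names: Sequence[str] | None = None,
    ) -> None:
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DataError(f"duplicate sample_id(s): {sorted(dupes)}")
        if parameter_names is None:
            parameter_names = []
            for s in samples:
                for name in s.clinical:
                    if name not in parameter_names:
                        parameter_names.append(name)
        self.parameter_names: list[str] = list(parameter_names)
        for s in samples:
            s.validate()
            for name in self.parameter_names:
                s.clinical.setdefault(name, float("nan"))
        self.samples: list[Sample] = samples

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def bmi(self) -> np.ndarray:
        return np.array([s.bmi for s in self.samples], dtype=float)

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.samples]

    def subset(self, sample_ids: Sequence[str]) -> "CohortTable":
        """New cohort containing ``sample_ids`` in the given order."""
        by_id = {s.sample_id: s for s in self.samples}
        missing = [i for i in sample_ids if i not in by_id]
        if missing:
            raise DataError(f"unknown sample_id(s): {missing}")
        return CohortTable([by_id[i] for i in sample_ids], self.parameter_names)

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical parameters as a samples x parameters DataFrame."""
        data = {
            name: [s.clinical.get(name, np.nan) for s in self.samples]
            for name in self.parameter_names
        }
        return pd.DataFrame(data, index=self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "group": s.group,
                "sex": s.sex,
                "age": s.age,
                "height": s.height,
                "weight": s.weight,
                "bmi": s.bmi,
            }
            row.update({name: s.clinical.get(name, np.nan) for name in self.parameter_names})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        return _cohort_from_frame(df, source="<dataframe>")

    def write_tsv(self, path: str | Path) -> None:
        # %.17g preserves doubles exactly, so write -> read is lossless
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.to_dataframe().equals(other.to_dataframe())


def _parse_numeric(value, *, row: str, column: str, source: str) -> float:
    if pd.isna(value) or (isinstance(value, str) and value.strip() in {"", "NA", "NaN"}):
        return float("nan")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"{source}: unparsable numeric value {value!r} in column {column!r}, row {row!r}"
        ) from None


def _cohort_from_frame(df: pd.DataFrame, *, source: str) -> CohortTable:
    missing = [c for c in _REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{source}: missing required column(s) {missing}")
    param_cols = [c for c in df.columns if c not in _RESERVED_COHORT_COLUMNS]
    samples = []
    for _, rec in df.iterrows():
        sid = str(rec["sample_id"])
        height = _parse_numeric(rec["height"], row=sid, column="height", source=source)
        weight = _parse_numeric(rec["weight"], row=sid, column="weight", source=source)
        age = _parse_numeric(rec["age"], row=sid, column="age", source=source)
        if not (height > 0) or not (weight > 0):
            raise DomainError(
                f"{source}: sample {sid}: height/weight must be positive "
                f"(got {height}, {weight})"
            )
        if "bmi" in df.columns and not pd.isna(rec["bmi"]):
            bmi = _parse_numeric(rec["bmi"], row=sid, column="bmi", source=source)
        else:
            bmi = compute_bmi(weight, height)
        if "group" in df.columns and isinstance(rec.get("group"), str) and rec["group"]:
            group = rec["group"]
        else:
            group = assign_group(bmi)
        clinical = {
            c: _parse_numeric(rec[c], row=sid, column=c, source=source) for c in param_cols
        }
        samples.append(
            Sample(
                sample_id=sid,
                group=group,
                sex=str(rec["sex"]),
                age=age,
                height=height,
                weight=weight,
                bmi=bmi,
                clinical=clinical,
            )
        )
    return CohortTable(samples, param_cols)


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read cohort metadata from TSV.

    Required columns: sample_id, sex, age, height, weight. Optional: group
    (assigned from BMI when absent), bmi (computed when absent); all other
    columns become clinical parameters. Raises :class:`ParseError` /
    :class:`DomainError` naming the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    return _cohort_from_frame(df, source=str(path))


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.write_tsv(path)


def read_identifications(path: str | Path) -> dict[str, set[str]]:
    """Read per-sample protein identification lists from long-format TSV.

    Two columns ``sample_id`` and ``accession``; duplicate rows within a
    sample collapse to one. An empty file yields an empty mapping with a
    warning. Accessions that do not look like UniProt ids are kept verbatim
    with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty identification file", stacklevel=2)
        return {}
    for col in ("sample_id", "accession"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df.empty:
        warnings.warn(f"{path}: identification file has no rows", stacklevel=2)
        return {}
    bad = sorted({a for a in df["accession"] if not UNIPROT_RE.match(str(a))})
    if bad:
        warnings.warn(
            f"{path}: {len(bad)} accession(s) do not match the UniProt pattern "
            f"(e.g. {bad[:3]}); retained verbatim",
            stacklevel=2,
        )
    idmap: dict[str, set[str]] = {}
    for sid, acc in zip(df["sample_id"], df["accession"]):
        idmap.setdefault(str(sid), set()).add(str(acc))
    return idmap


def read_identifications_dir(path: str | Path, pattern: str = "*.txt") -> dict[str, set[str]]:
    """Directory-of-files convenience reader: one file per sample (named by
    the file stem), one accession per line."""
    path = Path(path)
    idmap: dict[str, set[str]] = {}
    for f in sorted(path.glob(pattern)):
        accs = {line.strip() for line in f.read_text().splitlines() if line.strip()}
        idmap[f.stem] = accs
    return idmap


class PresenceMatrix:
    """Binary sample x protein occurrence matrix.

    ``values`` is an int8 array of 0/1 with rows aligned to ``sample_ids``
    and columns to ``protein_ids`` (UniProt accessions).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        protein_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.protein_ids = list(protein_ids)
        values = np.asarray(values)
        if values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise DataError(
                f"matrix shape {values.shape} does not match id lists "
                f"({len(self.sample_ids)} x {len(self.protein_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in presence matrix")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise DataError("duplicate protein ids in presence matrix")
        if values.size and not np.isin(values, (0, 1)).all():
            raise DataError("presence matrix entries must be 0 or 1")
        self.values = values.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_counts(self) -> np.ndarray:
        """Per-protein occurrence counts (column sums)."""
        return self.values.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "PresenceMatrix":
        idx = [self.sample_ids.index(i) for i in sample_ids]
        return PresenceMatrix(list(sample_ids), self.protein_ids, self.values[idx])

    def select_proteins(self, protein_ids: Sequence[str]) -> "PresenceMatrix":
        idx = [self.protein_ids.index(i) for i in protein_ids]
        return PresenceMatrix(self.sample_ids, list(protein_ids), self.values[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.protein_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.values, other.values)
        )


def build_presence_matrix(
    idmap: Mapping[str, Iterable[str]], sample_order: Sequence[str]
) -> PresenceMatrix:
    """Binary matrix from per-sample identification sets.

    Columns are the lexicographically sorted union of all accessions. A
    sample listed in ``sample_order`` but absent from ``idmap`` is an error:
    "no proteins identified" (empty set) is distinct from "no data".
    """
    missing = [s for s in sample_order if s not in idmap]
    if missing:
        raise DataError(f"sample(s) in order but absent from identification map: {missing}")
    proteins = sorted({a for s in sample_order for a in idmap[s]})
    col = {p: j for j, p in enumerate(proteins)}
    values = np.zeros((len(sample_order), len(proteins)), dtype=np.int8)
    for i, s in enumerate(sample_order):
        for a in idmap[s]:
            values[i, col[a]] = 1
    return PresenceMatrix(list(sample_order), proteins, values)
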