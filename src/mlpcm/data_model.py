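"""Dataset schema for continuum-solvation records and feature-matrix assembly.

A record describes one solute/solvent pair: the 15 per-run energy and
geometry components produced by a self-consistent reaction-field (SCRF)
calculation, the solvent dielectric constant, an optional auxiliary
COSMO-RS solvation free energy, and the experimental solvation free
energy in kcal/mol.  Records are exchanged as plain CSV; all energies are
stored in kcal/mol (``HARTREE_TO_KCAL`` is provided for data producers
whose QM program emits Hartree).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "COMPONENT_FIELDS",
    "FEATURE_COLUMNS",
    "CSV_COLUMNS",
    "SCRF_MODELS",
    "ScrfComponents",
    "SolvationRecord",
    "Dataset",
    "FeatureMatrix",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "load_dataset",
    "save_dataset",
    "build_feature_matrix",
]

#: kcal/mol per Hartree, CODATA-derived conversion for data producers.
HARTREE_TO_KCAL = 627.5094740631

#: The 15 SCRF components, in canonical column order.
COMPONENT_FIELDS = (
    "dg_model",                # solvation free energy of the continuum model
    "e_gas",                   # <Psi(0)|H|Psi(0)>
    "e_gas_halfV0",            # <Psi(0)|H+V(0)/2|Psi(0)>
    "e_gas_halfV1",            # <Psi(0)|H+V(1)/2|Psi(0)>
    "e_sol",                   # <Psi(1)|H|Psi(1)>
    "e_sol_halfV1",            # <Psi(1)|H+V(1)/2|Psi(1)>
    "e_int_unpol",             # interaction, unpolarized solute / polarized solvent
    "e_int_pol",               # interaction, polarized solute / polarized solvent
    "e_solute_polarization",   # solute polarization energy
    "e_electrostatic_total",   # total electrostatic interaction energy
    "cavity_area",             # cavity surface area, A^2
    "cavity_volume",           # cavity volume, A^3
    "e_kinetic",               # total kinetic energy
    "e_potential",             # total potential energy
    "e_kin_plus_pot",          # kinetic + potential
)

#: Candidate model inputs in canonical order: 15 components + dielectric
#: constant; ``dg_cosmors`` is appended when requested.
FEATURE_COLUMNS = COMPONENT_FIELDS + ("solvent_dielectric",)

CSV_COLUMNS = (
    "solute_id",
    "solvent_id",
    "solvent_dielectric",
    "level_of_theory",
    "scrf_model",
    *COMPONENT_FIELDS,
    "dg_cosmors",
    "dg_exp",
    "solute_elements",
)

SCRF_MODELS = ("PCM", "CPCM", "CPCM_x05")

# IUPAC element symbols (periods 1-7, no superheavy placeholders).
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr".split()
)

_SUM_TOL = 1e-6  # kcal/mol; e_kin_plus_pot consistency check


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class ParseError(ValueError):
    """A cell could not be parsed as its documented type."""


class ValidationError(ValueError):
    """One or more records violate a type invariant."""


@dataclass(frozen=True)
class ScrfComponents:
    """The 15 SCRF energy/geometry components of one record (kcal/mol, A^2, A^3)."""

    dg_model: float
    e_gas: float
    e_gas_halfV0: float
    e_gas_halfV1: float
    e_sol: float
    e_sol_halfV1: float
    e_int_unpol: float
    e_int_pol: float
    e_solute_polarization: float
    e_electrostatic_total: float
    cavity_area: float
    cavity_volume: float
    e_kinetic: float
    e_potential: float
    e_kin_plus_pot: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in COMPONENT_FIELDS], dtype=float)

    def problems(self) -> list[str]:
        """Invariant violations, empty when the components are valid."""
        out = []
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            bad = [f for f, v in zip(COMPONENT_FIELDS, vals) if not np.isfinite(v)]
            out.append(f"non-finite components: {', '.join(bad)}")
        if not self.cavity_area > 0:
            out.append(f"cavity_area must be > 0, got {self.cavity_area}")
        if not self.cavity_volume > 0:
            out.append(f"cavity_volume must be > 0, got {self.cavity_volume}")
        if abs(self.e_kin_plus_pot - (self.e_kinetic + self.e_potential)) > _SUM_TOL:
            out.append(
                "e_kin_plus_pot inconsistent with e_kinetic + e_potential "
                f"({self.e_kin_plus_pot} vs {self.e_kinetic + self.e_potential})"
            )
        return out


@dataclass(frozen=True)
class SolvationRecord:
    """One solute/solvent pair with its SCRF components and reference data."""

    solute_id: str
    solvent_id: str
    solvent_dielectric: float
    level_of_theory: str
    scrf_model: str
    components: ScrfComponents
    solute_elements: frozenset[str]
    dg_cosmors: float | None = None
    dg_exp: float | None = None

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.solute_id, self.solvent_id, self.scrf_model, self.level_of_theory)

    def problems(self) -> list[str]:
        out = self.components.problems()
        if not self.solvent_dielectric >= 1.0:
            out.append(f"solvent_dielectric must be >= 1, got {self.solvent_dielectric}")
        if not self.solute_elements:
            out.append("solute_elements is empty")
        unknown = sorted(set(self.solute_elements) - _ELEMENTS)
        if unknown:
            out.append(f"unknown element symbols: {', '.join(unknown)}")
        if self.scrf_model not in SCRF_MODELS:
            out.append(f"scrf_model must be one of {SCRF_MODELS}, got {self.scrf_model!r}")
        return out


@dataclass
class Dataset:
    """An ordered collection of records plus free-text provenance."""

    records: list[SolvationRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        msgs = []
        seen: dict[tuple, int] = {}
        for i, rec in enumerate(self.records):
            for p in rec.problems():
                msgs.append(f"row {i}: {p}")
            if rec.key in seen:
                msgs.append(
                    f"row {i}: duplicate (solute, solvent, model, level) key "
                    f"{rec.key} first seen at row {seen[rec.key]}"
                )
            else:
                seen[rec.key] = i
        if msgs:
            raise ValidationError("; ".join(msgs))

    def subset(self, indices) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        return Dataset([self.records[i] for i in idx], dict(self.provenance))

    def solvent_ids(self) -> np.ndarray:
        return np.array([r.solvent_id for r in self.records])

    def element_sets(self) -> list[frozenset[str]]:
        return [r.solute_elements for r in self.records]

    def dg_exp(self) -> np.ndarray:
        return np.array(
            [np.nan if r.dg_exp is None else r.dg_exp for r in self.records], dtype=float
        )

    def dg_model(self) -> np.ndarray:
        return np.array([r.components.dg_model for r in self.records], dtype=float)


@dataclass
class FeatureMatrix:
    """A numeric view of a dataset: candidate inputs plus the target vector."""

    column_names: tuple[str, ...]
    values: np.ndarray  # (n_records, n_features)
    target: np.ndarray  # (n_records,) experimental dG, kcal/mol

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def select(self, names) -> "FeatureMatrix":
        idx = [self.column_names.index(n) for n in names]
        return FeatureMatrix(tuple(names), self.values[:, idx], self.target)

    def rows(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(self.column_names, self.values[idx], self.target[idx])


def _serialize_elements(elements: frozenset[str]) -> str:
    return "-".join(sorted(elements))


def _parse_elements(text: str) -> frozenset[str]:
    parts = [p for p in re.split(r"-", text.strip()) if p]
    return frozenset(parts)


def _parse_float(cell: str, column: str, row: int) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {cell!r} as a number"
        ) from None


def load_dataset(path, strict: bool = False) -> Dataset:
    """Read a dataset CSV.

    Parameters
    ----------
    path
        CSV file with the documented 23-column header.
    strict
        When true, every type invariant is verified and violations raise
        :class:`ValidationError` listing the offending rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        comp = ScrfComponents(
            **{f: _parse_float(row[f], f, i) for f in COMPONENT_FIELDS}
        )
        dg_cosmors = row["dg_cosmors"].strip()
        dg_exp = row["dg_exp"].strip()
        records.append(
            SolvationRecord(
                solute_id=row["solute_id"],
                solvent_id=row["solvent_id"],
                solvent_dielectric=_parse_float(
                    row["solvent_dielectric"], "solvent_dielectric", i
                ),
                level_of_theory=row["level_of_theory"],
                scrf_model=row["scrf_model"],
                components=comp,
                solute_elements=_parse_elements(row["solute_elements"]),
                dg_cosmors=_parse_float(dg_cosmors, "dg_cosmors", i) if dg_cosmors else None,
                dg_exp=_parse_float(dg_exp, "dg_exp", i) if dg_exp else None,
            )
        )
    ds = Dataset(records, provenance={"source": str(path)})
    if strict:
        ds.validate()
    return ds


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def save_dataset(dataset: Dataset, path) -> None:
    """Write the canonical CSV; ``load_dataset(save_dataset(d))`` round-trips."""
    rows = []
    for rec in dataset.records:
        row = {
            "solute_id": rec.solute_id,
            "solvent_id": rec.solvent_id,
            "solvent_dielectric": _fmt(rec.solvent_dielectric),
            "level_of_theory": rec.level_of_theory,
            "scrf_model": rec.scrf_model,
            "dg_cosmors": _fmt(rec.dg_cosmors),
            "dg_exp": _fmt(rec.dg_exp),
            "solute_elements": _serialize_elements(rec.solute_elements),
        }
        for f in COMPONENT_FIELDS:
            row[f] = _fmt(getattr(rec.components, f))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False)


def build_feature_matrix(dataset: Dataset, include_cosmors: bool = False) -> FeatureMatrix:
    """Assemble the candidate-input matrix and target vector.

    Columns are the 15 SCRF components followed by the solvent dielectric
    constant and, when ``include_cosmors`` is set, the auxiliary COSMO-RS
    solvation free energy; rows follow record order.
    """
    missing_exp = [i for i, r in enumerate(dataset.records) if r.dg_exp is None]
    if missing_exp:
        raise ValidationError(f"records without dg_exp: rows {missing_exp}")
    if include_cosmors:
        missing_cos = [i for i, r in enumerate(dataset.records) if r.dg_cosmors is None]
        if missing_cos:
            raise ValidationError(f"records without dg_cosmors: rows {missing_cos}")
    names = FEATURE_COLUMNS + (("dg_cosmors",) if include_cosmors else ())
    n = len(dataset.records)
    values = np.empty((n, len(names)), dtype=float)
    for i, rec in enumerate(dataset.records):
        values[i, :15] = rec.components.as_array()
        values[i, 15] = rec.solvent_dielectric
        if include_cosmors:
            values[i, 16] = rec.dg_cosmors
    return FeatureMatrix(names, values, dataset.dg_exp())
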