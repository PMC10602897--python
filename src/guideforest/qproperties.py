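"""Quantum-chemical property tables for duplex k-mers.

Downstream feature encoding consumes per-k-mer quantum descriptors (total
electronic energy, frontier-orbital energies and their gap, hydrogen-bonding
and stacking interaction energies, electron count) from a delimited table
keyed by (k-mer strand-1 sequence, duplex class, method tag).  This module
defines that schema, reads/writes/validates it, derives supermolecular
interaction energies, and synthesizes a complete, deterministic stand-in
table for testing pipelines without running any quantum-chemistry engine.

Units are whatever the table header declares (orbital energies are typically
hartree, interaction energies kcal/mol); no implicit conversion is performed,
and the HOMO/LUMO/gap consistency check assumes the three share one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .duplex import parse_kmer_id

GAP_TOL = 1e-8

KEY_COLUMNS = ["kmer_id", "duplex_class", "method_tag"]
VALUE_COLUMNS = [
    "total_energy",
    "homo",
    "lumo",
    "hl_gap",
    "hbond_energy",
    "stacking_energy",
    "electron_count",
]
COLUMNS = KEY_COLUMNS + VALUE_COLUMNS

DEFAULT_UNITS = {
    "total_energy": "hartree",
    "homo": "hartree",
    "lumo": "hartree",
    "hl_gap": "hartree",
    "hbond_energy": "kcal/mol",
    "stacking_energy": "kcal/mol",
    "electron_count": "count",
}


class TableIntegrityError(ValueError):
    """Duplicate keys or malformed table structure."""


class TableValidationError(ValueError):
    """One or more records violate the property-record invariants.

    Carries *all* offending records in ``messages``, not just the first.
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__(
            f"{len(self.messages)} invalid property record(s):\n  "
            + "\n  ".join(self.messages)
        )


class TableCompletenessError(KeyError):
    """A declared enumeration has k-mers absent from the table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__(
            f"{len(self.missing)} enumerated k-mer(s) missing from table: "
            + ", ".join(self.missing[:10])
            + ("..." if len(self.missing) > 10 else "")
        )


@dataclass(frozen=True)
class PropertyRecord:
    """Quantum descriptors for one duplex k-mer under one method."""

    kmer_id: str
    duplex_class: str
    method_tag: str
    total_energy: float
    homo: float
    lumo: float
    hl_gap: float
    hbond_energy: float
    stacking_energy: float
    electron_count: int

    def violations(self) -> list[str]:
        """Human-readable list of invariant violations (empty when valid)."""
        key = f"({self.kmer_id}, {self.duplex_class}, {self.method_tag})"
        out = []
        vals = (self.homo, self.lumo, self.hl_gap)
        if all(np.isfinite(v) for v in vals):
            if abs(self.hl_gap - (self.lumo - self.homo)) > GAP_TOL:
                out.append(f"{key}: hl_gap != lumo - homo")
        if np.isfinite(self.hl_gap) and self.hl_gap < 0:
            out.append(f"{key}: hl_gap < 0")
        ec = self.electron_count
        if not (float(ec).is_integer() and ec > 0):
            out.append(f"{key}: electron_count must be a positive integer")
        return out


@dataclass
class PropertyTable:
    """Property records indexed by (kmer_id, duplex_class, method_tag)."""

    df: pd.DataFrame
    units: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise TableIntegrityError(f"table missing required columns: {missing}")
        dup = self.df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = self.df.loc[dup, KEY_COLUMNS].apply(tuple, axis=1).tolist()
            raise TableIntegrityError(f"duplicate property keys: {keys}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PropertyTable):
            return NotImplemented
        a = self.df[COLUMNS].sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.df[COLUMNS].sort_values(KEY_COLUMNS).reset_index(drop=True)
        return self.units == other.units and a.equals(b)

    def records(self) -> Iterable[PropertyRecord]:
        for row in self.df.itertuples(index=False):
            yield PropertyRecord(**{c: getattr(row, c) for c in COLUMNS})

    def validate(self) -> "PropertyTable":
        """Check every record; raise :class:`TableValidationError` listing all
        violations."""
        messages: list[str] = []
        for rec in self.records():
            messages.extend(rec.violations())
        if messages:
            raise TableValidationError(messages)
        return self

    def check_complete(self, enumeration: Iterable[str]) -> "PropertyTable":
        """Require a record for every enumerated ``"<class>|<seq>"`` k-mer."""
        have = set(zip(self.df["kmer_id"], self.df["duplex_class"]))
        missing = []
        for ident in enumeration:
            cls, seq = parse_kmer_id(ident)
            if (seq, cls) not in have:
                missing.append(ident)
        if missing:
            raise TableCompletenessError(missing)
        return self

    def lookup(self, kmer_seq: str, duplex_class: str, method_tag: str | None = None):
        """Values row for one k-mer; ``method_tag=None`` takes the sole method."""
        sel = (self.df["kmer_id"] == kmer_seq) & (self.df["duplex_class"] == duplex_class)
        if method_tag is not None:
            sel &= self.df["method_tag"] == method_tag
        rows = self.df.loc[sel]
        if len(rows) == 0:
            raise KeyError(f"no property record for ({kmer_seq}, {duplex_class})")
        if len(rows) > 1:
            raise KeyError(
                f"ambiguous record for ({kmer_seq}, {duplex_class}): "
                f"methods {sorted(rows['method_tag'])}; pass method_tag"
            )
        return rows.iloc[0]

    def property_lookup(
        self, prop: str, duplex_class: str, method_tag: str | None = None
    ) -> dict[str, float]:
        """Fast ``{kmer_seq: value}`` map for one property and duplex class."""
        sel = self.df["duplex_class"] == duplex_class
        if method_tag is not None:
            sel &= self.df["method_tag"] == method_tag
        sub = self.df.loc[sel]
        return dict(zip(sub["kmer_id"], sub[prop].astype(float)))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for col, unit in self.units.items():
                fh.write(f"# unit {col}={unit}\n")
            self.df[COLUMNS].to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str | None = None) -> PropertyTable:
    """Read and validate a TSV/CSV property table.

    ``# unit <column>=<unit>`` comment lines ahead of the header are retained
    as unit metadata.  Raises on duplicate keys or invariant violations; an
    empty body under a valid header yields an empty table.
    """
    path = Path(path)
    units = dict(DEFAULT_UNITS)
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("unit "):
                col, _, unit = body[5:].partition("=")
                units[col.strip()] = unit.strip()
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, skiprows=header_lines)
    if len(df) > 0:
        df["electron_count"] = df["electron_count"].astype(int)
    table = PropertyTable(df=df, units=units)
    table.validate()
    return table


def derive_interaction_energy(parts: Sequence[float], whole: float) -> float:
    """Supermolecular interaction energy: ``whole - sum(parts)``.

    Fixed-geometry difference of total energies; used to populate
    ``hbond_energy`` (pair vs its two isolated bases) and ``stacking_energy``
    (k-mer vs its isolated stacked sub-pairs).
    """
    parts = list(parts)
    if len(parts) < 2:
        raise ValueError("interaction energy needs at least two parts")
    return float(whole) - float(sum(parts))


def synth_table(
    enumeration: Iterable[str], seed: int, method_tag: str = "synthetic"
) -> PropertyTable:
    """Deterministic synthetic property table, complete over ``enumeration``.

    Values are drawn from plausible ranges (positive H-L gaps; negative-
    leaning hydrogen-bond and stacking energies; electron counts growing with
    k) and satisfy every record invariant.  This is a labelled synthetic
    stand-in for a quantum-chemistry-derived resource, intended for pipeline
    testing and benchmarking.
    """
    ids = sorted(set(enumeration))
    rng = np.random.default_rng(seed)
    rows = []
    for ident in ids:
        cls, seq = parse_kmer_id(ident)
        k = len(seq)
        gc = sum(b in "GC" for b in seq)
        homo = rng.uniform(-0.35, -0.20)
        gap = rng.uniform(0.05, 0.25)
        total = -60.0 * 2 * k + rng.normal(0.0, 1.0)
        rows.append(
            {
                "kmer_id": seq,
                "duplex_class": cls,
                "method_tag": method_tag,
                "total_energy": total,
                "homo": homo,
                "lumo": homo + gap,
                "hl_gap": gap,
                # GC pairs bond more strongly; stacking scales with steps
                "hbond_energy": -(8.0 + 6.0 * gc / k) + rng.normal(0.0, 1.0),
                "stacking_energy": (
                    0.0 if k == 1 else -(4.0 * (k - 1)) + rng.normal(0.0, 0.5)
                ),
                "electron_count": int(70 * k + 2 * gc + rng.integers(0, 3)),
            }
        )
    df = pd.DataFrame(rows, columns=COLUMNS)
    # rounding keeps write/read round-trips exact in decimal text
    for col in VALUE_COLUMNS[:-1]:
        df[col] = df[col].round(10)
    df["hl_gap"] = (df["lumo"] - df["homo"]).round(12)
    return PropertyTable(df=df).validate()
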