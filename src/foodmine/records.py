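"""Curated measurement records: unit standardization, compound
disambiguation, and per-compound aggregation.

Every quantified measurement is expressed in mg per 100 g of food. Compound
names from different papers are reconciled to PubChem CID keys through a
resolver (a packaged synonym-table fixture by default, a cached live PubChem
client optionally), and all records for one compound in one food merge into
a single :class:`CompoundEntry` carrying the mean, extrema, sample variance
and paper/record counts.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "UNIT_FACTORS",
    "UnitError",
    "standardize_unit",
    "from_mg_per_100g",
    "CompoundKey",
    "SynonymTable",
    "PubChemResolver",
    "disambiguate",
    "MeasurementRecord",
    "CompoundEntry",
    "attach_keys",
    "aggregate",
    "read_records_csv",
    "write_entries_csv",
]

# Exact rational factors: value_in_unit * factor == value in mg/100 g.
UNIT_FACTORS: dict[str, Fraction] = {
    "mg/100 g": Fraction(1),
    "g/100 g": Fraction(1000),
    "ug/g": Fraction(1, 10),
    "mg/g": Fraction(100),
    "mg/kg": Fraction(1, 10),
    "ppm": Fraction(1, 10),  # w/w, identical to mg/kg
    "%": Fraction(1000),
    "ug/100 g": Fraction(1, 1000),
    "g/kg": Fraction(100),
}

_UNIT_ALIASES = {
    "µg/g": "ug/g",
    "μg/g": "ug/g",
    "µg/100 g": "ug/100 g",
    "μg/100 g": "ug/100 g",
    "mg/100g": "mg/100 g",
    "g/100g": "g/100 g",
    "ug/100g": "ug/100 g",
    "percent": "%",
}


class UnitError(ValueError):
    pass


def _canonical_unit(unit_raw: str) -> str:
    unit = unit_raw.strip().lower()
    unit = _UNIT_ALIASES.get(unit, unit)
    if unit not in UNIT_FACTORS:
        supported = ", ".join(sorted(UNIT_FACTORS))
        raise UnitError(f"unsupported unit {unit_raw!r}; supported: {supported}")
    return unit


def standardize_unit(value, unit_raw: str, basis: str = "fresh"):
    """Convert ``value`` in ``unit_raw`` to mg/100 g.

    Arithmetic is rational (``Fraction``). A ``Fraction`` input returns an
    exact ``Fraction``, so every supported unit round-trips bit-for-bit
    through :func:`from_mg_per_100g`; int/float inputs return a float (the
    only rounding is the final binary representation). ``basis`` (fresh/dry
    sample basis) is recorded by callers but never converted: moisture
    corrections are out of scope and preparation effects (e.g. roasting)
    are handled by descriptor filters downstream.
    """
    if value < 0:
        raise ValueError(f"measurement value must be nonnegative, got {value}")
    unit = _canonical_unit(unit_raw)
    result = Fraction(value) * UNIT_FACTORS[unit]
    return result if isinstance(value, Fraction) else float(result)


def from_mg_per_100g(value_mg, unit_raw: str):
    """Inverse of :func:`standardize_unit` (exact rational division)."""
    unit = _canonical_unit(unit_raw)
    result = Fraction(value_mg) / UNIT_FACTORS[unit]
    return result if isinstance(value_mg, Fraction) else float(result)


_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Conservative normalization: lowercase, trim, collapse whitespace.

    Salt/hydrate suffixes and stereo descriptors are deliberately preserved
    to avoid false merges; the CID is the authoritative merge key.
    """
    return _WS.sub(" ", name.strip().lower())


@dataclass
class CompoundKey:
    """Disambiguated compound identity: PubChem CID first, name fallback.

    Equality follows the CID-first rule (equal CIDs when both present,
    otherwise equal normalized names). That relation is not transitive
    across keys with and without CIDs, so the class is deliberately
    unhashable; grouping uses :meth:`identity`.
    """

    cid: int | None = None
    canonical_name: str = ""
    smiles: str | None = None
    resolved: bool = True

    __hash__ = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.canonical_name = normalize_name(self.canonical_name)
        if self.cid is None:
            self.resolved = False

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompoundKey):
            return NotImplemented
        if self.cid is not None and other.cid is not None:
            return self.cid == other.cid
        return self.canonical_name == other.canonical_name

    def identity(self) -> tuple:
        """Hashable grouping identity: the CID when present, else the name."""
        if self.cid is not None:
            return ("cid", self.cid)
        return ("name", self.canonical_name)


class SynonymTable:
    """Fixture resolver: a name -> (CID, SMILES) lookup loaded from CSV."""

    def __init__(self, mapping: dict[str, tuple[int, str | None]]):
        self._map = {normalize_name(k): v for k, v in mapping.items()}

    @classmethod
    def from_csv(cls, path: str | Path | None = None) -> "SynonymTable":
        """Load from a (name, cid, smiles) CSV; defaults to the packaged table."""
        if path is None:
            text = (resources.files("foodmine.data") / "synonyms.csv").read_text("utf-8")
            rows = list(csv.DictReader(text.splitlines()))
        else:
            with open(path, encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
        mapping = {
            row["name"]: (int(row["cid"]), row.get("smiles") or None)
            for row in rows
            if row.get("cid")
        }
        return cls(mapping)

    def resolve(self, name: str) -> tuple[int, str | None] | None:
        return self._map.get(normalize_name(name))

    def names(self) -> list[str]:
        return sorted(self._map)


class PubChemResolver:  # pragma: no cover - network-only path
    """Live PubChem PUG-REST name resolver with an on-disk JSON cache.

    Never used by the default build or tests; the packaged
    :class:`SynonymTable` is the default resolver.
    """

    BASE = "https://pubchem.ncbi.nlm.nih.gov/rest/pug"

    def __init__(self, cache_path: str | Path = ".pubchem_cache.json"):
        self.cache_path = Path(cache_path)
        self._cache: dict[str, tuple[int, str | None] | None] = {}
        if self.cache_path.exists():
            self._cache = {
                k: tuple(v) if v else None
                for k, v in json.loads(self.cache_path.read_text()).items()
            }

    def resolve(self, name: str) -> tuple[int, str | None] | None:
        import urllib.parse
        import urllib.request

        key = normalize_name(name)
        if key in self._cache:
            return self._cache[key]
        url = (f"{self.BASE}/compound/name/{urllib.parse.quote(key)}"
               f"/property/CanonicalSMILES/JSON")
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:
                props = json.load(resp)["PropertyTable"]["Properties"][0]
            result = (int(props["CID"]), props.get("CanonicalSMILES"))
        except Exception:
            result = None
        self._cache[key] = result
        self.cache_path.write_text(json.dumps(
            {k: list(v) if v else None for k, v in self._cache.items()}
        ))
        return result


def disambiguate(name_raw: str, resolver=None) -> CompoundKey:
    """Resolve a raw compound name to a :class:`CompoundKey`.

    Unresolvable names keep a name-only key with ``resolved=False`` — they
    still aggregate (by name) but are flagged for manual review.
    """
    if resolver is None:
        resolver = SynonymTable.from_csv()
    name = normalize_name(name_raw)
    hit = resolver.resolve(name)
    if hit is None:
        return CompoundKey(cid=None, canonical_name=name, resolved=False)
    cid, smiles = hit
    return CompoundKey(cid=cid, canonical_name=name, smiles=smiles, resolved=True)


@dataclass
class MeasurementRecord:
    """One chemical measurement extracted from one paper.

    ``quantified`` is true exactly when a value is present and its unit
    converts to mg/100 g; relative-only reports (e.g. peak-area percentages
    of a chromatogram) are unquantified and carry no value.
    """

    record_id: str
    entry_id: str
    food: str
    compound_name_raw: str
    value: float | None = None
    unit_raw: str = ""
    sample_descriptor: str = ""
    quantified: bool = False
    basis: str = "fresh"
    key: CompoundKey | None = None
    value_mg_per_100g: float | None = None

    def standardized(self) -> "MeasurementRecord":
        if not self.quantified or self.value is None:
            return self
        return replace(
            self,
            value_mg_per_100g=standardize_unit(self.value, self.unit_raw, self.basis),
        )


@dataclass
class CompoundEntry:
    """Aggregated statistics for one compound in one food (mg/100 g)."""

    key: CompoundKey
    food: str
    mean_mg_per_100g: float | None
    min_mg_per_100g: float | None
    max_mg_per_100g: float | None
    variance: float | None
    n_records: int
    n_papers: int
    compound_class: str | None = None
    descriptors: tuple[str, ...] = ()
    bases: tuple[str, ...] = ("fresh",)

    @property
    def quantified(self) -> bool:
        return self.mean_mg_per_100g is not None

    @property
    def mixed_basis(self) -> bool:
        # dry vs fresh reports are never auto-converted; flag the mixture
        return len(set(self.bases)) > 1


def attach_keys(records: Iterable[MeasurementRecord],
                resolver=None) -> list[MeasurementRecord]:
    """Disambiguate every record's raw compound name (idempotent)."""
    if resolver is None:
        resolver = SynonymTable.from_csv()
    return [
        replace(r, key=disambiguate(r.compound_name_raw, resolver))
        for r in records
    ]


def aggregate(records: Sequence[MeasurementRecord]) -> list[CompoundEntry]:
    """Merge records into one entry per compound key per food.

    Statistics (mean, min, max, sample variance with n-1 denominator, zero
    when a single record) are computed over the quantified records'
    standardized values. Compounds reported only unquantified yield entries
    with absent statistics but a present key — they count as unquantified
    coverage downstream. Output order is deterministic (food, then name).
    """
    groups: dict[tuple, list[MeasurementRecord]] = {}
    for rec in records:
        if rec.key is None:
            raise ValueError(
                f"record {rec.record_id} has no compound key; run attach_keys first"
            )
        groups.setdefault((rec.food, rec.key.identity()), []).append(rec)
    entries: list[CompoundEntry] = []
    for (food, _ident), grp in groups.items():
        grp = [r.standardized() if (r.quantified and r.value_mg_per_100g is None) else r
               for r in grp]
        values = [r.value_mg_per_100g for r in grp if r.quantified]
        papers = {r.entry_id for r in grp}
        descriptors = tuple(sorted({r.sample_descriptor for r in grp
                                    if r.sample_descriptor}))
        bases = tuple(sorted({r.basis for r in grp})) or ("fresh",)
        if values:
            n = len(values)
            mean = sum(values) / n
            var = sum((v - mean) ** 2 for v in values) / (n - 1) if n > 1 else 0.0
            entry = CompoundEntry(
                key=grp[0].key, food=food,
                mean_mg_per_100g=mean,
                min_mg_per_100g=min(values),
                max_mg_per_100g=max(values),
                variance=var,
                n_records=len(grp), n_papers=len(papers),
                descriptors=descriptors, bases=bases,
            )
        else:
            entry = CompoundEntry(
                key=grp[0].key, food=food,
                mean_mg_per_100g=None, min_mg_per_100g=None,
                max_mg_per_100g=None, variance=None,
                n_records=len(grp), n_papers=len(papers),
                descriptors=descriptors, bases=bases,
            )
        entries.append(entry)
    entries.sort(key=lambda e: (e.food, e.key.canonical_name, e.key.cid or -1))
    return entries


_RECORD_COLUMNS = ["record_id", "entry_id", "food", "compound_name_raw",
                   "value", "unit_raw", "sample_descriptor", "quantified"]


def read_records_csv(path: str | Path) -> list[MeasurementRecord]:
    df = pd.read_csv(path, dtype={"record_id": str, "entry_id": str},
                     float_precision="round_trip")
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        value = None if pd.isna(row.value) else float(row.value)
        records.append(MeasurementRecord(
            record_id=str(row.record_id),
            entry_id=str(row.entry_id),
            food=str(row.food),
            compound_name_raw=str(row.compound_name_raw),
            value=value,
            unit_raw="" if pd.isna(row.unit_raw) else str(row.unit_raw),
            sample_descriptor="" if pd.isna(row.sample_descriptor) else str(row.sample_descriptor),
            quantified=bool(row.quantified),
            basis=str(getattr(row, "basis", "fresh")),
        ))
    return records


def write_records_csv(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    rows = [{
        "record_id": r.record_id, "entry_id": r.entry_id, "food": r.food,
        "compound_name_raw": r.compound_name_raw, "value": r.value,
        "unit_raw": r.unit_raw, "sample_descriptor": r.sample_descriptor,
        "quantified": r.quantified, "basis": r.basis,
    } for r in records]
    # %.17g guarantees float values survive the CSV round trip bit-for-bit
    pd.DataFrame(rows, columns=_RECORD_COLUMNS + ["basis"]).to_csv(
        path, index=False, float_format="%.17g")


def write_entries_csv(entries: Sequence[CompoundEntry], path: str | Path) -> None:
    rows = [{
        "cid": e.key.cid, "canonical_name": e.key.canonical_name,
        "smiles": e.key.smiles, "food": e.food,
        "mean_mg_per_100g": e.mean_mg_per_100g,
        "min_mg_per_100g": e.min_mg_per_100g,
        "max_mg_per_100g": e.max_mg_per_100g,
        "variance": e.variance, "n_records": e.n_records, "n_papers": e.n_papers,
        "compound_class": e.compound_class,
        "descriptors": ";".join(e.descriptors),
        "bases": ";".join(e.bases),
    } for e in entries]
    pd.DataFrame(rows).to_csv(path, index=False)
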