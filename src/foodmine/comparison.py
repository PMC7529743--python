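"""Comparison of literature-mined compound entries against reference
food-composition database snapshots.

Three analyses: quantified/unquantified/novel accounting against each
reference source and their union; a papers-per-compound frequency ranking;
and log-scale agreement of mined mean contents with a gold-standard
database, with zero-value and sample-descriptor exclusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import CompoundEntry, CompoundKey, MeasurementRecord

__all__ = [
    "SnapshotRow",
    "DatabaseSnapshot",
    "CoverageReport",
    "AgreementResult",
    "merge_variants",
    "coverage",
    "paper_frequency",
    "agreement",
    "read_snapshots_csv",
]


@dataclass
class SnapshotRow:
    food_variant: str
    key: CompoundKey
    quantity_mg_per_100g: float | None = None


@dataclass
class DatabaseSnapshot:
    """One reference database's compound list for a food and its variants.

    After variant merging a compound is quantified iff at least one row
    reports an absolute quantity.
    """

    source: str
    food_variants: list[str] = field(default_factory=list)
    rows: list[SnapshotRow] = field(default_factory=list)
    merged: bool = False


def merge_variants(snapshot: DatabaseSnapshot) -> DatabaseSnapshot:
    """Collapse food variants (e.g. "Garlic" + "Soft-necked Garlic") into one
    row set: quantified if quantified in any variant, quantities averaged."""
    groups: dict[tuple, list[SnapshotRow]] = {}
    for row in snapshot.rows:
        groups.setdefault(row.key.identity(), []).append(row)
    merged_rows = []
    for _ident, grp in sorted(groups.items(), key=lambda kv: repr(kv[0])):
        quantities = [r.quantity_mg_per_100g for r in grp
                      if r.quantity_mg_per_100g is not None]
        merged_rows.append(SnapshotRow(
            food_variant="|".join(sorted({r.food_variant for r in grp})),
            key=grp[0].key,
            quantity_mg_per_100g=(sum(quantities) / len(quantities)
                                  if quantities else None),
        ))
    return DatabaseSnapshot(
        source=snapshot.source,
        food_variants=sorted({r.food_variant for r in snapshot.rows}),
        rows=merged_rows,
        merged=True,
    )


@dataclass
class CoverageReport:
    """Set accounting of quantified/unquantified compounds per source.

    ``novel_quantified`` counts mined quantified compounds absent from every
    reference source, quantified or not.
    """

    per_source: dict[str, dict[str, int]]
    foodmine_quantified: int
    foodmine_unquantified: int
    shared_quantified: int
    shared_unquantified: int
    novel_quantified: int
    novel_list: list[CompoundKey]

    def to_dict(self) -> dict:
        return {
            "per_source": self.per_source,
            "foodmine": {"quantified": self.foodmine_quantified,
                         "unquantified": self.foodmine_unquantified},
            "shared_quantified": self.shared_quantified,
            "shared_unquantified": self.shared_unquantified,
            "novel_quantified": self.novel_quantified,
            "novel": sorted(k.canonical_name for k in self.novel_list),
        }


def _ensure_merged(snapshot: DatabaseSnapshot) -> DatabaseSnapshot:
    return snapshot if snapshot.merged else merge_variants(snapshot)


def coverage(entries: Sequence[CompoundEntry],
             refs: Sequence[DatabaseSnapshot]) -> CoverageReport:
    """Compare mined entries with reference snapshots by compound identity.

    Novelty is assessed against the union of all reference sources: a mined
    quantified compound is novel iff no reference lists it at all.
    """
    fm_quant = {e.key.identity(): e.key for e in entries if e.quantified}
    fm_unquant = {e.key.identity(): e.key for e in entries if not e.quantified}

    per_source: dict[str, dict[str, int]] = {}
    ref_all: set[tuple] = set()
    ref_quant: set[tuple] = set()
    for snap in refs:
        snap = _ensure_merged(snap)
        idents = [row.key.identity() for row in snap.rows]
        if len(idents) != len(set(idents)):
            raise ValueError(
                f"duplicate compound keys in source {snap.source!r} after merge"
            )
        quant = {i for i, row in zip(idents, snap.rows)
                 if row.quantity_mg_per_100g is not None}
        per_source[snap.source] = {
            "quantified": len(quant),
            "unquantified": len(idents) - len(quant),
        }
        ref_all.update(idents)
        ref_quant.update(quant)

    novel_idents = set(fm_quant) - ref_all
    shared_quant = set(fm_quant) & ref_quant
    shared_unquant = (set(fm_quant) & ref_all) - ref_quant
    return CoverageReport(
        per_source=per_source,
        foodmine_quantified=len(fm_quant),
        foodmine_unquantified=len(fm_unquant),
        shared_quantified=len(shared_quant),
        shared_unquantified=len(shared_unquant),
        novel_quantified=len(novel_idents),
        novel_list=sorted((fm_quant[i] for i in novel_idents),
                          key=lambda k: k.canonical_name),
    )


def paper_frequency(records: Sequence[MeasurementRecord],
                    top_k: int) -> list[tuple[CompoundKey, int]]:
    """Top-k compounds by the number of distinct papers reporting them.

    Descending paper count; ties broken by canonical name for stability.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    papers: dict[tuple, set[str]] = {}
    keys: dict[tuple, CompoundKey] = {}
    for rec in records:
        if rec.key is None:
            raise ValueError(f"record {rec.record_id} is not disambiguated")
        ident = rec.key.identity()
        papers.setdefault(ident, set()).add(rec.entry_id)
        keys.setdefault(ident, rec.key)
    ranked = sorted(
        ((keys[i], len(p)) for i, p in papers.items()),
        key=lambda kv: (-kv[1], kv[0].canonical_name),
    )
    return ranked[:top_k]


@dataclass
class AgreementResult:
    """Log-scale agreement between mined means and a gold-standard database.

    ``r2_log`` is the coefficient of determination of an ordinary
    least-squares fit of log10(mined) on log10(gold) — equivalently the
    squared Pearson correlation of the log10 values. Compounds whose gold
    value is zero cannot be log-transformed and are excluded; compounds
    whose contributing records all carry an excluded sample descriptor
    (e.g. "roasted") are dropped when that filter is active.
    """

    matched_pairs: list[tuple[CompoundKey, float, float]]
    excluded_zero: list[CompoundKey]
    excluded_descriptor: list[CompoundKey]
    r2_log: float
    slope: float
    intercept: float
    exclusion_tags: tuple[str, ...] = ()

    @property
    def n_pairs(self) -> int:
        return len(self.matched_pairs)


def agreement(entries: Sequence[CompoundEntry],
              gold: DatabaseSnapshot,
              exclude_descriptors: Sequence[str] = ()) -> AgreementResult:
    gold = _ensure_merged(gold)
    gold_by_ident = {row.key.identity(): row for row in gold.rows
                     if row.quantity_mg_per_100g is not None}
    exclude = {d.lower() for d in exclude_descriptors}

    pairs: list[tuple[CompoundKey, float, float]] = []
    excluded_zero: list[CompoundKey] = []
    excluded_descriptor: list[CompoundKey] = []
    for entry in entries:
        if not entry.quantified:
            continue
        row = gold_by_ident.get(entry.key.identity())
        if row is None:
            continue
        if exclude and entry.descriptors and all(
                d.lower() in exclude for d in entry.descriptors):
            excluded_descriptor.append(entry.key)
            continue
        if row.quantity_mg_per_100g == 0 or entry.mean_mg_per_100g == 0:
            excluded_zero.append(entry.key)
            continue
        pairs.append((entry.key, entry.mean_mg_per_100g, row.quantity_mg_per_100g))

    if len(pairs) < 3:
        raise ValueError(
            f"only {len(pairs)} matched pairs with positive values; "
            "at least 3 are needed for a meaningful R^2"
        )
    y = np.log10([p[1] for p in pairs])
    x = np.log10([p[2] for p in pairs])
    fit = stats.linregress(x, y)
    return AgreementResult(
        matched_pairs=pairs,
        excluded_zero=excluded_zero,
        excluded_descriptor=excluded_descriptor,
        r2_log=float(fit.rvalue ** 2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        exclusion_tags=tuple(sorted(exclude)),
    )


def read_snapshots_csv(path: str | Path) -> list[DatabaseSnapshot]:
    """Read reference snapshots from CSV
    (source, food_variant, compound_name, cid, quantity_mg_per_100g)."""
    df = pd.read_csv(path, float_precision="round_trip")
    snapshots = []
    for source, grp in df.groupby("source", sort=True):
        rows = []
        for r in grp.itertuples(index=False):
            cid = None if pd.isna(r.cid) else int(r.cid)
            qty = (None if pd.isna(r.quantity_mg_per_100g)
                   else float(r.quantity_mg_per_100g))
            rows.append(SnapshotRow(
                food_variant=str(r.food_variant),
                key=CompoundKey(cid=cid, canonical_name=str(r.compound_name)),
                quantity_mg_per_100g=qty,
            ))
        snapshots.append(DatabaseSnapshot(
            source=str(source),
            food_variants=sorted(grp["food_variant"].astype(str).unique()),
            rows=rows,
        ))
    return snapshots


def write_coverage_json(report: CoverageReport, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
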