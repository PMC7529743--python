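"""End-to-end pipeline: search -> filter -> label/classify -> aggregate ->
compare -> embed, with a stage funnel report.

Every stage reads only prior-stage artifacts from the output directory and
writes its own artifact plus a structured log line; the funnel report is
derived from the logs. Stages are resumable: an existing artifact is loaded
rather than recomputed, and rerunning with the same configuration
regenerates byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import comparison, corpus as corpus_mod, embedding as emb_mod
from . import records as records_mod, screening
from .fixtures import FixtureSpec, gen_records_and_snapshots

__all__ = ["FunnelReport", "PipelineConfig", "run", "load_config"]


@dataclass
class FunnelReport:
    """Stage-by-stage input/output counts, mirroring the collection funnel:
    papers searched, passing the vocabulary filter, retrievable via a
    full-text link, labelled useful, then measurement records and unique
    compounds."""

    searched: int
    filtered: int
    retrievable: int
    useful: int
    records: int
    unique_compounds: int

    def validate(self) -> None:
        seq = [self.searched, self.filtered, self.retrievable, self.useful]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {seq}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    """All tunables, explicit. Loadable from one YAML file."""

    out_dir: str
    seed: int = 0
    fixture_spec: FixtureSpec | None = None
    corpus_path: str | None = None
    labels_path: str | None = None
    records_path: str | None = None
    synonyms_path: str | None = None
    snapshots_path: str | None = None
    associations_path: str | None = None
    membership_path: str | None = None
    gold_source: str = "USDA"
    exclude_descriptors: tuple[str, ...] = ()
    classifier_split: float = 0.25
    embed_radius: int = 1
    embed_dim: int = 16
    embed_epochs: int = 10
    reduce_method: str = "pca"  # exactly deterministic; "tsne" available
    perplexity: float = 5.0


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if "fixture_spec" in raw and raw["fixture_spec"] is not None:
        fs = raw["fixture_spec"]
        for key in ("unit_mix", "n_records_per_compound", "planted_overlap"):
            if key in fs:
                fs[key] = tuple(fs[key])
        raw["fixture_spec"] = FixtureSpec(**fs)
    if "exclude_descriptors" in raw:
        raw["exclude_descriptors"] = tuple(raw["exclude_descriptors"])
    return PipelineConfig(**raw)


def _log(out: Path, stage: str, **counts) -> None:
    with (out / "log.jsonl").open("a", encoding="utf-8") as fh:
        fh.write(json.dumps({"stage": stage, **counts}, sort_keys=True) + "\n")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run(config: PipelineConfig) -> FunnelReport:
    """Execute the pipeline described by ``config``; returns the funnel."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "log.jsonl").unlink(missing_ok=True)

    inputs = out / "inputs"
    if config.fixture_spec is not None and not inputs.exists():
        bundle = gen_records_and_snapshots(config.fixture_spec)
        bundle.write(inputs)
    paths = {
        "corpus": Path(config.corpus_path or inputs / "corpus.jsonl"),
        "labels": Path(config.labels_path or inputs / "labels.csv"),
        "records": Path(config.records_path or inputs / "records.csv"),
        "synonyms": Path(config.synonyms_path or inputs / "synonyms.csv"),
        "snapshots": Path(config.snapshots_path or inputs / "snapshots.csv"),
        "associations": Path(config.associations_path or inputs / "associations.csv"),
        "membership": Path(config.membership_path or inputs / "membership.csv"),
    }
    for stage, p in paths.items():
        if stage in ("corpus", "labels", "records", "synonyms", "snapshots") \
                and not p.exists():
            raise FileNotFoundError(f"stage {stage!r}: missing input {p}")

    # stage 1: corpus
    corp = corpus_mod.read_jsonl(paths["corpus"])
    _log(out, "search", n_entries=len(corp))

    # stage 2: vocabulary filter
    decisions_path = out / "filter_decisions.csv"
    if decisions_path.exists():
        df = pd.read_csv(decisions_path, dtype={"entry_id": str})
        passed_ids = set(df[df["passed"]]["entry_id"])
    else:
        vocab = screening.Vocabulary.load()
        decisions = screening.apply_filter(corp, vocab)
        pd.DataFrame([{
            "entry_id": d.entry_id, "passed": d.passed,
            "matched_terms": ";".join(
                f"{cat}:{t}" for cat in sorted(d.matched)
                for t in d.matched[cat]),
        } for d in decisions]).to_csv(decisions_path, index=False)
        passed_ids = {d.entry_id for d in decisions if d.passed}
    filtered = [e for e in corp.entries if e.entry_id in passed_ids]
    _log(out, "filter", n_passed=len(filtered))

    # stage 3: full-text retrievability
    retrievable = [e for e in filtered if e.has_full_text_link]
    _log(out, "retrieve", n_retrievable=len(retrievable))

    # stage 4: curation labels; useful = quantified or unquantified
    labels_df = pd.read_csv(paths["labels"], dtype={"entry_id": str})
    labels = {r.entry_id: r.label for r in labels_df.itertuples(index=False)}
    useful = [e for e in retrievable
              if labels.get(e.entry_id) in screening.USEFUL_LABELS]
    _log(out, "curate", n_useful=len(useful))

    # stage 5: relevance classifier on the filtered, labelled corpus
    metrics_path = out / "classifier_metrics.json"
    if not metrics_path.exists():
        cur = [screening.CurationLabel(entry_id=i, label=l)
               for i, l in sorted(labels.items())]
        try:
            model = screening.train_and_eval(
                corp.entries, cur, split=config.classifier_split,
                seed=config.seed)
            ranking = screening.rank(model, filtered)
            pd.DataFrame(ranking, columns=["entry_id", "score"]).to_csv(
                out / "ranking.csv", index=False)
            _write_json(metrics_path, model.metrics)
        except ValueError as exc:  # degenerate labels (e.g. empty corpus)
            _write_json(metrics_path, {"skipped": str(exc)})
    _log(out, "classify")

    # stage 6: records -> standardized, disambiguated compound entries
    entries_path = out / "entries.csv"
    resolver = records_mod.SynonymTable.from_csv(paths["synonyms"])
    recs = records_mod.read_records_csv(paths["records"])
    recs = records_mod.attach_keys(recs, resolver)
    entries = records_mod.aggregate(recs)
    if not entries_path.exists():
        records_mod.write_entries_csv(entries, entries_path)
    _log(out, "aggregate", n_records=len(recs), n_compounds=len(entries))

    # stage 7: reference comparison
    snapshots = comparison.read_snapshots_csv(paths["snapshots"])
    report = comparison.coverage(entries, snapshots)
    if not (out / "coverage.json").exists():
        _write_json(out / "coverage.json", report.to_dict())
    gold = next((s for s in snapshots if s.source == config.gold_source), None)
    if gold is not None and not (out / "agreement.json").exists():
        try:
            agree = comparison.agreement(entries, gold,
                                         config.exclude_descriptors)
            _write_json(out / "agreement.json", {
                "r2_log": agree.r2_log, "n_pairs": agree.n_pairs,
                "slope": agree.slope, "intercept": agree.intercept,
                "excluded_zero": len(agree.excluded_zero),
                "excluded_descriptor": len(agree.excluded_descriptor),
            })
        except ValueError as exc:
            _write_json(out / "agreement.json", {"skipped": str(exc)})
    top = comparison.paper_frequency(recs, top_k=10)
    if not (out / "top_compounds.csv").exists():
        pd.DataFrame([{"compound": k.canonical_name, "n_papers": n}
                      for k, n in top]).to_csv(out / "top_compounds.csv",
                                               index=False)
    _log(out, "compare", novel_quantified=report.novel_quantified)

    # stage 8: chemical embedding + health overlay (optional inputs)
    if paths["associations"].exists() and paths["membership"].exists() \
            and not (out / "embedding.csv").exists():
        _embed_stage(config, out, entries, paths)
    _log(out, "embed")

    funnel = FunnelReport(
        searched=len(corp), filtered=len(filtered),
        retrievable=len(retrievable), useful=len(useful),
        records=len(recs), unique_compounds=len(entries),
    )
    funnel.validate()
    _write_json(out / "funnel.json", funnel.to_dict())
    return funnel


def _embed_stage(config: PipelineConfig, out: Path, entries, paths) -> None:
    assoc_df = pd.read_csv(paths["associations"])
    associations = {int(r.cid): int(r.n_associations)
                    for r in assoc_df.itertuples(index=False)}
    mem_df = pd.read_csv(paths["membership"])
    membership: dict[int, set[str]] = {}
    for r in mem_df.itertuples(index=False):
        membership.setdefault(int(r.cid), set()).add(str(r.database))
    sentences = []
    for e in entries:
        if e.quantified and e.key.cid is not None and e.key.smiles:
            sentences.append(emb_mod.sentence(
                e.key.smiles, radius=config.embed_radius, cid=e.key.cid))
    if not sentences:
        return
    table = emb_mod.train_embedding(sentences, d=config.embed_dim,
                                    seed=config.seed,
                                    epochs=config.embed_epochs)
    embeds = [emb_mod.embed_compound(s, table) for s in sentences]
    embeds = emb_mod.reduce_2d(embeds, perplexity=config.perplexity,
                               seed=config.seed, method=config.reduce_method)
    embeds, summary = emb_mod.overlay_health(embeds, associations, membership)
    rows = []
    for e in embeds:
        rows.append({
            "cid": e.cid, "x": e.coords2d[0], "y": e.coords2d[1],
            "health_count": e.health_count,
            "databases": ";".join(sorted(e.in_databases)),
            **{f"v{i}": float(v) for i, v in enumerate(e.vector)},
        })
    pd.DataFrame(rows).to_csv(out / "embedding.csv", index=False)
    _write_json(out / "health_summary.json", summary)
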