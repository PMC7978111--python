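"""Evaluation harness: variant categories, recall and specificity.

Known pathogenic regulatory variants are scored against search results at
three tissue tiers — a single best-matching tissue, a wider related-tissue
set, and a tissue-unselected control querying every tissue in the store.
Each case's variant is categorized relative to the affected gene's
transcripts:

* **promoter** — 1–100 bp upstream of any transcript start (upstream in
  transcription direction);
* **intragenic** — within any transcript span but not a promoter variant;
* **distal** — more than 100 bp from the closest transcript start.

Recall is the fraction of cases whose variant lies inside the identified
regions.  Specificity is the fraction of the tissue-unselected result
that a tissue-restricted query excludes, measured on genomic span (with a
region-count variant reported alongside).
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genes import Transcript
from .intervals import GenomeInterval, intersection_span, overlaps
from .search import DatasetConfig, MirnaConfig, SearchEngine, SearchQuery, SearchResult

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationCase",
    "Dist",
    "TierMetrics",
    "EvaluationReport",
    "categorize_variant",
    "compute_specificity",
    "evaluate_cases",
    "load_cases",
]

CATEGORIES = ("promoter", "intragenic", "distal")
TIERS = ("single", "multi", "unselected")

PROMOTER_MIN_BP = 1
PROMOTER_MAX_BP = 100


@dataclass(frozen=True)
class EvaluationCase:
    chrom: str
    pos: int  # 1-based
    ref: str
    gene: str
    best_tissue: str
    related_tissues: tuple[str, ...]
    build: str = "hg38"

    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref), self.build)


def categorize_variant(chrom: str, pos: int, transcripts: list[Transcript]) -> str:
    """Assign promoter / intragenic / distal relative to a gene's transcripts.

    ``pos`` is 1-based.  Promoter takes precedence over intragenic:
    a base 1–100 bp upstream (transcription direction) of *any* transcript
    start is a promoter variant even if it falls inside another transcript
    of the same gene.
    """
    if not transcripts:
        raise ValueError("categorize_variant requires at least one transcript")
    var0 = pos - 1
    same_chrom = [t for t in transcripts if t.chrom == chrom]
    for t in same_chrom:
        upstream = (t.tss - var0) if t.strand == "+" else (var0 - t.tss)
        if PROMOTER_MIN_BP <= upstream <= PROMOTER_MAX_BP:
            return "promoter"
    for t in same_chrom:
        if t.tx_start <= var0 < t.tx_end:
            return "intragenic"
    return "distal"


def compute_specificity(selected: SearchResult, unselected: SearchResult) -> float:
    """Fraction of the tissue-unselected span excluded by the tissue query."""
    unsel_span = unselected.total_span_bp
    if unsel_span == 0:
        raise ValueError("unselected result has zero span; specificity undefined")
    inter = intersection_span(selected.intervals, unselected.intervals)
    return 1.0 - inter / unsel_span


def count_specificity(selected: SearchResult, unselected: SearchResult) -> float:
    """Region-count analogue of :func:`compute_specificity`."""
    if unselected.region_count == 0:
        raise ValueError("unselected result has zero regions")
    return 1.0 - min(selected.region_count, unselected.region_count) / unselected.region_count


@dataclass(frozen=True)
class Dist:
    min: float
    mean: float
    median: float
    max: float

    @classmethod
    def of(cls, values: list[float]) -> "Dist":
        return cls(
            min=min(values),
            mean=statistics.fmean(values),
            median=statistics.median(values),
            max=max(values),
        )


@dataclass
class TierMetrics:
    n_cases: int
    n_identified: int
    region_count: Dist | None = None
    span_bp: Dist | None = None
    specificity_span: Dist | None = None
    specificity_count: Dist | None = None

    @property
    def recall(self) -> float:
        return self.n_identified / self.n_cases if self.n_cases else float("nan")


@dataclass
class EvaluationReport:
    per_category: dict[str, dict[str, TierMetrics]]
    overall: dict[str, TierMetrics]
    flagged_cases: list[EvaluationCase] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        cells = [(cat, tier, m) for cat, tiers in self.per_category.items() for tier, m in tiers.items()]
        cells += [("overall", tier, m) for tier, m in self.overall.items()]
        for cat, tier, m in cells:
            rows.append(
                {
                    "category": cat,
                    "tier": tier,
                    "n_cases": m.n_cases,
                    "n_identified": m.n_identified,
                    "recall": m.recall,
                    "median_region_count": m.region_count.median if m.region_count else None,
                    "median_span_bp": m.span_bp.median if m.span_bp else None,
                    "median_specificity_span": m.specificity_span.median if m.specificity_span else None,
                    "median_specificity_count": m.specificity_count.median if m.specificity_count else None,
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        return self.to_dataframe().to_markdown(index=False)


def load_cases(path: str | Path) -> list[EvaluationCase]:
    """Read a case CSV: chrom, pos, ref, gene, best_tissue, related_tissues, build.

    ``related_tissues`` holds ';'-separated labels (may be empty).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ("chrom", "pos", "ref", "gene", "best_tissue", "related_tissues", "build")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"case table {path} missing columns: {missing}")
    return [
        EvaluationCase(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            gene=r.gene,
            best_tissue=r.best_tissue,
            related_tissues=tuple(t for t in r.related_tissues.split(";") if t),
            build=r.build or "hg38",
        )
        for r in df.itertuples(index=False)
    ]


def _variant_identified(case: EvaluationCase, result: SearchResult) -> bool:
    span = case.span()
    return any(overlaps(span, a.interval) for a in result.intervals)


def evaluate_cases(
    cases: list[EvaluationCase],
    engine: SearchEngine,
    dataset_configs: dict[str, DatasetConfig],
    build: str = "hg38",
    mirna_config: MirnaConfig = MirnaConfig(),
) -> EvaluationReport:
    """Score every case at the three tissue tiers and tabulate the grid.

    Cases whose best tissue has no track anywhere in the store are
    flagged, logged and excluded from the denominators.  The unselected
    tier queries all tissues available in the store.
    """
    if not cases:
        raise ValueError("empty case list")
    all_tissues = tuple(engine.store.available_tissues())
    if not all_tissues:
        raise ValueError("track store is empty")

    usable: list[EvaluationCase] = []
    flagged: list[EvaluationCase] = []
    for case in cases:
        if case.best_tissue not in all_tissues:
            logger.warning(
                "case %s:%d (%s): best tissue %r has no track in the store; excluded",
                case.chrom,
                case.pos,
                case.gene,
                case.best_tissue,
            )
            flagged.append(case)
        else:
            usable.append(case)
    if not usable:
        raise ValueError("no evaluation case has a usable tissue")

    records: list[dict] = []
    for case in usable:
        txs = engine.gene_table.transcripts(case.gene)
        if not txs:
            logger.warning("case gene %r unknown; excluded", case.gene)
            flagged.append(case)
            continue
        category = categorize_variant(case.chrom, case.pos, txs)
        tier_tissues = {
            "single": (case.best_tissue,),
            "multi": tuple(
                dict.fromkeys((case.best_tissue,) + tuple(t for t in case.related_tissues if t in all_tissues))
            ),
            "unselected": all_tissues,
        }
        results: dict[str, SearchResult] = {}
        for tier, tissues in tier_tissues.items():
            query = SearchQuery(
                build=build,
                genes=(case.gene,),
                tissues=tissues,
                dataset_configs=dataset_configs,
                mirna_config=mirna_config,
            )
            results[tier] = engine.run_search(query)
        rec = {"case": case, "category": category}
        for tier in TIERS:
            res = results[tier]
            rec[f"{tier}_identified"] = _variant_identified(case, res)
            rec[f"{tier}_count"] = res.region_count
            rec[f"{tier}_span"] = res.total_span_bp
            if tier != "unselected" and results["unselected"].total_span_bp > 0:
                rec[f"{tier}_spec_span"] = compute_specificity(res, results["unselected"])
                rec[f"{tier}_spec_count"] = count_specificity(res, results["unselected"])
        records.append(rec)

    def metrics_for(subset: list[dict], tier: str) -> TierMetrics:
        m = TierMetrics(
            n_cases=len(subset),
            n_identified=sum(r[f"{tier}_identified"] for r in subset),
        )
        counts = [r[f"{tier}_count"] for r in subset]
        spans = [r[f"{tier}_span"] for r in subset]
        if counts:
            m.region_count = Dist.of(counts)
            m.span_bp = Dist.of(spans)
        spec_span = [r[f"{tier}_spec_span"] for r in subset if f"{tier}_spec_span" in r]
        if spec_span:
            m.specificity_span = Dist.of(spec_span)
            m.specificity_count = Dist.of([r[f"{tier}_spec_count"] for r in subset])
        return m

    per_category: dict[str, dict[str, TierMetrics]] = {}
    for cat in CATEGORIES:
        subset = [r for r in records if r["category"] == cat]
        if subset:
            per_category[cat] = {tier: metrics_for(subset, tier) for tier in TIERS}
    overall = {tier: metrics_for(records, tier) for tier in TIERS}
    return EvaluationReport(per_category=per_category, overall=overall, flagged_cases=flagged)
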