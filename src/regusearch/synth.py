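"""Seeded synthetic-data generator with planted ground truth.

Emulates the inputs of a regulatory-region search at desk scale: a
genePred-style gene table on synthetic chromosomes (``chrS1``...), a store
of tissue-specific regulator tracks, miRNA interaction/locus tables, a
patient VCF, an evaluation case table, and a *truth table* that records,
for every planted pathogenic variant, the minimal query that must recover
it and a query that must exclude it.

Planted regulators are placed at controlled offsets from gene TSSs so that
their variants fall into the three evaluation categories (promoter,
intragenic, distal).  A configurable fraction of plants is *tissue-
mismatched*: the regulator is active only in a tissue unrelated to the
case's phenotype, so a tissue-specific search must miss it while the
tissue-unselected control finds it.  Decoy regions are uniform random
intervals avoiding the planted spans, with dataset-flavoured width
distributions (sparse narrow CAGE-like tracks vs dense wide peak-calling
tracks) so summary statistics exercise realistic contrasts.

Everything is a pure function of the seed: the same spec yields
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import EvaluationCase, categorize_variant
from .genes import GeneTable, Transcript
from .intervals import GenomeInterval
from .mirna import InteractionRegistry, MiRNAInteraction, MiRNALocus
from .tracks import RegulatorClass, TrackStore, make_track

__all__ = ["Plant", "FixtureSpec", "FixtureSet", "generate"]

TISSUE_NAMES = [
    "pancreas", "liver", "brain", "heart", "kidney", "lung", "stomach", "muscle",
    "spleen", "thymus", "ovary", "testis",
]
DATASET_SPECS = [
    # (id, regulator class, decoy width lo/hi, decoys per track multiplier)
    ("FANTOM_enh", RegulatorClass.ENHANCER, 150, 400, 0.5),
    ("SCREEN_prom", RegulatorClass.PROMOTER, 300, 900, 1.0),
    ("ENCODE_chromatin", RegulatorClass.ACCESSIBLE_CHROMATIN, 100, 600, 1.5),
    ("ENCODE_tfbs", RegulatorClass.TFBS, 200, 500, 1.0),
    ("SCREEN_enh", RegulatorClass.ENHANCER, 250, 600, 1.0),
]
# transcription-direction offsets from the TSS (negative = upstream) chosen
# so the variant planted at the regulator's midpoint lands in each category
CATEGORY_OFFSETS = {
    "promoter": (-150, 200),   # midpoint 50 bp upstream of the TSS
    "intragenic": (2000, 400),  # inside the transcript body
    "distal": (-20000, 400),   # 20 kb upstream, outside every transcript
}


@dataclass(frozen=True)
class Plant:
    """One planted regulator and the variant inside it."""

    gene: str
    tissues: tuple[str, ...]
    dataset: str
    offset: int  # transcription-direction offset of the regulator start from the TSS
    width: int
    mismatched: bool = False  # active only in a phenotype-unrelated tissue
    case_best_tissue: str = ""  # tissue the evaluation case will query
    case_related: tuple[str, ...] = ()  # wider tissue set of the evaluation case


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 9
    n_tissues: int = 4
    n_datasets: int = 3
    n_mirnas: int = 6
    decoys_per_track: int = 30
    n_negative_variants: int = 12
    chrom_length: int = 1_000_000
    n_chroms: int = 2
    build: str = "hg38"
    planted: list[Plant] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        plants = doc.pop("planted", None)
        spec = cls(**doc)
        if plants:
            spec.planted = [Plant(**{**p, "tissues": tuple(p["tissues"])}) for p in plants]
        return spec


@dataclass
class FixtureSet:
    spec: FixtureSpec
    gene_table: GeneTable
    store: TrackStore
    mirna_registry: InteractionRegistry
    mirna_loci: dict[str, MiRNALocus]
    cases: list[EvaluationCase]
    truth: pd.DataFrame
    variant_rows: list[tuple[str, int, str, str]] = field(default_factory=list)
    vcf_path: Path | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _plant_interval(tx: Transcript, plant: Plant) -> tuple[int, int]:
    """Genomic [start, end) of a plant given its transcription-direction offset."""
    tss = tx.tss
    if tx.strand == "+":
        start = tss + plant.offset
        end = start + plant.width
    else:
        end = tss - plant.offset + 1
        start = end - plant.width
    return start, end


def _make_genes(spec: FixtureSpec, rng: np.random.Generator) -> GeneTable:
    transcripts: list[Transcript] = []
    per_chrom = -(-spec.n_genes // spec.n_chroms)
    # keep loci well inside the chromosome so upstream plants never clip
    lo, hi = 60_000, spec.chrom_length - 60_000
    slots = np.linspace(lo, hi, per_chrom, dtype=int)
    for gi in range(spec.n_genes):
        chrom = f"chrS{gi // per_chrom + 1}"
        base = int(slots[gi % per_chrom])
        strand = "+" if gi % 2 == 0 else "-"
        gene = f"GENE{gi + 1:03d}"
        n_tx = int(rng.integers(1, 4))
        for ti in range(n_tx):
            length = int(rng.integers(5_000, 20_000))
            if strand == "+":
                # alternative transcripts share the dominant TSS region
                start = base + (0 if ti == 0 else int(rng.integers(0, 300)))
                end = start + length
            else:
                end = base + (0 if ti == 0 else -int(rng.integers(0, 300)))
                start = end - length
            transcripts.append(
                Transcript(
                    gene=gene,
                    tx_id=f"NM_{gi + 1:03d}{ti:02d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    build=spec.build,
                )
            )
    return GeneTable(transcripts)


def _default_plants(spec: FixtureSpec, tissues: list[str], datasets: list[str]) -> list[Plant]:
    plants: list[Plant] = []
    cats = list(CATEGORY_OFFSETS.values())
    for gi in range(spec.n_genes):
        gene = f"GENE{gi + 1:03d}"
        offset, width = cats[gi % len(cats)]
        dataset = datasets[gi % len(datasets)]
        matched = tissues[gi % len(tissues)]
        related = tissues[(gi + 1) % len(tissues)]
        # every fourth plant is active only in an unrelated tissue: the
        # tissue-specific search must miss it, the unselected control finds it
        mismatched = len(tissues) >= 3 and gi % 4 == 3
        if mismatched:
            unrelated = tissues[(gi + 2) % len(tissues)]
            # the case's phenotype tissues deliberately avoid the planted one
            case_related = tuple(t for t in (related,) if t != unrelated)
            plants.append(
                Plant(
                    gene=gene,
                    tissues=(unrelated,),
                    dataset=dataset,
                    offset=offset,
                    width=width,
                    mismatched=True,
                    case_best_tissue=matched,
                    case_related=case_related,
                )
            )
        else:
            plants.append(
                Plant(
                    gene=gene,
                    tissues=(matched, related),
                    dataset=dataset,
                    offset=offset,
                    width=width,
                    case_best_tissue=matched,
                    case_related=(related,),
                )
            )
    return plants


def _sample_avoiding(
    rng: np.random.Generator,
    n: int,
    chrom_length: int,
    width_lo: int,
    width_hi: int,
    forbidden: list[tuple[int, int]],
    margin: int = 500,
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    attempts = 0
    while len(out) < n and attempts < n * 50:
        attempts += 1
        w = int(rng.integers(width_lo, width_hi + 1))
        s = int(rng.integers(0, chrom_length - w))
        if any(s < fe + margin and fs - margin < s + w for fs, fe in forbidden):
            continue
        out.append((s, s + w))
    return out


def generate(spec: FixtureSpec, out_dir: str | Path | None = None) -> FixtureSet:
    """Build the full fixture set; optionally write every file under ``out_dir``."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_datasets > len(DATASET_SPECS):
        raise ValueError(f"at most {len(DATASET_SPECS)} datasets supported")
    tissues = TISSUE_NAMES[: spec.n_tissues]
    dataset_specs = DATASET_SPECS[: spec.n_datasets]
    datasets = [d[0] for d in dataset_specs]
    ds_meta = {d[0]: d for d in dataset_specs}

    gene_table = _make_genes(spec, rng)
    plants = spec.planted if spec.planted is not None else _default_plants(spec, tissues, datasets)

    # resolve plants onto genomic coordinates (anchored on the first transcript)
    plant_rows = []
    per_track_plants: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    forbidden_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for plant in plants:
        txs = gene_table.transcripts(plant.gene)
        if not txs:
            raise ValueError(f"plant references unknown gene {plant.gene}")
        tx = txs[0]
        start, end = _plant_interval(tx, plant)
        if start < 0 or end > spec.chrom_length:
            raise ValueError(f"plant for {plant.gene} falls outside chromosome bounds")
        for tissue in plant.tissues:
            if tissue not in tissues:
                raise ValueError(f"plant tissue {tissue!r} not among fixture tissues")
            key = (plant.dataset, tissue)
            for ps, pe, _ in per_track_plants.get(key, []):
                if start < pe and ps < end:
                    raise ValueError(
                        f"infeasible spec: plants overlap in track {key} "
                        f"([{ps},{pe}) vs [{start},{end}))"
                    )
            per_track_plants.setdefault(key, []).append((start, end, tx.chrom))
        forbidden_by_chrom.setdefault(tx.chrom, []).append((start, end))
        plant_rows.append((plant, tx, start, end))

    # build tracks: planted regulators plus decoys avoiding every planted span
    store = TrackStore()
    for ds_id, cls, wlo, whi, density in dataset_specs:
        for tissue in tissues:
            intervals: list[GenomeInterval] = []
            for (pds, pt), entries in per_track_plants.items():
                if pds == ds_id and pt == tissue:
                    intervals += [
                        GenomeInterval(chrom, s, e, spec.build) for s, e, chrom in entries
                    ]
            n_decoys = int(spec.decoys_per_track * density)
            for ci in range(spec.n_chroms):
                chrom = f"chrS{ci + 1}"
                decoys = _sample_avoiding(
                    rng,
                    n_decoys,
                    spec.chrom_length,
                    wlo,
                    whi,
                    forbidden_by_chrom.get(chrom, []),
                )
                intervals += [GenomeInterval(chrom, s, e, spec.build) for s, e in decoys]
            store.add(make_track(ds_id, tissue, cls, spec.build, intervals))

    # variants: one planted inside each regulator, plus negatives in empty space
    variant_rows = []
    truth_rows = []
    cases: list[EvaluationCase] = []
    for plant, tx, start, end in plant_rows:
        pos = (start + end) // 2 + 1  # 1-based midpoint
        category = categorize_variant(tx.chrom, pos, gene_table.transcripts(plant.gene))
        variant_rows.append((tx.chrom, pos, "A", "G"))
        recovering_tissue = plant.tissues[0]
        best = plant.case_best_tissue or plant.tissues[0]
        related = plant.case_related or tuple(t for t in plant.tissues if t != best)
        related = tuple(t for t in related if t != best)
        excluding = next((t for t in tissues if t not in plant.tissues), "")
        up = max(200, -plant.offset + plant.width)
        down = max(200, plant.offset + plant.width)
        truth_rows.append(
            {
                "chrom": tx.chrom,
                "pos": pos,
                "gene": plant.gene,
                "dataset": plant.dataset,
                "tissue": recovering_tissue,
                "upstream_bp": up,
                "downstream_bp": down,
                "mode": "any",
                "excluding_tissue": excluding,
                "category": category,
                "mismatched": plant.mismatched,
            }
        )
        cases.append(
            EvaluationCase(
                chrom=tx.chrom,
                pos=pos,
                ref="A",
                gene=plant.gene,
                best_tissue=best,
                related_tissues=related,
                build=spec.build,
            )
        )

    all_track_spans: dict[str, list[tuple[int, int]]] = {}
    for track in store:
        for iv in track.intervals:
            all_track_spans.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for ci in range(spec.n_chroms):
        chrom = f"chrS{ci + 1}"
        negs = _sample_avoiding(
            rng,
            -(-spec.n_negative_variants // spec.n_chroms),
            spec.chrom_length,
            1,
            1,
            all_track_spans.get(chrom, []),
            margin=50,
        )
        variant_rows += [(chrom, s + 1, "C", "T") for s, _ in negs]
    variant_rows.sort()

    # miRNA branch: loci on the last chromosome; the first half of the
    # interacting miRNAs sit inside pancreas open chromatin, the rest outside
    mirna_registry = InteractionRegistry()
    mirna_loci: dict[str, MiRNALocus] = {}
    chrom_ds = next((d for d, c, *_ in dataset_specs if c == RegulatorClass.ACCESSIBLE_CHROMATIN), None)
    if spec.n_mirnas and chrom_ds:
        mchrom = f"chrS{spec.n_chroms}"
        forb = forbidden_by_chrom.get(mchrom, [])
        spots = _sample_avoiding(rng, spec.n_mirnas, spec.chrom_length, 70, 110, forb)
        open_tissue = tissues[0]
        track = store.get(chrom_ds, open_tissue, RegulatorClass.ACCESSIBLE_CHROMATIN, spec.build)
        extra_open: list[GenomeInterval] = list(track.intervals)
        for i, (s, e) in enumerate(spots):
            mid = f"hsa-mir-{i + 1:03d}"
            mirna_loci[mid] = MiRNALocus(mid, GenomeInterval(mchrom, s, e, spec.build))
            gene = f"GENE{(i % spec.n_genes) + 1:03d}"
            source = "experimental" if i % 2 == 0 else "predicted"
            mirna_registry.add(
                MiRNAInteraction(
                    mirna_id=mid,
                    gene=gene,
                    source=source,
                    confidence="Functional" if source == "experimental" else "predicted",
                    region="3UTR",
                )
            )
            if i < spec.n_mirnas // 2:
                extra_open.append(GenomeInterval(mchrom, max(0, s - 20), e + 20, spec.build))
        store.add(
            make_track(chrom_ds, open_tissue, RegulatorClass.ACCESSIBLE_CHROMATIN, spec.build, extra_open),
            replace_existing=True,
        )

    truth = pd.DataFrame(truth_rows)
    fixture = FixtureSet(
        spec=spec,
        gene_table=gene_table,
        store=store,
        mirna_registry=mirna_registry,
        mirna_loci=mirna_loci,
        cases=cases,
        truth=truth,
        variant_rows=variant_rows,
    )

    if out_dir is not None:
        fixture.paths = _write_all(fixture, variant_rows, Path(out_dir))
        fixture.vcf_path = fixture.paths["vcf"]
    return fixture


def _write_all(fx: FixtureSet, variant_rows, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes_path = out_dir / "genes.tsv"
    rows = sorted(
        (
            (t.tx_id, t.chrom, t.strand, t.tx_start, t.tx_end, t.gene)
            for g in fx.gene_table.genes
            for t in fx.gene_table.transcripts(g)
        )
    )
    with open(genes_path, "wt", encoding="utf-8") as fh:
        fh.write("name\tchrom\tstrand\ttxStart\ttxEnd\tname2\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    paths["genes"] = genes_path

    manifest = out_dir / "store.yaml"
    fx.store.to_manifest(manifest, out_dir / "tracks")
    paths["manifest"] = manifest

    vcf_path = out_dir / "variants.vcf"
    with open(vcf_path, "wt", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE01\n")
        for chrom, pos, ref, alt in variant_rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\tGT\t0/1\n")
    paths["vcf"] = vcf_path
    fx.vcf_path = vcf_path

    cases_path = out_dir / "cases.csv"
    pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "gene": c.gene,
                "best_tissue": c.best_tissue,
                "related_tissues": ";".join(c.related_tissues),
                "build": c.build,
            }
            for c in fx.cases
        ]
    ).to_csv(cases_path, index=False)
    paths["cases"] = cases_path

    truth_path = out_dir / "truth.csv"
    fx.truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path

    if fx.mirna_loci:
        mirna_bed = out_dir / "mirna_loci.bed"
        with open(mirna_bed, "wt", encoding="utf-8") as fh:
            for mid in sorted(fx.mirna_loci):
                iv = fx.mirna_loci[mid].interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{mid}\n")
        paths["mirna_loci"] = mirna_bed

        inter_path = out_dir / "mirna_interactions.tsv"
        with open(inter_path, "wt", encoding="utf-8") as fh:
            fh.write("mirna_id\tgene\tevidence\tregion\tsource\n")
            for rec in fx.mirna_registry.records():
                fh.write(f"{rec.mirna_id}\t{rec.gene}\t{rec.confidence}\t{rec.region}\t{rec.source}\n")
        paths["mirna_interactions"] = inter_path

    return paths
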