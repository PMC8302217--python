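"""IG / MEG / excluded classification of annotated genes.

Partitions protein-coding gene models into intronless genes (IG: one
transcript, one exon, CDS inside it, nuclear), multi-exon genes (MEG:
intron anywhere -- in the CDS or only in a UTR -- or more than one
transcript) and excluded records (non-coding biotype, mitochondrial
contig, or no CDS annotated).  The cascade is ordered; every gene gets
exactly one call with a reason code.

A gene whose coding sequence sits in a single exon but whose transcript
carries an additional non-coding exon (an intron in the UTR; "uiSEG") is
classified MEG with reason ``utr_intron`` -- only genes devoid of introns
over their whole length are IGs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

DEFAULT_MITO_NAMES = frozenset({"MT", "chrM", "chrMT"})

REASONS = ("multi_exon", "utr_intron", "multi_transcript", "mitochondrial",
           "non_coding", "incomplete_annotation", "ok")
EXCLUDED_REASONS = frozenset(
    {"mitochondrial", "non_coding", "incomplete_annotation"})


class AnnotationError(ValueError):
    """Malformed or unreadable annotation input."""


@dataclass
class TranscriptModel:
    transcript_id: str
    biotype: str
    exons: list[tuple[int, int]]          # 1-based inclusive, sorted
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def coding_exons(self) -> list[tuple[int, int]]:
        """Exons that overlap at least one CDS interval."""
        return [
            (s, e) for s, e in self.exons
            if any(cs <= e and ce >= s for cs, ce in self.cds)
        ]


@dataclass
class GeneModel:
    gene_id: str
    species: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for t in self.transcripts for s, _ in t.exons)

    @property
    def end(self) -> int:
        return max(e for t in self.transcripts for _, e in t.exons)


@dataclass(frozen=True)
class ArchitectureCall:
    gene_id: str
    klass: str    # IG | MEG | EXCLUDED
    reason: str

    def __post_init__(self) -> None:
        assert (self.klass == "EXCLUDED") == (self.reason in EXCLUDED_REASONS)
        assert (self.klass == "IG") == (self.reason == "ok")


# ---------------------------------------------------------------------------
# GTF ingestion

_MANDATORY_FEATURES = {"gene", "transcript", "exon", "CDS"}


def _validate_gtf_lines(path: Path) -> None:
    """Cheap pre-pass so malformed records fail with a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {i}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            feature = fields[2]
            if feature in _MANDATORY_FEATURES and "gene_id" not in fields[8]:
                raise AnnotationError(
                    f"{path}: line {i}: {feature} record lacks gene_id")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {i}: non-integer coordinates") from exc
            if start > end:
                raise AnnotationError(
                    f"{path}: line {i}: start > end ({start} > {end})")


def read_annotation(path: str | Path, species: str) -> list[GeneModel]:
    """Read a GTF file into gene models (1-based inclusive coordinates).

    Genes without any transcript record are dropped; transcripts without
    exons are dropped.  Raises :class:`AnnotationError` with a line number
    for malformed input.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    _validate_gtf_lines(path)
    text = path.read_text()
    if not any(line.strip() and not line.startswith("#")
               for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (g.attributes.get("gene_biotype") or ["protein_coding"])[0]
        model = GeneModel(
            gene_id=g.id, species=species, chrom=g.seqid,
            strand=g.strand or "+", biotype=biotype,
        )
        for t in db.children(g, featuretype="transcript"):
            exons = [(e.start, e.end)
                     for e in db.children(t, featuretype="exon")]
            cds = [(c.start, c.end) for c in db.children(t, featuretype="CDS")]
            if not exons:
                continue
            t_biotype = (t.attributes.get("transcript_biotype")
                         or t.attributes.get("gene_biotype") or [biotype])[0]
            model.transcripts.append(
                TranscriptModel(t.id, t_biotype, exons, cds))
        if model.transcripts:
            genes.append(model)
    return genes


# ---------------------------------------------------------------------------
# classification cascade


def classify_gene(
    gene: GeneModel,
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
) -> ArchitectureCall:
    """Apply the ordered IG/MEG/excluded cascade to one gene."""
    mito = set(mito_names)
    if gene.biotype != "protein_coding":
        return ArchitectureCall(gene.gene_id, "EXCLUDED", "non_coding")
    if gene.chrom in mito:
        return ArchitectureCall(gene.gene_id, "EXCLUDED", "mitochondrial")
    if not any(t.cds for t in gene.transcripts):
        return ArchitectureCall(gene.gene_id, "EXCLUDED",
                                "incomplete_annotation")
    if len(gene.transcripts) > 1:
        return ArchitectureCall(gene.gene_id, "MEG", "multi_transcript")
    t = gene.transcripts[0]
    if len(t.coding_exons()) >= 2:
        return ArchitectureCall(gene.gene_id, "MEG", "multi_exon")
    if t.n_exons >= 2:
        # single coding exon but an intron in the UTR: uiSEG -> MEG
        return ArchitectureCall(gene.gene_id, "MEG", "utr_intron")
    return ArchitectureCall(gene.gene_id, "IG", "ok")


def build_datasets(
    genes: Sequence[GeneModel],
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
) -> tuple[set[str], set[str], dict]:
    """Partition genes into the IG and MEG datasets with a census report."""
    calls = [classify_gene(g, mito_names) for g in genes]
    ig = {c.gene_id for c in calls if c.klass == "IG"}
    meg = {c.gene_id for c in calls if c.klass == "MEG"}
    excluded = {c.gene_id for c in calls if c.klass == "EXCLUDED"}
    report = {
        "total": len(genes),
        "IG": len(ig),
        "MEG": len(meg),
        "EXCLUDED": len(excluded),
        "by_reason": dict(Counter(c.reason for c in calls)),
    }
    assert len(ig) + len(meg) + len(excluded) == len(genes)
    return ig, meg, report


def classify_annotation(
    path: str | Path,
    species: str,
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
) -> tuple[list[ArchitectureCall], dict]:
    genes = read_annotation(path, species)
    calls = [classify_gene(g, mito_names) for g in genes]
    _, _, report = build_datasets(genes, mito_names)
    return calls, report


def write_calls(
    calls: Sequence[ArchitectureCall],
    species: str,
    prefix: str | Path,
    report: dict | None = None,
) -> None:
    """Write the gene-list TSV and, optionally, the JSON census."""
    import pandas as pd

    df = pd.DataFrame(
        [(c.gene_id, species, c.klass, c.reason) for c in calls],
        columns=["gene_id", "species", "class", "reason"],
    )
    df.to_csv(f"{prefix}.calls.tsv", sep="\t", index=False)
    if report is not None:
        Path(f"{prefix}.summary.json").write_text(json.dumps(report, indent=1))


def architecture_map(calls: Sequence[ArchitectureCall]) -> dict[str, str]:
    """gene id -> IG | MEG | Other (excluded records map to Other)."""
    return {
        c.gene_id: (c.klass if c.klass in ("IG", "MEG") else "Other")
        for c in calls
    }
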