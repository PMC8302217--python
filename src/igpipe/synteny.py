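"""Single-locus synteny comparison across species.

Built for cluster-scale questions like the beta-protocadherin locus: pull
the genes of a genomic interval in each species, tag them with their
orthogroup, and compare two loci pairwise -- which orthogroups match,
which are lost in one lineage, which are expanded (more copies), where
gene order is locally inverted and which matches flip strand.

Inversions are detected as maximal descending runs of matched partner
indices; adequate at single-locus scale, no breakpoint-graph machinery.
A gene overlapping the query interval by any amount belongs to the locus.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .gene_architecture import GeneModel
from .expression import DECall


@dataclass
class LocusEntry:
    gene_id: str
    start: int
    end: int
    strand: str
    orthogroup: str | None


@dataclass
class LocusMap:
    species: str
    chrom: str
    entries: list[LocusEntry] = field(default_factory=list)

    @property
    def span(self) -> int:
        if not self.entries:
            return 0
        return (max(e.end for e in self.entries)
                - min(e.start for e in self.entries) + 1)

    def orthogroup_counts(self) -> Counter:
        return Counter(e.orthogroup for e in self.entries
                       if e.orthogroup is not None)


@dataclass
class SyntenyReport:
    matches: list[str]             # orthogroups present in both loci
    losses: list[str]              # in A, absent in B
    novel: list[str]               # in B, absent in A
    expansions: list[str]          # matched, more copies in B than A
    strand_flips: list[str]        # matched, representative strand differs
    inversions: int                # maximal descending runs in B-order
    order_a: list[str]
    order_b: list[str]


def extract_locus(
    genes: Sequence[GeneModel],
    species: str,
    chrom: str,
    start: int,
    end: int,
    orthogroup_of: Mapping[str, str] | None = None,
) -> LocusMap:
    """Genes overlapping [start, end] on ``chrom``, in coordinate order."""
    known_chroms = {g.chrom for g in genes}
    if genes and chrom not in known_chroms:
        raise KeyError(f"unknown chromosome {chrom!r} "
                       f"(have {sorted(known_chroms)})")
    orthogroup_of = orthogroup_of or {}
    entries = []
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.end < start or g.start > end:
            continue
        entries.append(LocusEntry(
            g.gene_id, g.start, g.end, g.strand,
            orthogroup_of.get(g.gene_id)))
    entries.sort(key=lambda e: (e.start, e.gene_id))
    return LocusMap(species, chrom, entries)


def _descending_runs(seq: Sequence[int]) -> int:
    """Number of maximal strictly-descending runs of length >= 2."""
    runs = 0
    i = 0
    while i < len(seq) - 1:
        if seq[i + 1] < seq[i]:
            runs += 1
            while i < len(seq) - 1 and seq[i + 1] < seq[i]:
                i += 1
        else:
            i += 1
    return runs


def pairwise_synteny(a: LocusMap, b: LocusMap) -> SyntenyReport:
    """Compare locus B against reference locus A.

    Every orthogroup present in either locus lands in exactly one of
    matches / losses / novel; ``expansions`` flags matched groups with
    more copies in B, ``strand_flips`` matched groups whose first copies
    disagree in strand.
    """
    counts_a = a.orthogroup_counts()
    counts_b = b.orthogroup_counts()
    matches = sorted(set(counts_a) & set(counts_b))
    losses = sorted(set(counts_a) - set(counts_b))
    novel = sorted(set(counts_b) - set(counts_a))
    expansions = [og for og in matches if counts_b[og] > counts_a[og]]

    first_a = {}
    for i, e in enumerate(a.entries):
        if e.orthogroup is not None and e.orthogroup not in first_a:
            first_a[e.orthogroup] = (i, e.strand)
    first_b = {}
    for i, e in enumerate(b.entries):
        if e.orthogroup is not None and e.orthogroup not in first_b:
            first_b[e.orthogroup] = (i, e.strand)
    strand_flips = [og for og in matches
                    if first_a[og][1] != first_b[og][1]]

    order_a = sorted(matches, key=lambda og: first_a[og][0])
    partner_idx = [first_b[og][0] for og in order_a]
    inversions = _descending_runs(partner_idx)
    order_b = sorted(matches, key=lambda og: first_b[og][0])

    # category exhaustiveness over all orthogroups seen
    seen = set(counts_a) | set(counts_b)
    assert seen == set(matches) | set(losses) | set(novel)
    return SyntenyReport(matches, losses, novel, sorted(expansions),
                         sorted(strand_flips), inversions, order_a, order_b)


def report_frame(report: SyntenyReport) -> pd.DataFrame:
    rows = (
        [("match", og) for og in report.matches]
        + [("loss", og) for og in report.losses]
        + [("novel", og) for og in report.novel]
        + [("expansion", og) for og in report.expansions]
        + [("strand_flip", og) for og in report.strand_flips]
    )
    df = pd.DataFrame(rows, columns=["category", "orthogroup"])
    df.attrs["inversions"] = report.inversions
    return df


def locus_svg(a: LocusMap, b: LocusMap, path) -> None:
    """Minimal two-track SVG of the compared loci (black = single copy,
    gray = expanded), one box per gene."""
    rep = pairwise_synteny(a, b)
    expanded = set(rep.expansions)
    width, row_h, box = 20, 40, 16
    parts = ['<svg xmlns="http://www.w3.org/2000/svg" '
             f'width="{max(len(a.entries), len(b.entries)) * width + 80}" '
             f'height="{2 * row_h + 20}">']
    for row, locus in enumerate((a, b)):
        y = 10 + row * row_h
        parts.append(f'<text x="2" y="{y + 12}" font-size="10">'
                     f'{locus.species}</text>')
        for i, e in enumerate(locus.entries):
            fill = "#888" if (e.orthogroup in expanded) else "#000"
            x = 70 + i * width
            parts.append(f'<rect x="{x}" y="{y}" width="{box}" '
                         f'height="{box}" fill="{fill}"/>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def cluster_expression_summary(
    cluster: Sequence[tuple[str, bool]],
    de_calls: Mapping[str, DECall] | Mapping[str, str],
) -> dict:
    """Expression summary of a gene cluster.

    ``cluster`` rows are (gene id, is_IG flag); ``de_calls`` maps gene id
    to a DECall or directly to a class string.  Genes missing from the
    calls are counted NE with a warning.  Returns member counts, IG
    members, UP members, expressed members and the per-class tally.
    """
    def klass_of(gene: str) -> str | None:
        v = de_calls.get(gene)
        if v is None:
            return None
        return v.klass if isinstance(v, DECall) else str(v)

    classes = {}
    for gene, _ in cluster:
        k = klass_of(gene)
        if k is None:
            warnings.warn(f"cluster gene {gene!r} missing from DE calls; "
                          "counted as NE", stacklevel=2)
            k = "NE"
        classes[gene] = k
    counts = Counter(classes.values())
    members = len(cluster)
    assert sum(counts.values()) == members
    return {
        "members": members,
        "ig_members": sum(1 for _, is_ig in cluster if is_ig),
        "up_members": counts.get("UP", 0),
        "expressed_members": members - counts.get("NE", 0),
        "classes": dict(counts),
    }
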