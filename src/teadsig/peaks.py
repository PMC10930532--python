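"""Strand-aware ChIP-seq peak-to-gene annotation with a fixed feature
priority.

Each peak (BED-style, 0-based half-open) is tested against gene features in
the order Promoter, 5'UTR, 3'UTR, Exon, Intron, Downstream, Intergenic; the
first matching category wins and assigns the owning gene. The promoter is a
window of +/- ``tss_window`` bp around the transcription start site
(strand-aware TSS; the window itself is symmetric and inclusive of both
ends). UTR categories participate only when the gene model provides UTR
intervals. Intergenic peaks record the nearest gene by TSS distance for
context but assign no gene in the gene x dataset peak matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GeneRecord

logger = logging.getLogger("teadsig")

CATEGORIES = ("Promoter", "5UTR", "3UTR", "Exon", "Intron", "Downstream", "Intergenic")


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("peak chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"empty peak interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakAnnotation:
    peak: Peak
    gene_id: str | None
    category: str
    distance_to_tss: int
    nearest_gene: str | None = None


class _ChromIndex:
    """Per-chromosome interval lookup for one feature category."""

    def __init__(self) -> None:
        self.trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, record: GeneRecord) -> None:
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end, record)

    def query(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _signed_tss_distance(peak: Peak, rec: GeneRecord) -> int:
    """Distance from the peak midpoint to the TSS, positive downstream of
    transcription."""
    d = peak.midpoint - rec.tss
    return d if rec.strand == "+" else -d


def annotate_peaks(
    peaks: Iterable[Peak],
    model: GeneModel,
    tss_window: int = 1000,
    downstream_window: int = 3000,
) -> list[PeakAnnotation]:
    """Assign each peak exactly one category and (except Intergenic) one
    gene by the fixed priority cascade.

    A peak overlapping promoter windows of several genes goes to the gene
    with the smallest |TSS distance| (ties: lexicographically smaller gene
    id); the same rule resolves multi-gene overlaps in the other
    categories. Peaks on chromosomes absent from the model are Intergenic
    with a warning.
    """
    if tss_window <= 0 or downstream_window <= 0:
        raise ValueError("windows must be positive")
    promoter = _ChromIndex()
    utr5 = _ChromIndex()
    utr3 = _ChromIndex()
    exon = _ChromIndex()
    body = _ChromIndex()
    downstream = _ChromIndex()
    for rec in model:
        # promoter window [tss - w, tss + w] inclusive -> half-open +1
        promoter.add(rec.chrom, rec.tss - tss_window, rec.tss + tss_window + 1, rec)
        for s, e in rec.utr5:
            utr5.add(rec.chrom, s, e, rec)
        for s, e in rec.utr3:
            utr3.add(rec.chrom, s, e, rec)
        for s, e in rec.exons:
            exon.add(rec.chrom, s, e, rec)
        body.add(rec.chrom, rec.start, rec.end, rec)
        if rec.strand == "+":
            downstream.add(rec.chrom, rec.end, rec.end + downstream_window, rec)
        else:
            downstream.add(rec.chrom, rec.start - downstream_window, rec.start, rec)

    by_chrom = model.by_chrom()
    tss_by_chrom = {
        c: (np.array([r.tss for r in recs]), recs) for c, recs in by_chrom.items()
    }
    cascade = [
        ("Promoter", promoter),
        ("5UTR", utr5),
        ("3UTR", utr3),
        ("Exon", exon),
        ("Intron", body),
        ("Downstream", downstream),
    ]
    warned: set[str] = set()
    out: list[PeakAnnotation] = []
    for peak in peaks:
        if peak.chrom not in by_chrom and peak.chrom not in warned:
            logger.warning("peak chrom %r not in gene model; Intergenic", peak.chrom)
            warned.add(peak.chrom)
        annotation = None
        for category, index in cascade:
            candidates = index.query(peak.chrom, peak.start, peak.end)
            if not candidates:
                continue
            rec = min(
                candidates,
                key=lambda r: (abs(_signed_tss_distance(peak, r)), r.gene_id),
            )
            annotation = PeakAnnotation(
                peak=peak,
                gene_id=rec.gene_id,
                category=category,
                distance_to_tss=_signed_tss_distance(peak, rec),
                nearest_gene=rec.gene_id,
            )
            break
        if annotation is None:
            nearest, dist = None, 0
            if peak.chrom in tss_by_chrom:
                tss_arr, recs = tss_by_chrom[peak.chrom]
                i = int(np.abs(tss_arr - peak.midpoint).argmin())
                nearest = recs[i].gene_id
                dist = _signed_tss_distance(peak, recs[i])
            annotation = PeakAnnotation(
                peak=peak, gene_id=None, category="Intergenic",
                distance_to_tss=dist, nearest_gene=nearest,
            )
        out.append(annotation)
    return out


def gene_peak_matrix(
    annotations_by_dataset: Mapping[str, Iterable[PeakAnnotation]],
    genes: list[str],
) -> pd.DataFrame:
    """Binary gene x dataset matrix: 1 iff at least one non-Intergenic peak
    in that dataset is assigned to the gene."""
    if not annotations_by_dataset:
        raise ValueError("no datasets supplied")
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=list(annotations_by_dataset), dtype=int)
    gene_set = set(genes)
    for dataset, annos in annotations_by_dataset.items():
        for a in annos:
            if a.category == "Intergenic" or a.gene_id is None:
                continue
            if a.gene_id in gene_set:
                mat.loc[a.gene_id, dataset] = 1
    return mat
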