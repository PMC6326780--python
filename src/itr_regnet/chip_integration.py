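"""ChIP peak-to-ITR distance tiers, bound ITRs and per-gene binding classes.

Peaks are binned by their edge-to-edge gap to the nearest annotated ITR
(overlap, <150 bp, <=500 bp, >500 bp, or no ITR on the chromosome). An ITR
with at least one peak within 500 bp is "bound". Peak-bearing genes are
classified by whether their intragenic ITR is bound, whether they carry a
more distal peak despite an ITR, or whether they have a peak but no ITR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    gap_distance,
    intersect_features,
)
from .itr_scanner import ItrHit

TIERS = ["overlap", "lt150", "le500", "gt500", "no_itr_on_chrom"]
GENE_CLASSES = ["bound_itr", "distal_peak_with_itr", "peak_no_itr", "no_peak"]


@dataclass(frozen=True)
class PeakAssignment:
    """A peak, its nearest ITR and the distance tier."""

    peak: GenomicInterval
    nearest_itr: Optional[ItrHit]
    distance: Optional[int]
    tier: str


@dataclass(frozen=True)
class GeneChipClass:
    """Per-gene binding class derived from peak and ITR positions."""

    gene_id: str
    chip_class: str
    n_peaks: int
    n_intragenic_itrs: int
    biotype: str = "protein_coding"


def _tier_of(distance: Optional[int], config: PipelineConfig) -> str:
    if distance is None:
        return "no_itr_on_chrom"
    if distance == 0:
        return "overlap"
    if distance < config.near_dist:
        return "lt150"
    if distance <= config.bound_dist:
        return "le500"
    return "gt500"


def _peak_interval(peak: GenomicInterval, config: PipelineConfig) -> GenomicInterval:
    """Peak geometry used for distances: full span, or 1 bp summit proxy."""
    if config.peak_distance_mode == "summit":
        mid = peak.midpoint
        return GenomicInterval(peak.chrom, mid, mid + 1, peak.strand, peak.name)
    return peak


def assign_peaks(peaks: Sequence[GenomicInterval], itrs: Sequence[ItrHit],
                 config: Optional[PipelineConfig] = None) -> list[PeakAssignment]:
    """Assign each peak to its nearest ITR and distance tier."""
    config = config or PipelineConfig()
    loci = [h.locus for h in itrs]
    by_locus = {(h.locus.chrom, h.locus.start, h.locus.end, h.strand): h
                for h in itrs}
    pairings = intersect_features(
        [_peak_interval(p, config) for p in peaks], loci,
        max_gap=config.bound_dist)
    out = []
    for peak, pairing in zip(peaks, pairings):
        hit = None
        if pairing.target is not None:
            t = pairing.target
            hit = by_locus[(t.chrom, t.start, t.end, t.strand)]
        out.append(PeakAssignment(
            peak=peak, nearest_itr=hit, distance=pairing.distance,
            tier=_tier_of(pairing.distance, config)))
    return out


def bound_itrs(assignments: Sequence[PeakAssignment],
               config: Optional[PipelineConfig] = None) -> list[ItrHit]:
    """Distinct ITRs with at least one peak within the bound distance."""
    config = config or PipelineConfig()
    seen = {}
    for a in assignments:
        if (a.nearest_itr is not None and a.distance is not None
                and a.distance <= config.bound_dist):
            loc = a.nearest_itr.locus
            seen[(loc.chrom, loc.start, loc.end, a.nearest_itr.strand)] = a.nearest_itr
    return [seen[key] for key in sorted(seen)]


def tier_table(assignments: Sequence[PeakAssignment]) -> pd.DataFrame:
    """Peak counts and fractions per distance tier (fractions sum to 1)."""
    counts = {t: 0 for t in TIERS}
    for a in assignments:
        counts[a.tier] += 1
    total = max(1, len(assignments))
    df = pd.DataFrame({
        "tier": TIERS,
        "count": [counts[t] for t in TIERS],
    })
    df["fraction"] = df["count"] / total
    return df


def within_bound_fraction(assignments: Sequence[PeakAssignment],
                          config: Optional[PipelineConfig] = None) -> float:
    """Fraction of peaks within the bound distance of an ITR (overlap included)."""
    config = config or PipelineConfig()
    n = sum(1 for a in assignments
            if a.distance is not None and a.distance <= config.bound_dist)
    return n / len(assignments) if assignments else 0.0


def near_within_bound_fraction(assignments: Sequence[PeakAssignment],
                               config: Optional[PipelineConfig] = None) -> float:
    """Of the peaks within the bound distance, the fraction at < near_dist."""
    config = config or PipelineConfig()
    within = [a for a in assignments
              if a.distance is not None and a.distance <= config.bound_dist]
    if not within:
        return 0.0
    near = sum(1 for a in within if a.distance < config.near_dist)
    return near / len(within)


def _intragenic_itr_intervals(gene: GeneModel,
                              itrs: Sequence[ItrHit],
                              config: PipelineConfig) -> list[ItrHit]:
    """ITRs inside the gene: span overlap by default, intron-only as a mode."""
    inside = [h for h in itrs if h.locus.overlaps(gene.gene)]
    if config.intragenic_itr_mode == "intron":
        inside = [h for h in inside
                  if not any(h.locus.overlaps(e) for e in gene.exons)]
    return inside


def classify_genes(assignments: Sequence[PeakAssignment],
                   genes: Sequence[GeneModel], itrs: Sequence[ItrHit],
                   config: Optional[PipelineConfig] = None,
                   ) -> list[GeneChipClass]:
    """Per-gene binding class.

    A gene is peak-bearing when at least one peak overlaps its span
    (overlapping genes each receive the peak). Classes, in priority order:
    ``bound_itr`` (a peak within the bound distance of an intragenic ITR),
    ``distal_peak_with_itr``, ``peak_no_itr``, else ``no_peak``.
    """
    config = config or PipelineConfig()
    out = []
    for gene in sorted(genes, key=lambda g: (g.gene.chrom, g.gene.start, g.gene_id)):
        gene_peaks = [a for a in assignments if a.peak.overlaps(gene.gene)]
        inside = _intragenic_itr_intervals(gene, itrs, config)
        if not gene_peaks:
            cls = "no_peak"
        elif not inside:
            cls = "peak_no_itr"
        else:
            near = any(
                gap_distance(_peak_interval(a.peak, config), h.locus)
                <= config.bound_dist
                for a in gene_peaks for h in inside)
            cls = "bound_itr" if near else "distal_peak_with_itr"
        out.append(GeneChipClass(gene_id=gene.gene_id, chip_class=cls,
                                 n_peaks=len(gene_peaks),
                                 n_intragenic_itrs=len(inside),
                                 biotype=gene.biotype))
    return out


def gene_class_summary(classes: Sequence[GeneChipClass] = (),
                       counts: Optional[dict[str, int]] = None) -> pd.DataFrame:
    """Counts and integer percentages of peak-bearing genes per class.

    Percentages are over peak-bearing genes only (``no_peak`` excluded),
    rounded to the nearest integer. ``counts`` may be given directly, e.g.
    from published per-class subgroup totals.
    """
    if counts is None:
        counts = {c: 0 for c in GENE_CLASSES if c != "no_peak"}
        for g in classes:
            if g.chip_class != "no_peak":
                counts[g.chip_class] += 1
    order = [c for c in GENE_CLASSES if c != "no_peak"]
    total = sum(counts.get(c, 0) for c in order)
    df = pd.DataFrame({
        "chip_class": order,
        "count": [counts.get(c, 0) for c in order],
    })
    df["percent"] = [int(round(100 * c / total)) if total else 0
                     for c in df["count"]]
    return df


def peak_gene_distribution(peaks: Sequence[GenomicInterval],
                           genes: Sequence[GeneModel],
                           flank: int = 3000) -> pd.DataFrame:
    """Peak counts per exclusive context: intragenic > within_flank > intergenic."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    gene_spans = [g.gene for g in genes]
    counts = {"intragenic": 0, "within_flank": 0, "intergenic": 0}
    pairings = intersect_features(list(peaks), gene_spans, max_gap=flank)
    for pairing in pairings:
        if pairing.distance is not None and pairing.distance == 0:
            counts["intragenic"] += 1
        elif pairing.within_max_gap:
            counts["within_flank"] += 1
        else:
            counts["intergenic"] += 1
    total = max(1, len(peaks))
    df = pd.DataFrame({
        "context": list(counts), "count": list(counts.values()),
    })
    df["fraction"] = df["count"] / total
    return df
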