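"""Coordinate conventions, interval algebra and text-format I/O.

All internal coordinates are 0-based half-open (BED-native). GFF3 input,
which is 1-based closed, is converted at the boundary and never leaks
inward. Distances between intervals are edge-to-edge gaps: overlapping or
abutting intervals are at distance 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap in bp; 0 if the intervals overlap or abut.

    Raises ``ValueError`` on different chromosomes: the gap is undefined
    there, and silently returning infinity hides upstream errors.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class GeneModel:
    """A gene as a TSS-to-poly(A) span plus its (union) exon structure."""

    gene: GenomicInterval
    gene_id: str
    biotype: str = "protein_coding"
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.gene.chrom:
                raise ValueError(f"exon off-chromosome in gene {self.gene_id}")
            if ex.start < self.gene.start or ex.end > self.gene.end:
                raise ValueError(f"exon outside gene span in gene {self.gene_id}")
        self.exons = union_intervals(self.exons)

    @property
    def tss(self) -> int:
        """TSS position: span start on '+', span end − 1 on '−'."""
        return self.gene.start if self.gene.strand != "-" else self.gene.end - 1

    @property
    def exon_length(self) -> int:
        return sum(len(e) for e in self.exons)


def union_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals into a sorted disjoint union."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = dataclasses.replace(last, end=iv.end)
        else:
            out.append(iv)
    return out


@dataclass
class PipelineConfig:
    """Every numeric threshold of the analysis, with the study defaults.

    consensus_length
        Length of the consensus inverted terminal repeat (28 bp for Hsmar1).
    min_length_frac, min_identity
        The dual >=80% retention filters for decayed-ITR hits.
    bound_dist
        A peak within this many bp of an ITR marks it "bound" (500 bp).
    near_dist
        The inner distance tier boundary (150 bp, strict '<').
    gene_flank
        Promoter/terminator flank for peak-to-gene context (3 kb).
    itr_neighborhood
        Radius for "ITR-less gene near an ITR" (10 kb).
    fc_threshold, padj_threshold
        Differential-expression calls: |fold change| strictly above 2,
        adjusted P at most 0.05.
    bin_size
        Metaprofile bin width (10 bp).
    made1_spacer
        Spacer of the miniature element: 6 bp between the inverted ITR
        pair; matched with ``made1_spacer_tol`` slack for indel decay.
    pair_max_gap
        Largest gap at which an inverted ITR pair still counts as a
        single longer remnant (approximate interior of the full-length
        element).
    """

    consensus_length: int = 28
    min_length_frac: float = 0.80
    min_identity: float = 0.80
    bound_dist: int = 500
    near_dist: int = 150
    gene_flank: int = 3000
    itr_neighborhood: int = 10_000
    fc_threshold: float = 2.0
    padj_threshold: float = 0.05
    bin_size: int = 10
    made1_spacer: int = 6
    made1_spacer_tol: int = 2
    pair_max_gap: int = 1500
    profile_halfwidth: int = 2000
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    peak_distance_mode: str = "edge"  # or "summit"
    intragenic_itr_mode: str = "span"  # or "intron"

    def __post_init__(self) -> None:
        for name in (
            "consensus_length", "bound_dist", "near_dist", "gene_flank",
            "itr_neighborhood", "bin_size", "made1_spacer", "pair_max_gap",
            "profile_halfwidth", "padj_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_length_frac", "min_identity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered name -> uppercase sequence map."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = parts[3] if len(parts) > 3 else ""
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            out.append(GenomicInterval(parts[0], start, end, strand, name))
    out.sort(key=lambda i: (i.chrom, i.start, i.end, i.name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              scores: Optional[Sequence[float]] = None) -> None:
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end, i.name))
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 / BED12)


def _finish_gene(gene_id, chrom, strand, gstart, gend, exons, biotype) -> GeneModel:
    span = GenomicInterval(chrom, gstart, gend, strand, gene_id)
    try:
        return GeneModel(gene=span, gene_id=gene_id, biotype=biotype, exons=exons)
    except ValueError as exc:
        raise ValueError(f"invalid gene model for {gene_id}: {exc}") from exc


def read_annotation(path: str | Path,
                    biotype_filter: Optional[str] = None) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (chosen by extension).

    GFF3 gene/exon features are matched through the exon Parent (or
    gene_id) attribute; coordinates are converted to 0-based half-open.
    Output is sorted by (chrom, start, gene_id).
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        genes = _read_bed12(path)
    else:
        genes = _read_gff3(path)
    if biotype_filter is not None:
        genes = [g for g in genes if g.biotype == biotype_filter]
    genes.sort(key=lambda g: (g.gene.chrom, g.gene.start, g.gene_id))
    return genes


def _gff3_attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = parts
            try:
                start, end = int(start1) - 1, int(end1)  # 1-closed -> 0-half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            a = _gff3_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID") or a.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "chrom": chrom, "strand": strand if strand in STRANDS else ".",
                    "start": start, "end": end,
                    "biotype": a.get("biotype", a.get("gene_biotype", "protein_coding")),
                    "exons": [],
                }
            elif ftype == "exon":
                gid = a.get("Parent") or a.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: exon without Parent")
                genes.setdefault(gid, {
                    "chrom": chrom, "strand": strand if strand in STRANDS else ".",
                    "start": start, "end": end,
                    "biotype": "protein_coding", "exons": [],
                })
                genes[gid]["exons"].append((chrom, start, end))
    out = []
    for gid, g in genes.items():
        exons = [
            GenomicInterval(c, s, e, g["strand"], f"{gid}_exon")
            for c, s, e in g["exons"]
        ]
        out.append(_finish_gene(gid, g["chrom"], g["strand"], g["start"], g["end"],
                                exons, g["biotype"]))
    return out


def _read_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if parts[5] in STRANDS else "."
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != len(offsets):
                raise ValueError(f"{path}:{lineno}: blockSizes/blockStarts mismatch")
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand, f"{name}_exon")
                for s, o in zip(sizes, offsets)
            ]
            out.append(_finish_gene(name, chrom, strand, start, end, exons,
                                    "protein_coding"))
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + exon features, 1-based closed)."""
    genes = sorted(genes, key=lambda g: (g.gene.chrom, g.gene.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gi = g.gene
            fh.write(
                f"{gi.chrom}\titr_regnet\tgene\t{gi.start + 1}\t{gi.end}\t.\t"
                f"{gi.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for k, ex in enumerate(g.exons):
                fh.write(
                    f"{ex.chrom}\titr_regnet\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# bedGraph and TSV


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into columns (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df = df.sort_values(["chrom", "start"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Nearest-feature pairing


@dataclass
class FeaturePairing:
    """A query paired with its nearest target (or none on that chrom)."""

    query: GenomicInterval
    target: Optional[GenomicInterval]
    distance: Optional[int]
    within_max_gap: bool


def intersect_features(queries: Sequence[GenomicInterval],
                       targets: Sequence[GenomicInterval],
                       max_gap: int = 0) -> list[FeaturePairing]:
    """Pair each query with its nearest target by edge-to-edge gap.

    Ties go to the leftmost target start, then lexicographic name.
    Strand is ignored. Queries on chromosomes with no target are
    unpaired (``target is None``).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    index: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom, tl in by_chrom.items():
        tl.sort(key=lambda t: (t.start, t.end, t.name))
        starts = np.array([t.start for t in tl])
        index[chrom] = (starts, np.array([t.end for t in tl]), tl)

    out = []
    for q in queries:
        if q.chrom not in index:
            out.append(FeaturePairing(q, None, None, False))
            continue
        starts, ends, tl = index[q.chrom]
        # candidates bracketing the query by sorted start; the nearest by gap
        # must be among targets with start <= q.end (ending latest) or the
        # first ones starting at/after q.end.  Scan a bounded neighbourhood
        # on both sides to be robust to nested intervals.
        gaps = np.maximum(0, np.maximum(starts, q.start) - np.minimum(ends, q.end))
        best = int(np.min(gaps))
        cands = [tl[i] for i in np.flatnonzero(gaps == best)]
        cands.sort(key=lambda t: (t.start, t.name))
        out.append(FeaturePairing(q, cands[0], best, best <= max_gap))
    return out
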