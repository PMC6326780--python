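"""Detection and classification of decayed inverted-terminal-repeat copies.

A consensus ITR (28 bp for the Hsmar1 mariner element) is aligned locally
against both strands of a genome. A hit is retained when it keeps at least
80% of the consensus length aligned AND at least 80% identity over the
aligned columns — the two filters are applied separately, which is the
strictest reading of "80% of the length and identity".

Hit finding is a two-stage scan: a fast ungapped seed pass (chunked
Hamming distances computed with numpy shifts) proposes candidate windows,
which are then re-scored with a proper local (Smith-Waterman) alignment.
The affine scoring (+1 match, -1 mismatch, -2 gap open, -1 gap extend)
approximates the megablast regime and is configurable.

Retained hits are grouped into remnants: a Made1-like miniature element is
an inverted ITR pair around a ~6 bp spacer; wider inverted pairs up to the
interior length of the full element are "paired" remnants; everything else
is a solo ITR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_intervals import (
    FeaturePairing,
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    intersect_features,
)

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "",
}
# N in the genome never matches anything, including N in the consensus.

_BASE_TO_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ItrHit:
    """One retained degraded-ITR match."""

    locus: GenomicInterval
    identity: float
    aligned_consensus_frac: float
    score: float
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 1):
            raise ValueError("identity must be in [0, 1]")
        if not (0 < self.aligned_consensus_frac <= 1):
            raise ValueError("aligned_consensus_frac must be in (0, 1]")


@dataclass(frozen=True)
class RemnantAnnotation:
    """A remnant: solo ITR, Made1-like inverted pair, or wider pair."""

    remnant_class: str  # solo_itr | made1 | paired_itr_remnant
    itrs: tuple[ItrHit, ...]
    spacer_length: Optional[int] = None

    @property
    def locus(self) -> GenomicInterval:
        first, last = self.itrs[0].locus, self.itrs[-1].locus
        return GenomicInterval(first.chrom, first.start, last.end, ".",
                               self.remnant_class)


def _substitution_matrix(config: PipelineConfig) -> substitution_matrices.Array:
    """Consensus-vs-genome scores honouring IUPAC codes in the consensus."""
    alphabet = "ACGTRYSWKMBDHVN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            allowed = IUPAC[a]
            mat[a, b] = config.match_score if b in allowed else config.mismatch_score
    return mat


def _make_aligner(config: PipelineConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _substitution_matrix(config)
    aligner.open_gap_score = config.gap_open + config.gap_extend
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _score_window(consensus: str, window: str, aligner: Align.PairwiseAligner,
                  config: PipelineConfig):
    """Best local alignment of consensus vs window.

    Returns (score, identity, aligned_frac, win_start, win_end) or None
    when no positive-scoring alignment exists.
    """
    if not window:
        return None
    try:
        alns = aligner.align(consensus, window)
        if len(alns) == 0:
            return None
        aln = alns[0]
    except (ValueError, OverflowError):
        return None
    score = float(aln.score)
    if score <= 0:
        return None
    blocks_q, blocks_t = aln.aligned
    if len(blocks_q) == 0:
        return None
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            aligned_cols += 1
            if window[ti] in IUPAC[consensus[qi]]:
                matches += 1
    # gap columns inside the local span
    q_span = blocks_q[-1][1] - blocks_q[0][0]
    t_span = blocks_t[-1][1] - blocks_t[0][0]
    aligned_pairs = aligned_cols
    gap_cols = (q_span - aligned_pairs) + (t_span - aligned_pairs)
    aligned_cols += gap_cols
    identity = matches / aligned_cols if aligned_cols else 0.0
    aligned_frac = q_span / len(consensus)
    return score, identity, aligned_frac, int(blocks_t[0][0]), int(blocks_t[-1][1])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.uint8)  # 4 = N/other, never matches
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _seed_candidates(genome_codes: np.ndarray, consensus: str,
                     max_mismatch_frac: float = 0.32,
                     chunk_len: int = 7) -> np.ndarray:
    """Candidate hit start offsets from ungapped chunked Hamming scans.

    A decayed copy passing the retention filters has few edit operations;
    by pigeonhole some chunk of the consensus survives nearly intact and
    ungapped. Offsets where the full-length mismatch count is low, or any
    chunk matches with <=1 mismatch, become candidates.
    """
    L, w = len(genome_codes), len(consensus)
    if L < chunk_len:
        return np.empty(0, dtype=np.int64)
    cons_sets = [IUPAC[b] for b in consensus]
    n_off = L - w + 1
    cand = np.zeros(max(L, 1), dtype=bool)

    if n_off > 0:
        mism = np.zeros(n_off, dtype=np.int16)
        for i, allowed in enumerate(cons_sets):
            col = genome_codes[i:i + n_off]
            ok = np.zeros(n_off, dtype=bool)
            for b in allowed:
                ok |= col == _BASE_TO_CODE[b]
            mism += ~ok
        cand[:n_off] |= mism <= int(round(max_mismatch_frac * w))

    # chunk seeds: a chunk at consensus offset c found at genome pos p
    # suggests a hit starting near p - c (allow +-3 for indel shift)
    for c0 in range(0, w - chunk_len + 1, chunk_len):
        clen = min(chunk_len, w - c0)
        n = L - clen + 1
        if n <= 0:
            continue
        mism = np.zeros(n, dtype=np.int16)
        for i in range(clen):
            allowed = cons_sets[c0 + i]
            col = genome_codes[i:i + n]
            ok = np.zeros(n, dtype=bool)
            for b in allowed:
                ok |= col == _BASE_TO_CODE[b]
            mism += ~ok
        hits = np.flatnonzero(mism <= 1) - c0
        for shift in range(-3, 4):
            pos = hits + shift
            pos = pos[(pos >= 0) & (pos < L)]
            cand[pos] = True
    return np.flatnonzero(cand)


def _merge_candidate_windows(offsets: np.ndarray, width: int,
                             pad: int, genome_len: int) -> list[tuple[int, int]]:
    """Collapse candidate start offsets into padded scan windows."""
    if offsets.size == 0:
        return []
    windows = []
    run_start = prev = int(offsets[0])
    for off in offsets[1:]:
        off = int(off)
        if off - prev <= width:
            prev = off
        else:
            windows.append((max(0, run_start - pad),
                            min(genome_len, prev + width + pad)))
            run_start = prev = off
    windows.append((max(0, run_start - pad), min(genome_len, prev + width + pad)))
    return windows


def _scan_window_exhaustive(chrom: str, seq: str, lo: int, hi: int, consensus: str,
                            strand: str, aligner: Align.PairwiseAligner,
                            config: PipelineConfig) -> list[ItrHit]:
    """All retained hits within seq[lo:hi] by repeated best-local-alignment.

    The best local alignment of the window is taken; if retained, its span
    is masked and the flanks are re-scanned, so multiple non-overlapping
    hits inside one window are all reported.
    """
    out: list[ItrHit] = []
    stack = [(lo, hi)]
    min_len = int(np.ceil(config.min_length_frac * len(consensus)))
    while stack:
        a, b = stack.pop()
        if b - a < min_len:
            continue
        res = _score_window(consensus, seq[a:b], aligner, config)
        if res is None:
            continue
        score, identity, frac, ws, we = res
        if identity >= config.min_identity and frac >= config.min_length_frac:
            out.append(ItrHit(
                locus=GenomicInterval(chrom, a + ws, a + we, strand, "itr"),
                identity=round(identity, 6),
                aligned_consensus_frac=round(frac, 6),
                score=score, strand=strand,
            ))
        # recurse on flanks either way: a weaker centre alignment may mask
        # a retained hit to one side
        if we <= ws:
            continue
        stack.append((a, a + ws))
        stack.append((a + we, b))
    return out


def _dedupe_same_strand(hits: list[ItrHit]) -> list[ItrHit]:
    """Merge overlapping same-strand hits, keeping the higher score.

    Ties break leftmost start, then plus strand first.
    """
    hits = sorted(
        hits,
        key=lambda h: (-h.score, h.locus.chrom, h.locus.start,
                       0 if h.strand == "+" else 1),
    )
    kept: list[ItrHit] = []
    for h in hits:
        if any(h.strand == k.strand and h.locus.overlaps(k.locus) for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.locus.chrom, h.locus.start, h.locus.end, h.strand))
    return kept


def scan_consensus(genome: dict[str, str], consensus: str,
                   config: Optional[PipelineConfig] = None) -> list[ItrHit]:
    """Scan a genome for decayed copies of a consensus ITR on both strands.

    Parameters
    ----------
    genome
        Mapping of sequence name to sequence (A/C/G/T/N).
    consensus
        The consensus ITR (IUPAC ambiguity codes allowed).
    config
        Thresholds and alignment scores; study defaults if omitted.

    Returns
    -------
    Sorted list of retained :class:`ItrHit` passing both 80% filters.
    """
    config = config or PipelineConfig()
    consensus = consensus.strip().upper()
    if not consensus:
        raise ValueError("empty consensus")
    if not genome or all(not s for s in genome.values()):
        raise ValueError("empty genome")
    bad = set(consensus) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
    if all(len(s) < len(consensus) for s in genome.values()):
        logger.warning("consensus longer than every genome sequence")
        return []

    aligner = _make_aligner(config)
    rc = str(Seq(consensus).reverse_complement())
    hits: list[ItrHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        codes = _encode(seq)
        for strand, cons in (("+", consensus), ("-", rc)):
            offsets = _seed_candidates(codes, cons)
            windows = _merge_candidate_windows(
                offsets, len(cons), pad=10, genome_len=len(seq))
            for lo, hi in windows:
                hits.extend(_scan_window_exhaustive(
                    chrom, seq, lo, hi, cons, strand, aligner, config))
    return _dedupe_same_strand(hits)


def scan_consensus_bruteforce(genome: dict[str, str], consensus: str,
                              config: Optional[PipelineConfig] = None,
                              ) -> list[ItrHit]:
    """Exhaustive reference scan: every window is aligned, no seed heuristic.

    Quadratically slower than :func:`scan_consensus`; intended for
    validation on small sequences.
    """
    config = config or PipelineConfig()
    consensus = consensus.strip().upper()
    aligner = _make_aligner(config)
    rc = str(Seq(consensus).reverse_complement())
    hits: list[ItrHit] = []
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for strand, cons in (("+", consensus), ("-", rc)):
            hits.extend(_scan_window_exhaustive(
                chrom, seq, 0, len(seq), cons, strand, aligner, config))
    return _dedupe_same_strand(hits)


def classify_remnants(hits: Sequence[ItrHit],
                      config: Optional[PipelineConfig] = None,
                      ) -> list[RemnantAnnotation]:
    """Group sorted hits into remnant annotations.

    Greedy left-to-right: each unconsumed hit tries to pair with the next
    unconsumed hit on the same chromosome in inverted orientation. A gap
    within the Made1 spacer tolerance yields a ``made1`` annotation; gaps
    up to ``pair_max_gap`` yield ``paired_itr_remnant``; everything else
    is ``solo_itr``. Every hit belongs to exactly one annotation.
    """
    config = config or PipelineConfig()
    hits = sorted(hits, key=lambda h: (h.locus.chrom, h.locus.start, h.locus.end))
    lo = config.made1_spacer - config.made1_spacer_tol
    hi = config.made1_spacer + config.made1_spacer_tol
    out: list[RemnantAnnotation] = []
    i = 0
    while i < len(hits):
        h = hits[i]
        if i + 1 < len(hits):
            nxt = hits[i + 1]
            if (nxt.locus.chrom == h.locus.chrom and nxt.strand != h.strand):
                gap = max(0, nxt.locus.start - h.locus.end)
                if lo <= gap <= hi:
                    out.append(RemnantAnnotation("made1", (h, nxt), gap))
                    i += 2
                    continue
                if gap <= config.pair_max_gap:
                    out.append(RemnantAnnotation("paired_itr_remnant", (h, nxt), gap))
                    i += 2
                    continue
        out.append(RemnantAnnotation("solo_itr", (h,)))
        i += 1
    return out


def census_report(annotations: Sequence[RemnantAnnotation],
                  genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Counts of remnants per class and genomic context.

    Context is ``intragenic_exon`` when the remnant overlaps a gene's exon
    union, ``intragenic_intron`` when it overlaps the gene span only, and
    ``intergenic`` otherwise. One row per (chrom, class, context).
    """
    classes = ["solo_itr", "made1", "paired_itr_remnant"]
    contexts = ["intragenic_exon", "intragenic_intron", "intergenic"]
    gene_spans = [g.gene for g in genes]
    exon_union = [e for g in genes for e in g.exons]
    rows = []
    loci = [a.locus for a in annotations]
    gene_pairs = intersect_features(loci, gene_spans, max_gap=0) if loci else []
    exon_pairs = intersect_features(loci, exon_union, max_gap=0) if loci else []
    for a, gp, ep in zip(annotations, gene_pairs, exon_pairs):
        if gp.within_max_gap and gp.distance == 0:
            ctx = "intragenic_exon" if (ep.within_max_gap and ep.distance == 0) \
                else "intragenic_intron"
        else:
            ctx = "intergenic"
        rows.append((a.locus.chrom, a.remnant_class, ctx))
    df = pd.DataFrame(rows, columns=["chrom", "remnant_class", "context"])
    if df.empty:
        counts = pd.DataFrame(
            [(c, x, 0) for c in classes for x in contexts],
            columns=["remnant_class", "context", "count"],
        )
        counts.insert(0, "chrom", "")
        return counts
    counts = (df.value_counts(["chrom", "remnant_class", "context"])
                .rename("count").reset_index()
                .sort_values(["chrom", "remnant_class", "context"])
                .reset_index(drop=True))
    return counts


def hits_to_bed_names(hits: Sequence[ItrHit],
                      annotations: Sequence[RemnantAnnotation]) -> list[str]:
    """BED name strings encoding class and identity, e.g. ``solo_itr|id=0.82``."""
    cls_of = {}
    for a in annotations:
        for h in a.itrs:
            cls_of[id(h)] = a.remnant_class
    return [f"{cls_of.get(id(h), 'itr')}|id={h.identity:.2f}" for h in hits]
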