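"""Synthetic fixtures with ground truth for every pipeline stage.

The generator emulates the structure of the study system: a genome
carrying decayed copies of a 28 bp consensus ITR (solo, or as miniature
Made1-like elements — two inverted ITRs around a ~6 bp spacer), gene
models whose introns host about two-thirds of the remnants, ChIP peak
sets preferentially placed at ITRs, coverage tracks with nucleosome
depletion and phased oscillation at ITR centres, and paired
differential-expression tables in which ITR-containing genes are enriched
among up-regulated genes and most shared DE genes flip direction between
conditions.

Background sequence is i.i.d. uniform A/C/G/T — sufficient for
correctness testing; a realistic repeat landscape is a non-goal. All
draws come from one seeded generator, so outputs are byte-identical for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gff3,
    write_tsv,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")

# Hsmar1-like 28 bp consensus used by the default presets. Any consensus
# can be supplied; this one is synthetic (generated once, fixed) and is
# NOT the Repbase sequence, which is an input, never hard-coded.
DEFAULT_CONSENSUS = "TTAGGTTGGTGCAAAAGTAATTGCGGTT"


@dataclass
class SimulationConfig:
    """Study-condition defaults for the generator.

    The counts mirror the study's printed numbers where it states them:
    875 ChIP peaks with 34% near ITRs; DE tables over 16,776 analyzed
    genes with 960 up / 517 down in the active condition, 103 shared DE
    genes of which ~74% flip direction; roughly 45% of remnants are
    Made1-like pairs and two-thirds sit inside genes.
    """

    genome_length: int = 200_000
    chrom: str = "chr1"
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 7)
    n_remnants: int = 30
    made1_frac: float = 0.45
    frac_intragenic: float = 2 / 3
    divergence: float = 0.08
    min_separation: int = 1200
    consensus: str = DEFAULT_CONSENSUS
    # ChIP
    n_peaks: int = 60
    frac_at_itr: float = 0.34
    peak_width: int = 50
    near_dist: int = 150
    make_tracks: bool = True
    background_rate: float = 1.0
    # DE
    n_de_genes: int = 16_776
    n_up_a: int = 960
    n_down_a: int = 517
    n_shared: int = 103
    opposite_frac: float = 0.74
    itr_odds_ratio: float = 3.0
    itr_gene_frac: float = 0.07
    n_b_exclusive: int = 1149
    b_down_frac: float = 0.75


def preset(name: str) -> SimulationConfig:
    """Named generator configurations.

    ``small`` runs end-to-end in seconds (200 kb genome, tracks emitted);
    ``paper-scale`` keeps the printed peak and DE counts on a 10 Mb
    genome with 160 remnants (tracks suppressed: at per-bp resolution
    they would dwarf every other output).
    """
    if name == "small":
        return SimulationConfig()
    if name == "paper-scale":
        return SimulationConfig(
            genome_length=10_000_000, n_genes=400, n_remnants=160,
            n_peaks=875, make_tracks=False, min_separation=2000)
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class PlantedItr:
    """Ground truth for one planted (possibly decayed) ITR copy."""

    start: int
    end: int
    strand: str
    divergence: float
    n_sub: int
    n_indel: int
    remnant_class: str
    remnant_index: int
    gene_id: Optional[str] = None


@dataclass
class SimulationManifest:
    """Everything needed to recompute expected stage outputs."""

    seed: int
    genome_length: int
    chrom: str
    consensus: str
    planted_itrs: list[PlantedItr] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)
    itr_gene_ids: list[str] = field(default_factory=list)
    bound_itr_indices: list[int] = field(default_factory=list)
    de_truth: Optional[pd.DataFrame] = None
    enrichment_truth: Optional[dict] = None

    def itr_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, p.start, p.end, p.strand,
                                f"planted_{i}")
                for i, p in enumerate(self.planted_itrs)]

    def to_json(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "chrom": self.chrom,
            "consensus": self.consensus,
            "planted_itrs": [dataclasses.asdict(p) for p in self.planted_itrs],
            "genes": [
                {"gene_id": g.gene_id, "start": g.gene.start, "end": g.gene.end,
                 "strand": g.gene.strand, "biotype": g.biotype,
                 "exons": [[e.start, e.end] for e in g.exons]}
                for g in self.gene_models
            ],
            "itr_gene_ids": self.itr_gene_ids,
            "bound_itr_indices": self.bound_itr_indices,
            "enrichment_truth": self.enrichment_truth,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def decay_sequence(seq: str, divergence: float,
                   rng: np.random.Generator) -> tuple[str, int, int]:
    """Mutate a sequence: per-site substitutions at rate d, indels at d/10.

    Indel lengths are geometric with mean 1. Returns the decayed sequence
    and the substitution / indel event counts.
    """
    out = []
    n_sub = n_indel = 0
    i = 0
    while i < len(seq):
        ch = seq[i]
        r = rng.random()
        if r < divergence:  # substitution to a different base
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(0, 3)])
            n_sub += 1
            i += 1
        elif r < divergence * 1.1:  # indel, geometric length (p=0.5)
            n_indel += 1
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:
                i += length  # deletion of `length` bases
            else:
                out.append(ch)
                out.append("".join(_random_seq(rng, length).astype(str)))
                i += 1
        else:
            out.append(ch)
            i += 1
    return "".join(out), n_sub, n_indel


def _make_gene_models(cfg: SimulationConfig,
                      rng: np.random.Generator) -> list[GeneModel]:
    slot = cfg.genome_length // cfg.n_genes
    genes = []
    for i in range(cfg.n_genes):
        margin = max(200, slot // 10)
        glen = int(rng.integers(int(slot * 0.35), int(slot * 0.6)))
        start = i * slot + int(rng.integers(margin // 2, margin))
        end = min(start + glen, (i + 1) * slot - 50)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        # breakpoints give alternating exon/intron blocks, starting and
        # ending with an exon
        n_break = 2 * n_ex - 2
        inner = np.sort(rng.choice(
            np.arange(start + 50, end - 50), size=n_break, replace=False))
        bounds = [start, *inner.tolist(), end]
        exons = []
        for j in range(0, len(bounds) - 1, 2):
            if bounds[j + 1] > bounds[j]:
                exons.append(GenomicInterval(cfg.chrom, bounds[j], bounds[j + 1],
                                             strand, f"g{i:04d}_exon"))
        biotype = "protein_coding" if rng.random() < 0.8 else "non_coding"
        genes.append(GeneModel(
            gene=GenomicInterval(cfg.chrom, start, end, strand, f"g{i:04d}"),
            gene_id=f"g{i:04d}", biotype=biotype, exons=exons))
    return genes


def _introns(gene: GeneModel) -> list[tuple[int, int]]:
    out = []
    prev = None
    for e in gene.exons:
        if prev is not None and e.start > prev:
            out.append((prev, e.start))
        prev = e.end
    return out


def simulate_genome(config: Optional[SimulationConfig] = None,
                    seed: int = 0) -> tuple[dict[str, str], SimulationManifest]:
    """Generate a genome with planted decayed remnants and gene models.

    About ``frac_intragenic`` of remnants land in introns of randomly
    chosen genes, the rest in intergenic space; ``made1_frac`` of
    remnants are inverted ITR pairs with a 6 bp spacer. Deterministic for
    a fixed seed.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    consensus = cfg.consensus.upper()
    footprint = cfg.n_remnants * (2 * len(consensus) + 6 + cfg.min_separation)
    if cfg.genome_length < max(10 * cfg.n_remnants * (2 * len(consensus) + 6),
                               footprint // 2):
        raise ValueError("genome too small for requested planting density")

    seq = _random_seq(rng, cfg.genome_length)
    genes = _make_gene_models(cfg, rng)
    intron_sites = [(g, iv) for g in genes for iv in _introns(g)
                    if iv[1] - iv[0] > 2 * len(consensus) + 60]

    manifest = SimulationManifest(
        seed=seed, genome_length=cfg.genome_length, chrom=cfg.chrom,
        consensus=consensus)
    occupied: list[tuple[int, int]] = []
    rc = str(Seq(consensus).reverse_complement())

    def _free(lo: int, hi: int) -> bool:
        return all(hi + cfg.min_separation <= s or lo >= e + cfg.min_separation
                   for s, e in occupied)

    itr_gene_ids: set[str] = set()
    for ridx in range(cfg.n_remnants):
        is_made1 = rng.random() < cfg.made1_frac
        left, ls, li = decay_sequence(consensus, cfg.divergence, rng)
        parts = [left]
        meta = [("+", ls, li, len(left))]
        if is_made1:
            spacer = "".join(_random_seq(rng, 6).astype(str))
            right, rs, ri = decay_sequence(rc, cfg.divergence, rng)
            parts += [spacer, right]
            meta.append(("-", rs, ri, len(right)))
        insert = "".join(parts)

        intragenic = bool(intron_sites) and rng.random() < cfg.frac_intragenic
        placed = None
        for _ in range(200):
            if intragenic:
                g, (ilo, ihi) = intron_sites[rng.integers(0, len(intron_sites))]
                if ihi - ilo <= len(insert) + 20:
                    continue
                pos = int(rng.integers(ilo + 10, ihi - len(insert) - 10))
                gene_id = g.gene_id
            else:
                pos = int(rng.integers(0, cfg.genome_length - len(insert)))
                gene_id = None
                if any(gv.gene.start - 100 < pos < gv.gene.end + 100
                       for gv in genes):
                    continue
            if _free(pos, pos + len(insert)):
                placed = (pos, gene_id)
                break
        if placed is None:
            raise ValueError("infeasible packing: could not place remnant")
        pos, gene_id = placed
        seq[pos:pos + len(insert)] = np.frombuffer(
            insert.encode(), dtype="S1")
        occupied.append((pos, pos + len(insert)))
        cls = "made1" if is_made1 else "solo_itr"
        cursor = pos
        for j, (strand, n_sub, n_indel, length) in enumerate(meta):
            manifest.planted_itrs.append(PlantedItr(
                start=cursor, end=cursor + length, strand=strand,
                divergence=cfg.divergence, n_sub=n_sub, n_indel=n_indel,
                remnant_class=cls, remnant_index=ridx, gene_id=gene_id))
            cursor += length
            if is_made1 and j == 0:
                cursor += 6  # spacer
        if gene_id is not None:
            itr_gene_ids.add(gene_id)

    manifest.gene_models = genes
    manifest.itr_gene_ids = sorted(itr_gene_ids)
    genome = {cfg.chrom: seq.tobytes().decode("ascii")}
    return genome, manifest


def simulate_chip(manifest: SimulationManifest,
                  n_peaks: Optional[int] = None,
                  frac_at_itr: Optional[float] = None,
                  seed: int = 0,
                  config: Optional[SimulationConfig] = None,
                  ) -> dict:
    """Plant a peak set: a fixed share centred near randomly chosen ITRs.

    ``round(frac_at_itr * n_peaks)`` peaks are centred within
    +-``near_dist`` bp of planted ITR centres (these ITRs become the
    ground-truth bound set); the remainder are uniform over the genome.
    Optionally emits per-bp IP/input tracks: the IP track is the peak set
    convolved with a triangular kernel over Poisson background, the input
    is Poisson background alone.
    """
    cfg = config or SimulationConfig()
    n_peaks = cfg.n_peaks if n_peaks is None else n_peaks
    frac = cfg.frac_at_itr if frac_at_itr is None else frac_at_itr
    if not (0 <= frac <= 1):
        raise ValueError("frac_at_itr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = manifest.genome_length
    half = cfg.peak_width // 2
    n_at = int(round(frac * n_peaks))
    peaks = []
    bound: set[int] = set()
    n_itrs = len(manifest.planted_itrs)
    for i in range(n_at):
        idx = int(rng.integers(0, n_itrs))
        p = manifest.planted_itrs[idx]
        center = (p.start + p.end) // 2 + int(
            rng.integers(-cfg.near_dist, cfg.near_dist + 1))
        center = min(max(center, half), L - half)
        peaks.append(GenomicInterval(manifest.chrom, center - half,
                                     center + half, ".", f"peak_itr_{i}"))
        bound.add(idx)
    for i in range(n_peaks - n_at):
        center = int(rng.integers(half, L - half))
        peaks.append(GenomicInterval(manifest.chrom, center - half,
                                     center + half, ".", f"peak_bg_{i}"))
    peaks.sort(key=lambda p: (p.start, p.name))
    manifest.bound_itr_indices = sorted(bound)

    result = {"peaks": peaks, "bound_itr_indices": sorted(bound)}
    if cfg.make_tracks:
        bg_ip = rng.poisson(cfg.background_rate, size=L).astype(float)
        bg_in = rng.poisson(cfg.background_rate, size=L).astype(float)
        kernel_half = 100
        kernel = np.concatenate([
            np.linspace(0, 1, kernel_half, endpoint=False),
            np.linspace(1, 0, kernel_half + 1),
        ]) * 20.0
        signal = np.zeros(L)
        for p in peaks:
            mid = p.midpoint
            lo = max(0, mid - kernel_half)
            hi = min(L, mid + kernel_half + 1)
            signal[lo:hi] += kernel[lo - (mid - kernel_half):
                                    hi - (mid - kernel_half)]
        result["ip_track"] = coverage_to_bedgraph(bg_ip + signal, manifest.chrom)
        result["input_track"] = coverage_to_bedgraph(bg_in, manifest.chrom)
    return result


def simulate_nucleosome_track(manifest: SimulationManifest, seed: int = 0,
                              period: int = 200, phase_extent: int = 1000,
                              depletion_width: int = 80,
                              noise_sd: float = 0.05) -> pd.DataFrame:
    """Nucleosome-like coverage: trough at each ITR centre, phased cosine.

    Baseline 1x coverage with, at every planted ITR centre, a Gaussian
    depletion trough and an exponentially damped cosine with the given
    period extending ~``phase_extent`` bp to either side.
    """
    rng = np.random.default_rng(seed)
    L = manifest.genome_length
    cov = np.ones(L) + rng.normal(0, noise_sd, size=L)
    x = np.arange(-phase_extent, phase_extent + 1)
    trough = -0.8 * np.exp(-0.5 * (x / depletion_width) ** 2)
    wave = 0.3 * np.cos(2 * np.pi * x / period) * np.exp(
        -np.abs(x) / (phase_extent / 2.5))
    wave[np.abs(x) < depletion_width] *= np.abs(
        x[np.abs(x) < depletion_width]) / depletion_width
    shape = trough + wave
    for p in manifest.planted_itrs:
        mid = (p.start + p.end) // 2
        lo = max(0, mid - phase_extent)
        hi = min(L, mid + phase_extent + 1)
        cov[lo:hi] += shape[lo - (mid - phase_extent):
                            hi - (mid - phase_extent)]
    return coverage_to_bedgraph(np.maximum(cov, 0.0), manifest.chrom)


def coverage_to_bedgraph(cov: np.ndarray, chrom: str) -> pd.DataFrame:
    """Run-length encode a per-bp coverage vector as a bedGraph frame."""
    change = np.flatnonzero(np.diff(cov)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(cov)]])
    return pd.DataFrame({
        "chrom": chrom, "start": starts.astype(np.int64),
        "end": ends.astype(np.int64), "value": cov[starts],
    })


def simulate_de(manifest: SimulationManifest, seed: int = 0,
                config: Optional[SimulationConfig] = None,
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired DE tables (conditions A and B) with planted structure.

    The gene universe extends the manifest's physical genes with virtual
    ITR-less genes up to ``n_de_genes``; a configured fraction of the
    padding is flagged ITR-containing so the universe-level ITR share is
    realistic. Up-calls in condition A are drawn by weighted sampling
    without replacement, ITR genes weighted ``itr_odds_ratio``; condition
    B shares ``n_shared`` of A's DE genes, each flipping direction with
    probability ``opposite_frac``, plus exclusive DE genes of its own.
    padj is assigned consistently (<=0.05 iff called), not fitted: the DE
    model itself is out of scope.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    physical = [g.gene_id for g in manifest.gene_models]
    has_itr = {g: (g in set(manifest.itr_gene_ids)) for g in physical}
    n_pad = cfg.n_de_genes - len(physical)
    if n_pad < 0:
        raise ValueError("n_de_genes smaller than the physical gene count")
    target_k = int(round(cfg.itr_gene_frac * cfg.n_de_genes))
    pad_itr = max(0, target_k - sum(has_itr.values()))
    pad_ids = [f"v{i:05d}" for i in range(n_pad)]
    pad_flag = np.zeros(n_pad, dtype=bool)
    if n_pad:
        pad_flag[rng.choice(n_pad, size=min(pad_itr, n_pad), replace=False)] = True
    for gid, fl in zip(pad_ids, pad_flag):
        has_itr[gid] = bool(fl)
    universe = physical + pad_ids
    itr_mask = np.array([has_itr[g] for g in universe])

    weights = np.where(itr_mask, cfg.itr_odds_ratio, 1.0)
    n_up, n_down = cfg.n_up_a, cfg.n_down_a
    up_idx = rng.choice(len(universe), size=n_up, replace=False,
                        p=weights / weights.sum())
    remaining = np.setdiff1d(np.arange(len(universe)), up_idx)
    down_idx = rng.choice(remaining, size=n_down, replace=False)

    call_a = np.full(len(universe), "ns", dtype=object)
    call_a[up_idx] = "up"
    call_a[down_idx] = "down"

    de_a_idx = np.concatenate([up_idx, down_idx])
    n_shared = min(cfg.n_shared, len(de_a_idx))
    shared_idx = rng.choice(de_a_idx, size=n_shared, replace=False)
    call_b = np.full(len(universe), "ns", dtype=object)
    for i in shared_idx:
        flip = rng.random() < cfg.opposite_frac
        if call_a[i] == "up":
            call_b[i] = "down" if flip else "up"
        else:
            call_b[i] = "up" if flip else "down"
    pool_b = np.setdiff1d(np.arange(len(universe)), de_a_idx)
    excl_idx = rng.choice(pool_b, size=min(cfg.n_b_exclusive, len(pool_b)),
                          replace=False)
    for i in excl_idx:
        call_b[i] = "down" if rng.random() < cfg.b_down_frac else "up"

    def _table(calls: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        n = len(universe)
        base_mean = np.exp(rng.normal(4.0, 1.5, size=n))
        l2fc = rng.normal(0, 0.45, size=n).clip(-0.99, 0.99)
        padj = rng.uniform(0.06, 1.0, size=n)
        called = calls != "ns"
        mag = 1.0 + rng.exponential(0.8, size=n)
        sign = np.where(calls == "up", 1.0, -1.0)
        l2fc = np.where(called, sign * mag, l2fc)
        padj = np.where(called, rng.uniform(1e-8, 0.05, size=n), padj)
        return pd.DataFrame({
            "gene_id": universe, "baseMean": base_mean,
            "log2FoldChange": l2fc, "padj": padj,
        })

    de_a = _table(call_a, rng)
    de_b = _table(call_b, rng)
    k_up = int(np.sum(itr_mask[up_idx]))
    truth = {
        "N": len(universe), "K": int(itr_mask.sum()),
        "n": int(n_up), "k": k_up,
        "call_a": dict(zip(universe, call_a)),
        "call_b": dict(zip(universe, call_b)),
        "n_shared": int(n_shared),
        "n_opposite_true": int(sum(
            1 for i in shared_idx if call_a[i] != call_b[i])),
    }
    manifest.de_truth = pd.DataFrame({
        "gene_id": universe, "has_itr": itr_mask,
        "call_a": call_a, "call_b": call_b,
    })
    manifest.enrichment_truth = {k: truth[k] for k in ("N", "K", "n", "k")}
    return de_a, de_b, truth


def simulate_counts(manifest: SimulationManifest, seed: int = 0,
                    mean_fragments: float = 200.0) -> pd.DataFrame:
    """Gene-level fragment counts for the physical genes (for FPKM)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in manifest.gene_models:
        lam = mean_fragments * g.exon_length / 1000.0
        rows.append((g.gene_id, int(rng.poisson(lam))))
    return pd.DataFrame(rows, columns=["gene_id", "fragments"])


def write_simulation(outdir: str | Path, genome: dict[str, str],
                     manifest: SimulationManifest,
                     chip: Optional[dict] = None,
                     de_a: Optional[pd.DataFrame] = None,
                     de_b: Optional[pd.DataFrame] = None,
                     counts: Optional[pd.DataFrame] = None,
                     nucleosome: Optional[pd.DataFrame] = None) -> dict[str, Path]:
    """Write all generated artefacts (FASTA/BED/GFF3/bedGraph/TSV/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["consensus"] = outdir / "consensus.fa"
    write_fasta({"consensus_itr": manifest.consensus}, paths["consensus"])
    paths["genes"] = outdir / "genes.gff3"
    write_gff3(manifest.gene_models, paths["genes"])
    paths["planted"] = outdir / "planted_itrs.bed"
    write_bed(manifest.itr_intervals(), paths["planted"])
    paths["manifest"] = outdir / "manifest.json"
    manifest.to_json(paths["manifest"])
    if chip is not None:
        paths["peaks"] = outdir / "peaks.bed"
        write_bed(chip["peaks"], paths["peaks"])
        if "ip_track" in chip:
            paths["ip"] = outdir / "ip.bedgraph"
            write_bedgraph(chip["ip_track"], paths["ip"])
            paths["input"] = outdir / "input.bedgraph"
            write_bedgraph(chip["input_track"], paths["input"])
    if de_a is not None:
        paths["de_smf"] = outdir / "de_smf.tsv"
        write_tsv(de_a, paths["de_smf"])
    if de_b is not None:
        paths["de_smfn"] = outdir / "de_smfn.tsv"
        write_tsv(de_b, paths["de_smfn"])
    if counts is not None:
        paths["counts"] = outdir / "counts.tsv"
        write_tsv(counts, paths["counts"])
    if nucleosome is not None:
        paths["nucleosome"] = outdir / "nucleosome.bedgraph"
        write_bedgraph(nucleosome, paths["nucleosome"])
    return paths
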