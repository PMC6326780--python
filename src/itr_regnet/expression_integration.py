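"""Differential-expression thresholds, FPKM, expression bins and concordance.

DE model fitting is consumed, not performed: tables arrive with a mean
expression, a log2 fold-change and an adjusted P per gene. Calls use a
strict two-fold cutoff (|FC| must exceed 2) with padj <= 0.05 inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chip_integration import GeneChipClass
from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    PipelineConfig,
    intersect_features,
)

DE_COLUMNS = ["gene_id", "baseMean", "log2FoldChange", "padj"]


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result and its call."""

    gene_id: str
    mean_expr: float
    log2fc: float
    padj: Optional[float]
    call: str  # up | down | ns


@dataclass
class GeneIntegrationRecord:
    """One gene's ITR status, binding class and DE calls, joined."""

    gene_id: str
    has_itr: bool
    near_itr_10kb: bool
    chip_class: str
    call_smf: str
    call_smfn: str
    fpkm: float = float("nan")

    def __post_init__(self) -> None:
        if self.has_itr and self.near_itr_10kb:
            raise ValueError("has_itr and near_itr_10kb are mutually exclusive")


def _call(log2fc: float, padj: Optional[float],
          config: PipelineConfig) -> str:
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return "ns"
    if padj > config.padj_threshold:
        return "ns"
    cut = math.log2(config.fc_threshold)
    if log2fc > cut:
        return "up"
    if log2fc < -cut:
        return "down"
    return "ns"


def apply_de_thresholds(table: pd.DataFrame | str | Path,
                        config: Optional[PipelineConfig] = None,
                        ) -> list[DERecord]:
    """Classify every table row as up / down / ns.

    Fold-change cutoff is strict (|FC| must exceed the threshold; FC
    exactly 2 is ns) and the adjusted-P cutoff is inclusive. Missing padj
    means ns, matching independent-filtering NAs from DE fitters.
    """
    config = config or PipelineConfig()
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in table.columns and c != "padj"]
    if missing:
        raise ValueError(f"missing DE table columns: {missing}")
    out = []
    for idx, row in table.iterrows():
        try:
            l2fc = float(row["log2FoldChange"])
            mean = float(row["baseMean"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric field in DE table row {idx}") from exc
        padj = row.get("padj", np.nan)
        try:
            padj = None if pd.isna(padj) else float(padj)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric padj in DE table row {idx}") from exc
        out.append(DERecord(gene_id=str(row["gene_id"]), mean_expr=mean,
                            log2fc=l2fc, padj=padj,
                            call=_call(l2fc, padj, config)))
    return out


def de_call_counts(records: Sequence[DERecord]) -> dict[str, int]:
    counts = {"up": 0, "down": 0, "ns": 0}
    for r in records:
        counts[r.call] += 1
    return counts


def compute_fpkm(counts: Mapping[str, int] | pd.DataFrame | str | Path,
                 genes: Sequence[GeneModel]) -> dict[str, float]:
    """FPKM per gene: fragments x 1e9 / (total fragments x union exon bp)."""
    if isinstance(counts, (str, Path)):
        counts = pd.read_csv(counts, sep="\t")
    if isinstance(counts, pd.DataFrame):
        counts = dict(zip(counts.iloc[:, 0].astype(str), counts.iloc[:, 1]))
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("total fragment count must be positive")
    lengths = {g.gene_id: g.exon_length for g in genes}
    out = {}
    for gid, c in counts.items():
        if gid not in lengths:
            continue
        if lengths[gid] == 0:
            raise ValueError(f"gene {gid} has zero exon length")
        out[gid] = float(c) * 1e9 / (total * lengths[gid])
    return out


def expression_bins(fpkm: Mapping[str, float], edges: Sequence[float],
                    gene_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-bin gene fractions for named gene sets.

    Bins are half-open ``[e_i, e_{i+1})`` with an implicit first bin
    ``[0, e_1)`` and a final open-ended bin ``[e_last, inf)``. Fractions
    per set sum to 1; an empty set yields a zero row.
    """
    edges = list(edges)
    if edges != sorted(edges):
        raise ValueError("edges must be ascending")
    full_edges = [0.0] + edges + [np.inf]
    labels = [f"[{full_edges[i]:g},{full_edges[i+1]:g})"
              for i in range(len(full_edges) - 1)]
    rows = {}
    for set_name, gids in gene_sets.items():
        vals = []
        for gid in gids:
            if gid in fpkm:
                v = fpkm[gid]
                if v < 0:
                    raise ValueError(f"negative FPKM for {gid}")
                vals.append(v)
        hist = np.zeros(len(labels))
        if vals:
            idx = np.searchsorted(full_edges, vals, side="right") - 1
            for i in idx:
                hist[i] += 1
            hist /= len(vals)
        rows[set_name] = hist
    return pd.DataFrame(rows, index=labels).T


def direction_concordance(de_a: Sequence[DERecord],
                          de_b: Sequence[DERecord]) -> dict:
    """Cross-condition overlap of DE calls and direction agreement.

    Returns the shared-DE count, how many flipped direction, and per
    direction in A how many respond the same way in B (the paper-style
    "only N up-in-both" statistic), plus Venn-style exclusive counts.
    """
    def calls(records):
        m = {}
        for r in records:
            if r.gene_id in m:
                raise ValueError(f"duplicate gene_id {r.gene_id}")
            m[r.gene_id] = r.call
        return m

    a, b = calls(de_a), calls(de_b)
    de_in_a = {g for g, c in a.items() if c != "ns"}
    de_in_b = {g for g, c in b.items() if c != "ns"}
    both = de_in_a & de_in_b
    opposite = {g for g in both if a[g] != b[g]}
    same = both - opposite
    return {
        "n_de_a": len(de_in_a),
        "n_de_b": len(de_in_b),
        "n_both": len(both),
        "n_opposite": len(opposite),
        "n_same": len(same),
        "n_a_only": len(de_in_a - de_in_b),
        "n_b_only": len(de_in_b - de_in_a),
        "up_a_same_in_b": sum(1 for g in same if a[g] == "up"),
        "down_a_same_in_b": sum(1 for g in same if a[g] == "down"),
    }


def build_integration_records(genes: Sequence[GeneModel],
                              itrs: Sequence,
                              chip_classes: Sequence[GeneChipClass],
                              de_smf: Sequence[DERecord],
                              de_smfn: Sequence[DERecord],
                              fpkm: Optional[Mapping[str, float]] = None,
                              config: Optional[PipelineConfig] = None,
                              ) -> list[GeneIntegrationRecord]:
    """Join ITR containment, neighbourhood, binding class and DE calls.

    ``has_itr`` means an ITR overlaps the gene span; ``near_itr_10kb``
    marks ITR-less genes whose span edge lies within the neighbourhood
    radius of an ITR. Genes absent from a DE table are ns.
    """
    config = config or PipelineConfig()
    itr_loci = [h.locus if hasattr(h, "locus") else h for h in itrs]
    spans = [g.gene for g in genes]
    pairings = intersect_features(spans, itr_loci,
                                  max_gap=config.itr_neighborhood)
    chip_of = {c.gene_id: c.chip_class for c in chip_classes}
    smf = {r.gene_id: r.call for r in de_smf}
    smfn = {r.gene_id: r.call for r in de_smfn}
    fpkm = fpkm or {}
    out = []
    for g, pairing in zip(genes, pairings):
        has_itr = pairing.distance is not None and pairing.distance == 0
        near = (not has_itr) and pairing.within_max_gap
        out.append(GeneIntegrationRecord(
            gene_id=g.gene_id, has_itr=has_itr, near_itr_10kb=near,
            chip_class=chip_of.get(g.gene_id, "no_peak"),
            call_smf=smf.get(g.gene_id, "ns"),
            call_smfn=smfn.get(g.gene_id, "ns"),
            fpkm=float(fpkm.get(g.gene_id, float("nan")))))
    return out


def de_fraction_among_class(records: Sequence[GeneIntegrationRecord],
                            chip_class: str = "bound_itr",
                            condition: str = "call_smf",
                            biotypes: Optional[Sequence[str]] = None,
                            chip_classes: Optional[Sequence[GeneChipClass]] = None,
                            ) -> dict:
    """Share of genes of a binding class that are differentially expressed.

    Returns counts and the integer percentage (e.g. 50 DE of 97 bound
    protein-coding genes -> 52).
    """
    if biotypes is not None and chip_classes is not None:
        keep_ids = {c.gene_id for c in chip_classes if c.biotype in biotypes}
        records = [r for r in records if r.gene_id in keep_ids]
    subset = [r for r in records if r.chip_class == chip_class]
    n_de = sum(1 for r in subset if getattr(r, condition) != "ns")
    pct = int(round(100 * n_de / len(subset))) if subset else 0
    return {"n_class": len(subset), "n_de": n_de, "percent_de": pct}


def de_percentage(n_de: int, n_total: int) -> int:
    """Integer percentage of DE genes in a subgroup (52 for 50 of 97)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round(100 * n_de / n_total))
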