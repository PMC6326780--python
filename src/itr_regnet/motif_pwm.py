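"""Position weight matrices: construction from aligned sites and log-odds scanning.

A verifiable stand-in for de novo motif discovery over ChIP-bound sites:
the PWM is built from peak-centred sequences aligned to the consensus hit,
and scanned with standard log2-odds scoring against a background model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass
class Pwm:
    """A position weight matrix over A/C/G/T.

    ``counts`` has shape (width, 4) in base order A, C, G, T. Probabilities
    include the pseudocount: p(b, i) = (count + pc) / (n + 4 pc).
    """

    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        if self.width < 4:
            raise ValueError("width must be >= 4")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return int(round(self.counts[0].sum()))

    @property
    def probabilities(self) -> np.ndarray:
        n = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + self.pseudocount) / (n + 4 * self.pseudocount)

    @property
    def information_content(self) -> np.ndarray:
        """Per-position information content in bits: 2 + sum p log2 p."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))


def build_pwm(sites: Sequence[str], pseudocount: float = 0.25,
              background: Optional[Sequence[float]] = None) -> Pwm:
    """Build a PWM from >=2 equal-length A/C/G/T sequences."""
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    width = len(sites[0])
    counts = np.zeros((width, 4))
    for s in sites:
        s = s.upper()
        if len(s) != width:
            raise ValueError(f"ragged site lengths: {len(s)} vs {width}")
        for i, b in enumerate(s):
            if b not in _IDX:
                raise ValueError(f"non-ACGT base {b!r} in site")
            counts[i, _IDX[b]] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return Pwm(counts=counts, pseudocount=pseudocount, background=bg)


def _score_forward(seq_codes: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Log-odds score at every valid offset; N positions score -inf."""
    w = lod.shape[0]
    n = len(seq_codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(w):
        col = seq_codes[i:i + n]
        valid = col < 4
        contrib = np.where(valid, lod[i][np.clip(col, 0, 3)], -np.inf)
        scores = scores + contrib
    return scores


def pwm_scan(seq: str, pwm: Pwm, threshold: float) -> list[tuple[int, str, float]]:
    """Scan both strands; return (offset, strand, score) with score >= threshold.

    Offsets are 0-based positions of the motif window on the forward
    sequence for both strands; results sorted by offset then strand.
    """
    if not np.isfinite(threshold):
        if threshold == np.inf:
            return []
        raise ValueError("threshold must be finite or +inf")
    seq = seq.upper()
    if len(seq) < pwm.width:
        return []
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _IDX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    lod = pwm.log_odds
    hits = []
    fwd = _score_forward(codes, lod)
    for off in np.flatnonzero(fwd >= threshold):
        hits.append((int(off), "+", float(fwd[off])))
    # reverse strand: score of revcomp(window) == score of window against
    # the reverse-complemented matrix
    lod_rc = lod[::-1, ::-1]
    rev = _score_forward(codes, lod_rc)
    for off in np.flatnonzero(rev >= threshold):
        hits.append((int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def extract_site_sequences(genome: dict[str, str], loci, width: int,
                           ) -> list[str]:
    """Centre-aligned fixed-width sequences at loci, minus strand revcomped."""
    out = []
    for iv in loci:
        seq = genome[iv.chrom]
        mid = iv.midpoint
        lo = mid - width // 2
        hi = lo + width
        if lo < 0 or hi > len(seq):
            continue
        s = seq[lo:hi]
        if iv.strand == "-":
            s = str(Seq(s).reverse_complement())
        if set(s) <= set(BASES):
            out.append(s)
    return out


def write_meme(pwm: Pwm, path: str | Path, name: str = "motif_1") -> None:
    """Serialize as MEME minimal motif format."""
    p = pwm.probabilities
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*pwm.background))
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.n_sites} E= 0\n"
        )
        for row in p:
            fh.write(" {:.6f} {:.6f} {:.6f} {:.6f}\n".format(*row))


def read_meme(path: str | Path) -> Pwm:
    """Read the first motif of a MEME minimal file back as a probability PWM.

    Probabilities are rescaled to pseudo-counts using the recorded nsites;
    a zero pseudocount keeps them bit-comparable to the written matrix.
    """
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    nsites = 1
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    in_matrix = False
    for line in lines:
        line = line.strip()
        if line.startswith("Background letter"):
            continue
        if line.startswith("A ") and "C" in line and not in_matrix:
            parts = line.split()
            background = np.array([float(parts[i]) for i in (1, 3, 5, 7)])
        elif line.startswith("letter-probability"):
            in_matrix = True
            toks = line.replace("=", " = ").split()
            if "nsites" in toks:
                nsites = int(toks[toks.index("nsites") + 2])
        elif in_matrix:
            if not line or line.startswith("MOTIF"):
                break
            rows.append([float(x) for x in line.split()])
    counts = np.array(rows) * nsites
    return Pwm(counts=counts, pseudocount=0.0, background=background)
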