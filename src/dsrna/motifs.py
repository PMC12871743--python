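"""Cis-motif scanning, promoter-region extraction, enrichment, TSS mapping.

Meiotic transcription factors activate antisense transcription through DNA
elements located past the 3′ end of gene loci: the Ume6p-bound URS1 element
(consensus TCGGCGGCTA, early meiosis) and the Ndt80p-bound middle
sporulation element MSE (consensus GNCRCAAAW, mid meiosis).  This module
scans strand-aware promoter regions with position weight matrices, tests
known-motif enrichment of a foreground region set against a background set
(hypergeometric), clusters strand-tagged read 5′ ends into transcription
initiation sites, and links motifs to antisense TSSs that initiate within a
bounded distance downstream of the motif in the antisense direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

URS1_CONSENSUS = "TCGGCGGCTA"
MSE_CONSENSUS = "GNCRCAAAW"

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
# full IUPAC complement so degenerate consensus strings reverse correctly
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv", "TGCANYRSWMKVHDBtgcanyrswmkvhdb"
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in 0-based half-open genomic coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: need 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PositionWeightMatrix:
    """Column-stochastic 4×W probability matrix over A,C,G,T."""

    matrix_id: str
    probs: np.ndarray
    source: str = "pfm_file"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM must be a 4×W matrix (rows A,C,G,T)")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be strictly positive")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2(p/background) per base and column; uniform background by
        default (synthetic genomes are uniform)."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return np.log2(self.probs / bg[:, None])

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=0).sum())


def consensus_to_pwm(iupac: str, eps: float = 0.01) -> PositionWeightMatrix:
    """PWM from an IUPAC consensus string.

    Each column spreads 1 − (4−k)·eps equally over its k allowed bases and
    gives eps to each disallowed base (N → uniform).
    """
    if not 0 < eps < 0.25:
        raise ValueError("eps must be in (0, 0.25)")
    iupac = iupac.upper()
    cols = []
    for ch in iupac:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in {iupac!r}")
        allowed = IUPAC[ch]
        k = len(allowed)
        col = np.full(4, eps)
        col[[BASE_INDEX[b] for b in allowed]] = (1.0 - (4 - k) * eps) / k
        cols.append(col)
    return PositionWeightMatrix(
        matrix_id=iupac, probs=np.column_stack(cols), source="iupac_consensus"
    )


@dataclass(frozen=True)
class MotifHit:
    """One PWM match; coordinates are on the forward strand of the scanned
    sequence (genomic once mapped through a Region)."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float  # log-odds, bits
    score_fraction: float
    pwm_id: str = ""


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    out = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def scan_pwm(
    sequence: str,
    pwm: PositionWeightMatrix,
    min_score_fraction: float = 0.85,
    strands: str = "both",
    background: np.ndarray | None = None,
    chrom: str = "",
) -> list[MotifHit]:
    """Score every window of ``sequence`` with the PWM log-odds.

    N bases contribute 0 bits (neutral under a uniform background).  Hits
    with score_fraction >= ``min_score_fraction`` are returned sorted by
    coordinate; minus-strand windows are scored on the reverse complement
    with coordinates reported on the forward strand.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError("strands must be '+', '-' or 'both'")
    W = pwm.width
    L = len(sequence)
    if L < W:
        return []
    lodds = pwm.log_odds(background)
    lut = np.vstack([lodds, np.zeros((1, W))])  # row 4: N → 0 bits
    smax = pwm.max_score(background)

    hits: list[MotifHit] = []

    def _scan_one(seq: str, strand: str) -> None:
        codes = _encode(seq)
        n_win = L - W + 1
        scores = np.zeros(n_win)
        for j in range(W):
            scores += lut[codes[j : j + n_win], j]
        frac = scores / smax
        for p in np.nonzero(frac >= min_score_fraction)[0]:
            p = int(p)
            if strand == "+":
                start = p
            else:
                start = L - p - W
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=start,
                    end=start + W,
                    strand=strand,
                    score=float(scores[p]),
                    score_fraction=float(frac[p]),
                    pwm_id=pwm.matrix_id,
                )
            )

    if strands in ("+", "both"):
        _scan_one(sequence, "+")
    if strands in ("-", "both"):
        _scan_one(reverse_complement(sequence), "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class Region:
    """A strand-aware extracted genomic region.

    ``seq`` reads 5′→3′ along the region's own orientation: for a + gene's
    downstream region that is the forward genome strand; for a − gene it is
    the reverse complement of the genomic slice.
    """

    name: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    orientation: str  # "+": seq is forward genome; "-": seq is revcomp
    seq: str
    truncated: bool = False

    def hit_to_genomic(self, hit: MotifHit) -> MotifHit:
        """Map a region-local hit back to genomic coordinates/strand."""
        W = hit.end - hit.start
        if self.orientation == "+":
            gstart = self.start + hit.start
            gstrand = hit.strand
        else:
            gstart = self.end - hit.end
            gstrand = "-" if hit.strand == "+" else "+"
        return MotifHit(
            chrom=self.chrom,
            start=gstart,
            end=gstart + W,
            strand=gstrand,
            score=hit.score,
            score_fraction=hit.score_fraction,
            pwm_id=hit.pwm_id,
        )


def _extract(
    gene: GeneModel, genome: dict[str, str], gstart: int, gend: int, name: str
) -> Region:
    if gene.chrom not in genome:
        raise KeyError(f"{gene.gene_id}: chromosome {gene.chrom!r} not in genome")
    chrom_seq = genome[gene.chrom]
    L = len(chrom_seq)
    if gene.end > L:
        raise ValueError(f"{gene.gene_id}: gene beyond chromosome bounds")
    cstart, cend = max(0, gstart), min(L, gend)
    truncated = (cstart != gstart) or (cend != gend)
    seq = chrom_seq[cstart:cend]
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return Region(
        name=name,
        chrom=gene.chrom,
        start=cstart,
        end=cend,
        orientation=gene.strand,
        seq=seq,
        truncated=truncated,
    )


def extract_downstream_regions(
    genes: list[GeneModel], genome: dict[str, str], length: int = 1000
) -> dict[str, Region]:
    """Strand-aware regions past each gene's 3′ end (antisense promoters).

    + gene → genomic [end, end+length) forward; − gene → [start−length,
    start) reverse-complemented.  Regions hitting a chromosome edge are
    truncated and flagged.
    """
    out = {}
    for g in genes:
        if g.strand == "+":
            out[g.gene_id] = _extract(g, genome, g.end, g.end + length, g.gene_id)
        else:
            out[g.gene_id] = _extract(g, genome, g.start - length, g.start, g.gene_id)
    return out


def extract_upstream_regions(
    genes: list[GeneModel], genome: dict[str, str], length: int = 1000
) -> dict[str, Region]:
    """Strand-aware regions 5′ of each gene (sense promoters)."""
    out = {}
    for g in genes:
        if g.strand == "+":
            out[g.gene_id] = _extract(g, genome, g.start - length, g.start, g.gene_id)
        else:
            out[g.gene_id] = _extract(g, genome, g.end, g.end + length, g.gene_id)
    return out


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    fg_positive: int
    fg_total: int
    bg_positive: int
    bg_total: int


def motif_enrichment(
    foreground: list[Region],
    background: list[Region],
    pwm: PositionWeightMatrix,
    min_score_fraction: float = 0.85,
    bg_model: np.ndarray | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of motif-positive regions in the foreground.

    A region is positive if it carries >= 1 hit on either strand.  The
    p-value is the one-sided hypergeometric upper tail for the number of
    foreground positives; the odds ratio is Haldane-corrected (+0.5 per
    cell) when any cell is zero.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must both be non-empty")

    def positive(r: Region) -> bool:
        return bool(
            scan_pwm(r.seq, pwm, min_score_fraction, strands="both", background=bg_model)
        )

    a = sum(positive(r) for r in foreground)  # fg positive
    b = len(foreground) - a
    c = sum(positive(r) for r in background)  # bg positive
    d = len(background) - c
    M, n_success, N = a + b + c + d, a + c, a + b
    p = float(stats.hypergeom.sf(a - 1, M, n_success, N))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    logger.info(
        "motif %s enrichment: fg %d/%d, bg %d/%d, OR=%.3g, p=%.3g",
        pwm.matrix_id, a, len(foreground), c, len(background), odds, p,
    )
    return EnrichmentResult(float(odds), p, a, len(foreground), c, len(background))


@dataclass(frozen=True)
class FivePrimeEnd:
    chrom: str
    position: int
    strand: str
    count: int = 1


@dataclass(frozen=True)
class TssCluster:
    """A strand-specific transcription-initiation cluster of read 5′ ends."""

    chrom: str
    position: int  # representative (modal) coordinate
    strand: str
    read_count: int
    window_start: int
    window_end: int


def call_tss_clusters(
    ends: list[FivePrimeEnd],
    min_count: int = 3,
    merge_window: int = 10,
) -> list[TssCluster]:
    """Merge same-strand 5′ ends within ``merge_window`` into clusters.

    The representative is the modal position; ties break toward the 5′-most
    position in the transcription direction (smallest coordinate on +,
    largest on −).  Clusters with summed count below ``min_count`` are
    dropped.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    by_key: dict[tuple[str, str], dict[int, int]] = {}
    for e in ends:
        if e.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {e.strand!r}")
        by_key.setdefault((e.chrom, e.strand), {}).setdefault(e.position, 0)
        by_key[(e.chrom, e.strand)][e.position] += e.count

    clusters: list[TssCluster] = []
    for (chrom, strand), counts in sorted(by_key.items()):
        positions = sorted(counts)
        group: list[int] = []
        for pos in positions + [None]:  # sentinel flushes the last group
            if group and (pos is None or pos - group[-1] > merge_window):
                total = sum(counts[p] for p in group)
                if total >= min_count:
                    best = max(counts[p] for p in group)
                    modal = [p for p in group if counts[p] == best]
                    rep = min(modal) if strand == "+" else max(modal)
                    clusters.append(
                        TssCluster(chrom, rep, strand, total, group[0], group[-1] + 1)
                    )
                group = []
            if pos is not None:
                group.append(pos)
    clusters.sort(key=lambda c: (c.chrom, c.position, c.strand))
    return clusters


@dataclass(frozen=True)
class MotifTssLink:
    """A motif whose downstream edge (in the antisense direction) lies
    within ``max_distance`` upstream of an opposite-strand TSS."""

    gene_id: str
    motif: MotifHit
    tss: TssCluster
    offset: int  # distance motif edge → TSS along the NAT direction


@dataclass
class LinkReport:
    links: list[MotifTssLink] = field(default_factory=list)
    n_genes: int = 0
    n_linked_genes: int = 0

    @property
    def linked_fraction(self) -> float:
        return self.n_linked_genes / self.n_genes if self.n_genes else float("nan")


def link_motifs_to_tss(
    genes: list[GeneModel],
    motif_hits: dict[str, list[MotifHit]],
    tss_clusters: list[TssCluster],
    max_distance: int = 100,
) -> LinkReport:
    """Link genomic motif hits to antisense TSS clusters.

    Antisense transcription of a + gene runs on the − strand toward lower
    coordinates; its offset to a motif is motif_start − tss_position.  For a
    − gene (antisense on +) it is tss_position − motif_end + 1.  A link is
    kept when 0 <= offset <= ``max_distance`` and the TSS strand is opposite
    the gene strand.
    """
    report = LinkReport(n_genes=len(genes))
    by_chrom_strand: dict[tuple[str, str], list[TssCluster]] = {}
    for c in tss_clusters:
        by_chrom_strand.setdefault((c.chrom, c.strand), []).append(c)

    for gene in genes:
        nat_strand = "-" if gene.strand == "+" else "+"
        candidates = by_chrom_strand.get((gene.chrom, nat_strand), [])
        linked = False
        for hit in motif_hits.get(gene.gene_id, []):
            for tss in candidates:
                if gene.strand == "+":
                    offset = hit.start - tss.position
                else:
                    offset = tss.position - hit.end + 1
                if 0 <= offset <= max_distance:
                    report.links.append(MotifTssLink(gene.gene_id, hit, tss, offset))
                    linked = True
        if linked:
            report.n_linked_genes += 1
    logger.info(
        "motif→TSS linking: %d genes in, %d linked (%d links)",
        report.n_genes, report.n_linked_genes, len(report.links),
    )
    return report
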