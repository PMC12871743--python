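"""Pulsed sense-expression detection and convergent-promoter annotation.

Genes whose sense mRNAs are cleared by antisense-driven dsRNA formation
show pulsed abundance: a rapid rise to a peak in the pre-meiotic→prophase I
window followed by an equally rapid fall, visible as a z-scored trajectory
with both a rise and a fall of at least δ z-units around the peak.  At such
loci, mRNA decline is concurrent (same or adjacent stage interval) with the
initial rise in antisense ratio, and the locus architecture often carries a
pair of sequentially convergent promoters: an early-acting URS1 element in
the sense promoter (1 kb upstream) and a mid-meiotic MSE in the antisense
promoter (1 kb downstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .antisense import assign_activation
from .motifs import (
    GeneModel,
    MotifHit,
    PositionWeightMatrix,
    extract_downstream_regions,
    extract_upstream_regions,
    scan_pwm,
)
from .stages import StageSeries

logger = logging.getLogger(__name__)


def zscore_rows(
    matrix: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Row-wise z-scores over defined stages (population sd, divisor n).

    Returns (z matrix, kept gene ids, dropped gene ids); rows with fewer
    than 2 defined stages or zero variance are dropped with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    keep_rows, kept, dropped = [], [], []
    for i, gid in enumerate(gene_ids):
        vals = matrix[i][~np.isnan(matrix[i])]
        if vals.size >= 2 and np.ptp(vals) > 0:
            keep_rows.append(i)
            kept.append(gid)
        else:
            dropped.append(gid)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} zero-variance/undercovered rows before z-scoring",
            stacklevel=2,
        )
    sub = matrix[keep_rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, keepdims=True)  # population sd
    return (sub - mean) / sd, kept, dropped


@dataclass
class PulseCall:
    gene_id: str
    pulsed: bool
    peak_stage: str | None
    rise: float
    fall: float
    window: tuple[str, str]


def detect_pulse(
    gene_id: str,
    z: np.ndarray,
    stages: StageSeries,
    window: tuple[str, str] = ("P", "T1"),
    delta: float = 1.0,
) -> PulseCall:
    """Pulse rule on a z-scored trajectory.

    peak = argmax of z within the window; rise = peak − min(z) over stages
    from the series start through the peak; fall = peak − min(z) over
    stages after the peak through one stage past the window end.  Pulsed
    iff rise >= δ and fall >= δ.
    """
    z = np.asarray(z, dtype=float)
    lo, hi = stages.rank(window[0]), stages.rank(window[1])
    if lo > hi:
        raise ValueError(f"pulse window out of order: {window}")
    win = np.arange(lo, hi + 1)
    win_defined = win[~np.isnan(z[win])]
    if win_defined.size == 0:
        return PulseCall(gene_id, False, None, float("nan"), float("nan"), window)
    peak = int(win_defined[np.argmax(z[win_defined])])
    before = z[: peak + 1]
    after = z[peak + 1 : min(hi + 2, len(z)) ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rise = float(z[peak] - np.nanmin(before)) if np.any(~np.isnan(before)) else float("nan")
        fall = float(z[peak] - np.nanmin(after)) if after.size and np.any(~np.isnan(after)) else float("nan")
    pulsed = bool(
        np.isfinite(rise) and np.isfinite(fall) and rise >= delta and fall >= delta
    )
    return PulseCall(gene_id, pulsed, stages.labels[peak], rise, fall, window)


@dataclass
class ConcurrencyResult:
    gene_id: str
    decline_interval: tuple[str, str] | None
    activation_interval: tuple[str, str] | None
    concurrent: bool
    reason: str = ""


def sense_antisense_concurrency(
    gene_id: str,
    sense_tpm: np.ndarray,
    ratio: np.ndarray,
    stages: StageSeries,
    background: float = 0.15,
    margin: float = 0.05,
) -> ConcurrencyResult:
    """Is the sharpest mRNA decline concurrent with antisense activation?

    The decline interval is the consecutive-defined-stage pair with the
    largest TPM decrease; concurrency means the decline and activation
    intervals are identical or adjacent (they share or abut a stage).
    """
    sense_tpm = np.asarray(sense_tpm, dtype=float)
    defined = np.nonzero(~np.isnan(sense_tpm))[0]
    decline = None
    best = 0.0
    for a, b in zip(defined[:-1], defined[1:]):
        drop = sense_tpm[a] - sense_tpm[b]
        if drop > best:
            decline, best = (int(a), int(b)), float(drop)
    act = assign_activation(gene_id, ratio, stages, background, margin)
    if act.interval is None:
        return ConcurrencyResult(
            gene_id,
            (stages.labels[decline[0]], stages.labels[decline[1]]) if decline else None,
            None, False, reason="no antisense activation",
        )
    if decline is None:
        return ConcurrencyResult(gene_id, None, act.interval, False, reason="no decline")
    act_ranks = (stages.rank(act.interval[0]), stages.rank(act.interval[1]))
    # share a stage or abut: [a0,a1] and [d0,d1] intersect or touch
    concurrent = decline[0] <= act_ranks[1] and act_ranks[0] <= decline[1]
    return ConcurrencyResult(
        gene_id,
        (stages.labels[decline[0]], stages.labels[decline[1]]),
        act.interval,
        bool(concurrent),
    )


@dataclass
class ConvergentPromoterAnnotation:
    gene_id: str
    sense_promoter_motif: MotifHit | None  # URS1 class, 1 kb upstream
    antisense_promoter_motif: MotifHit | None  # MSE class, 1 kb downstream
    convergent: bool


def annotate_convergent_promoters(
    genes: list[GeneModel],
    genome: dict[str, str],
    urs1_pwm: PositionWeightMatrix,
    mse_pwm: PositionWeightMatrix,
    min_score_fraction: float = 0.95,
    region_length: int = 1000,
) -> list[ConvergentPromoterAnnotation]:
    """Scan each gene's sense promoter (1 kb upstream) for URS1 and its
    antisense promoter (1 kb downstream) for MSE; convergent iff both are
    found (best-scoring hit reported, either strand)."""
    upstream = extract_upstream_regions(genes, genome, region_length)
    downstream = extract_downstream_regions(genes, genome, region_length)
    out = []
    for g in genes:
        def best_hit(region, pwm):
            hits = scan_pwm(region.seq, pwm, min_score_fraction, strands="both")
            if not hits:
                return None
            local = max(hits, key=lambda h: (h.score, -h.start))
            return region.hit_to_genomic(local)

        up = best_hit(upstream[g.gene_id], urs1_pwm)
        down = best_hit(downstream[g.gene_id], mse_pwm)
        out.append(
            ConvergentPromoterAnnotation(g.gene_id, up, down, up is not None and down is not None)
        )
    n_conv = sum(a.convergent for a in out)
    logger.info("convergent-promoter annotation: %d genes, %d convergent", len(out), n_conv)
    return out
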