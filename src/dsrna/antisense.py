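"""Strand-specific antisense-transcript dynamics.

For each gene locus, reads are assigned per strand and normalized to TPM
(sense and antisense entries of a locus are separate terms in the per-stage
million).  The antisense read ratio at a stage is

    ratio = antisense_tpm / (sense_tpm + antisense_tpm)

with stages below a TPM floor (default 10, locus total) treated as missing.
Genes whose ratio changes by more than 20 percentage points across the
course, with at most one missing stage, are the "dynamic" set; each dynamic
gene's activation stage is the consecutive-defined-stage interval with the
largest ratio increase.  A gene is meiosis-specific when its pre-meiotic
ratios sit at the technical background (~15%, from undigested second-strand
cDNA) and the activation interval starts at the pre-meiotic stage or later.

Trajectories are clustered by centroid-linkage agglomeration on the
centered-Pearson distance (1 − r), with centroids recomputed as member mean
profiles over co-defined stages — the semantics of the classic Cluster 3.0
program, which can yield non-monotone merge heights; heights are reported
as computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import StrandedCounts
from .stages import StageSeries

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTracks:
    """Per-gene, per-stage TPM for both strands (NaN where unobserved)."""

    gene_ids: list[str]
    stages: StageSeries
    sense_tpm: np.ndarray
    antisense_tpm: np.ndarray
    observed: np.ndarray


def tpm_normalize(counts: StrandedCounts) -> AbundanceTracks:
    """TPM with sense and antisense as separate terms in the per-stage sum.

    rate = count / gene_length per (gene, strand, stage); tpm = rate /
    Σ(all rates at that stage) × 1e6, so per stage the sense+antisense TPM
    over all genes sums to one million.  Unobserved cells contribute
    nothing and come out NaN.  A stage with zero total signal is an error.
    """
    lens = counts.lengths[:, None].astype(float)
    sense_rate = np.where(counts.observed, counts.sense / lens, 0.0)
    anti_rate = np.where(counts.observed, counts.antisense / lens, 0.0)
    totals = sense_rate.sum(axis=0) + anti_rate.sum(axis=0)
    if np.any(totals == 0):
        bad = counts.stages.labels[int(np.argmax(totals == 0))]
        raise ValueError(f"stage {bad!r} has zero total signal; cannot normalize")
    sense_tpm = sense_rate / totals * 1e6
    anti_tpm = anti_rate / totals * 1e6
    sense_tpm[~counts.observed] = np.nan
    anti_tpm[~counts.observed] = np.nan
    return AbundanceTracks(
        counts.gene_ids, counts.stages, sense_tpm, anti_tpm, counts.observed
    )


@dataclass
class RatioTracks:
    """Antisense read ratio per gene per stage (NaN = missing)."""

    gene_ids: list[str]
    stages: StageSeries
    ratio: np.ndarray

    def max_change(self) -> np.ndarray:
        """Per gene: max defined ratio − min defined ratio (NaN if < 2)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmax(self.ratio, axis=1) - np.nanmin(self.ratio, axis=1)
        out[np.sum(~np.isnan(self.ratio), axis=1) < 2] = np.nan
        return out

    def n_missing(self) -> np.ndarray:
        return np.sum(np.isnan(self.ratio), axis=1)


def antisense_ratio(tracks: AbundanceTracks, tpm_floor: float = 10.0) -> RatioTracks:
    """Per-stage antisense ratio with the TPM floor applied to the locus
    total (sense + antisense); stages at or below the floor, or unobserved,
    are missing."""
    if tpm_floor < 0:
        raise ValueError("tpm_floor must be >= 0")
    total = tracks.sense_tpm + tracks.antisense_tpm
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, tracks.antisense_tpm / total, np.nan)
    ratio = np.where(np.isnan(total) | (total <= tpm_floor), np.nan, ratio)
    return RatioTracks(tracks.gene_ids, tracks.stages, ratio)


def select_dynamic_genes(
    tracks: RatioTracks, min_change: float = 0.20, max_missing: int = 1
) -> list[str]:
    """Genes with ratio change > ``min_change`` (absolute, in ratio units)
    and at most ``max_missing`` missing stages."""
    change = tracks.max_change()
    nmiss = tracks.n_missing()
    keep = (~np.isnan(change)) & (change > min_change) & (nmiss <= max_missing)
    selected = [g for g, k in zip(tracks.gene_ids, keep) if k]
    logger.info(
        "dynamic-gene filter: %d in, %d out (min_change=%g, max_missing=%d)",
        len(tracks.gene_ids), len(selected), min_change, max_missing,
    )
    return selected


@dataclass
class ActivationCall:
    gene_id: str
    interval: tuple[str, str] | None  # None: no increase anywhere
    magnitude: float
    meiosis_specific: bool


def assign_activation(
    gene_id: str,
    ratio: np.ndarray,
    stages: StageSeries,
    background: float = 0.15,
    margin: float = 0.05,
) -> ActivationCall:
    """Activation interval = consecutive defined-stage pair with the
    largest ratio increase (ties → earliest).  No interval is called when
    no increase is positive.  Meiosis-specific requires every defined V/P
    ratio at or below background+margin and an interval starting at P or
    later."""
    ratio = np.asarray(ratio, dtype=float)
    defined = np.nonzero(~np.isnan(ratio))[0]
    if defined.size < 2:
        return ActivationCall(gene_id, None, float("nan"), False)
    best_i, best_mag = None, 0.0
    for a, b in zip(defined[:-1], defined[1:]):
        inc = ratio[b] - ratio[a]
        if inc > best_mag:  # strict: ties keep the earliest interval
            best_i, best_mag = (int(a), int(b)), float(inc)
    if best_i is None:
        return ActivationCall(gene_id, None, 0.0, False)
    interval = (stages.labels[best_i[0]], stages.labels[best_i[1]])
    pre_ranks = [stages.rank("V"), stages.rank("P")] if "V" in stages and "P" in stages else []
    pre_ok = all(
        np.isnan(ratio[r]) or ratio[r] <= background + margin for r in pre_ranks
    )
    starts_late = "P" in stages and best_i[0] >= stages.rank("P")
    return ActivationCall(gene_id, interval, best_mag, bool(pre_ok and starts_late))


def background_subtract(ratio: np.ndarray, b: float) -> np.ndarray:
    """Optional correction for the stranded-library background floor:
    ratio' = max(0, (ratio − b) / (1 − b))."""
    if not 0 <= b < 1:
        raise ValueError("background must be in [0, 1)")
    return np.maximum(0.0, (ratio - b) / (1.0 - b))


# ---------------------------------------------------------------------------
# hierarchical clustering (centroid linkage, centered Pearson)

def _centered_pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 − Pearson r over co-defined entries; NaN if < 2 or zero variance."""
    keep = ~np.isnan(x) & ~np.isnan(y)
    if keep.sum() < 2:
        return float("nan")
    xv, yv = x[keep] - x[keep].mean(), y[keep] - y[keep].mean()
    den = np.sqrt((xv ** 2).sum() * (yv ** 2).sum())
    if den == 0:
        return float("nan")
    return float(1.0 - (xv * yv).sum() / den)


@dataclass
class ClusterResult:
    """Merge history plus leaf ids.

    ``merges`` rows are (new_node, left, right, height) with leaves 0..n−1
    and internal nodes n, n+1, ...; heights are the centroid distances as
    computed (centroid linkage may be non-monotone).
    """

    gene_ids: list[str]
    merges: list[tuple[int, int, int, float]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment after stopping ``n − k`` merges in."""
        n = len(self.gene_ids)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for new, left, right, _h in self.merges[: n - k]:
            members[new] = members.pop(left) + members.pop(right)
        labels: dict[str, int] = {}
        for cid, (node, mem) in enumerate(sorted(members.items())):
            for leaf in mem:
                labels[self.gene_ids[leaf]] = cid
        return labels


def hierarchical_cluster(
    matrix: np.ndarray,
    gene_ids: list[str],
) -> ClusterResult:
    """Agglomerate rows by centroid linkage on centered-Pearson distance.

    At each step the pair of clusters with the most-correlated centroids
    (member mean profiles over co-defined stages) merges; ties break toward
    the lexically smallest node pair.  Constant rows (zero variance over
    defined stages) are dropped with a warning before clustering.
    """
    matrix = np.asarray(matrix, dtype=float)
    keep, dropped = [], []
    for i, row in enumerate(matrix):
        vals = row[~np.isnan(row)]
        if vals.size >= 2 and np.ptp(vals) > 0:
            keep.append(i)
        else:
            dropped.append(gene_ids[i])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} constant/undercovered rows before clustering",
            stacklevel=2,
        )
    matrix = matrix[keep]
    kept_ids = [gene_ids[i] for i in keep]
    n = len(kept_ids)
    result = ClusterResult(gene_ids=kept_ids, dropped=dropped)
    if n < 2:
        return result

    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    def centroid(node: int) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(matrix[members[node]], axis=0)

    next_node = n
    while len(members) > 1:
        live = sorted(members)
        cents = {node: centroid(node) for node in live}
        best = None
        for ai, a in enumerate(live):
            for b in live[ai + 1 :]:
                d = _centered_pearson_distance(cents[a], cents[b])
                if np.isnan(d):
                    d = 2.0  # maximally dissimilar when incomparable
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        members[next_node] = members.pop(a) + members.pop(b)
        result.merges.append((next_node, a, b, float(d)))
        next_node += 1
    return result
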