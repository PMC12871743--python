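"""Structural-dynamics statistics from time-resolved chemical probing.

DMS probing reports per-nucleotide accessibility (reactivity): paired or
protected bases react less.  Comparing reactivity profiles of the same
transcript between two stages therefore reports structural remodeling:

* The Pearson correlation ``r`` of the two profiles measures overall
  structural similarity; for each transcript the minimum ``r`` over all
  stage pairs marks the stage pair with the greatest structural change.
* The per-nucleotide difference ΔDMS = reactivity(early) − reactivity(late)
  is positive where reactivity was lost over time.  Ordinary intramolecular
  refolding moves reactivity in both directions, so the transcript-level
  median ΔDMS stays near 0; formation of an intermolecular duplex (e.g. a
  sense mRNA base-paired with its natural antisense transcript) suppresses
  reactivity across the whole molecule and pushes the median ΔDMS up.
  Transcripts whose maximal median ΔDMS over ordered stage pairs exceeds a
  cutoff are the dsRNA-formation candidates of the screen.

DMS modifies A and C; statistics are restricted to A/C positions by default
whenever base identities are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import RunConfig
from .stages import StageSeries

logger = logging.getLogger(__name__)

AC_BASES = frozenset({"A", "C"})


@dataclass
class ReactivityProfile:
    """Per-position reactivity of one transcript at one stage."""

    transcript_id: str
    stage: str
    reactivity: np.ndarray  # float, >= 0 where not missing
    missing: np.ndarray  # bool mask, True = no measurement
    base: np.ndarray | None = None  # optional, letters in {A,C,G,U,N}

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.reactivity.shape != self.missing.shape:
            raise ValueError("reactivity and missing mask differ in length")
        if self.base is not None:
            self.base = np.asarray(self.base, dtype="U1")
            if self.base.shape != self.reactivity.shape:
                raise ValueError("base vector differs in length")
        obs = self.reactivity[~self.missing]
        if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs < 0)):
            raise ValueError(
                f"{self.transcript_id}/{self.stage}: reactivity must be finite and >= 0"
            )

    def __len__(self) -> int:
        return self.reactivity.size

    def ac_mask(self) -> np.ndarray:
        """True at A/C positions (all True when bases unknown)."""
        if self.base is None:
            return np.ones(len(self), dtype=bool)
        return np.isin(self.base, ("A", "C"))


@dataclass
class RemodelingSummary:
    """Per-transcript stage-pair remodeling statistics.

    Matrices are stage×stage with NaN where undefined; ``delta_median`` is
    antisymmetric with the (earlier-row, later-column) entry positive when
    reactivity decreased over time.
    """

    transcript_id: str
    stages: StageSeries
    r_matrix: np.ndarray
    n_common: np.ndarray
    delta_median: np.ndarray
    min_r: float  # NaN when no pair defined
    min_r_pair: tuple[str, str] | None
    max_delta_median: float
    max_delta_pair: tuple[str, str] | None
    class_label: str = "insufficient"
    n_pairs_evaluated: int = 0


def pair_correlation(
    a: ReactivityProfile,
    b: ReactivityProfile,
    min_common: int = 50,
    ac_only: bool = True,
) -> tuple[float | None, int]:
    """Pearson r of two profiles over jointly covered positions.

    Returns ``(r, n)`` where ``n`` is the number of co-covered positions
    used; ``r`` is None (undefined, not 0) when fewer than ``min_common``
    positions overlap or either vector is constant on the overlap.
    """
    if len(a) != len(b):
        raise ValueError(
            f"profile length mismatch: {a.transcript_id}/{a.stage} vs {b.stage}"
        )
    keep = ~a.missing & ~b.missing
    if ac_only:
        keep &= a.ac_mask() & b.ac_mask()
    x = a.reactivity[keep]
    y = b.reactivity[keep]
    n = int(x.size)
    if n < min_common:
        return None, n
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None, n
    r = stats.pearsonr(x, y).statistic
    return float(r), n


def delta_profile(
    early: ReactivityProfile,
    late: ReactivityProfile,
    stages: StageSeries,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔDMS vector, earlier minus later, with the joint missing mask.

    Positive Δ means reactivity decreased over time.  Raises if the stage
    pair is not oriented earlier→later in the series.
    """
    if len(early) != len(late):
        raise ValueError("profile length mismatch")
    if stages.rank(early.stage) >= stages.rank(late.stage):
        raise ValueError(
            f"stage pair out of order: {early.stage} is not earlier than {late.stage}"
        )
    mask = early.missing | late.missing
    delta = early.reactivity - late.reactivity
    delta[mask] = np.nan
    return delta, mask


def median_delta(
    delta: np.ndarray,
    mask: np.ndarray | None = None,
    min_common: int = 1,
) -> float | None:
    """Median of defined Δ values; None if fewer than ``min_common``."""
    delta = np.asarray(delta, dtype=float)
    keep = np.isfinite(delta)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    vals = delta[keep]
    if vals.size < min_common:
        return None
    return float(np.median(vals))


def classify(
    min_r: float,
    max_delta_median: float,
    stable_min_r: float = 0.8,
    delta_cutoff: float = 0.15,
) -> str:
    """Operational remodeling taxonomy.

    stable: structure preserved everywhere (min r >= stable_min_r);
    unidirectional: a strong one-way reactivity loss (median ΔDMS above the
    cutoff), the intermolecular-duplex signature; bidirectional: strong
    remodeling without a one-way shift, i.e. ordinary refolding.
    """
    if np.isnan(min_r):
        return "insufficient"
    if min_r >= stable_min_r:
        return "stable"
    if max_delta_median > delta_cutoff:
        return "unidirectional"
    return "bidirectional"


def summarize_transcript(
    profiles: dict[str, ReactivityProfile],
    config: RunConfig,
) -> RemodelingSummary:
    """All pairwise stage statistics for one transcript.

    ``profiles`` maps stage label → profile.  Pairs with fewer than
    ``config.min_common_positions`` co-covered (A/C if ``ac_only``)
    positions are undefined and excluded from the min-r / max-ΔDMS scans.
    """
    stages = config.stages
    S = len(stages)
    ids = {p.transcript_id for p in profiles.values()}
    if len(ids) != 1:
        raise ValueError(f"profiles from multiple transcripts: {sorted(ids)}")
    tid = ids.pop()

    r_mat = np.full((S, S), np.nan)
    n_mat = np.zeros((S, S), dtype=int)
    dm_mat = np.full((S, S), np.nan)

    present = [s for s in stages if s in profiles]
    for s in present:
        i = stages.rank(s)
        if np.any(~profiles[s].missing):
            r_mat[i, i] = 1.0
            n_mat[i, i] = int(np.sum(~profiles[s].missing))

    min_r, min_pair = np.nan, None
    max_dm, max_pair = np.nan, None
    n_pairs = 0
    for ii, si in enumerate(present):
        for sj in present[ii + 1 :]:
            i, j = stages.rank(si), stages.rank(sj)
            a, b = profiles[si], profiles[sj]
            r, n = pair_correlation(
                a, b, min_common=config.min_common_positions, ac_only=config.ac_only
            )
            n_mat[i, j] = n_mat[j, i] = n
            if r is None:
                continue
            n_pairs += 1
            r_mat[i, j] = r_mat[j, i] = r
            delta, mask = delta_profile(a, b, stages)
            if config.ac_only:
                mask = mask | ~(a.ac_mask() & b.ac_mask())
            dm = median_delta(delta, mask, min_common=config.min_common_positions)
            if dm is not None:
                dm_mat[i, j] = dm
                dm_mat[j, i] = -dm
            if np.isnan(min_r) or r < min_r:
                min_r, min_pair = r, (si, sj)
            if dm is not None and (max_pair is None or dm > max_dm):
                max_dm, max_pair = dm, (si, sj)

    label = classify(
        min_r,
        max_dm if max_pair is not None else np.nan,
        stable_min_r=config.stable_min_r,
        delta_cutoff=config.delta_median_cutoff,
    )
    if max_pair is None:
        max_dm = np.nan
    return RemodelingSummary(
        transcript_id=tid,
        stages=stages,
        r_matrix=r_mat,
        n_common=n_mat,
        delta_median=dm_mat,
        min_r=float(min_r) if not np.isnan(min_r) else np.nan,
        min_r_pair=min_pair,
        max_delta_median=float(max_dm) if not np.isnan(max_dm) else np.nan,
        max_delta_pair=max_pair,
        class_label=label,
        n_pairs_evaluated=n_pairs,
    )


@dataclass
class ScreenReport:
    """Structural-screen output: per-cutoff low-r gene lists and the
    dsRNA-candidate list (max median ΔDMS above the cutoff)."""

    r_cutoffs: tuple[float, ...]
    low_r: dict[float, list[str]] = field(default_factory=dict)
    candidates: list[str] = field(default_factory=list)
    n_input: int = 0
    n_evaluable: int = 0

    @property
    def counts(self) -> dict[str, int]:
        out = {f"min_r_below_{c:g}": len(v) for c, v in self.low_r.items()}
        out["delta_candidates"] = len(self.candidates)
        return out


def screen_transcripts(
    summaries: list[RemodelingSummary],
    r_cutoffs: tuple[float, ...] = (0.6, 0.5),
    delta_cutoff: float = 0.15,
) -> ScreenReport:
    """Screen remodeling summaries with strict-inequality cutoffs.

    Low-r lists are sorted ascending by min r; the candidate list is sorted
    descending by max median ΔDMS.
    """
    report = ScreenReport(r_cutoffs=tuple(r_cutoffs), n_input=len(summaries))
    evaluable = [s for s in summaries if s.min_r_pair is not None]
    report.n_evaluable = len(evaluable)
    for cutoff in r_cutoffs:
        hits = [s for s in evaluable if s.min_r < cutoff]
        hits.sort(key=lambda s: (s.min_r, s.transcript_id))
        report.low_r[cutoff] = [s.transcript_id for s in hits]
    cand = [
        s
        for s in evaluable
        if s.max_delta_pair is not None and s.max_delta_median > delta_cutoff
    ]
    cand.sort(key=lambda s: (-s.max_delta_median, s.transcript_id))
    report.candidates = [s.transcript_id for s in cand]
    logger.info(
        "structural screen: %d in, %d evaluable, %s",
        report.n_input,
        report.n_evaluable,
        report.counts,
    )
    return report
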