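"""Synthetic inputs with the statistical structure the screen assumes.

The generator emulates a nine-stage synchronized meiosis time course
(V, P, T0..T6) and emits every file the pipeline reads, together with
ground-truth labels for recovery tests:

* reactivity series — per-transcript profiles with three remodeling
  classes: stable (baseline at all stages), intramolecular (balanced ±δ
  shifts inside a stage window, transcript median Δ exactly 0) and
  intermolecular (all positions multiplied by 1−f inside the suppression
  window, the duplex-protection signature);
* stranded counts — negative-binomial sense/antisense counts with a ~15%
  antisense background (undigested second-strand cDNA), stage-specific
  antisense induction concentrated in the P→T0 and T0→T1 intervals
  (78% of activated genes by default) and pulsed sense trajectories at
  activated loci;
* genomes with motif/TSS architecture — URS1 or MSE elements planted in
  the 1-kb region past each active gene's 3′ end, a true antisense TSS at
  a truncated-geometric offset (mean 40 bp, max 100 bp) downstream of the
  motif in the antisense direction, jittered read 5′ ends around the TSS
  plus uniformly scattered artifact ends, and URS1 sense-promoter elements
  at convergent loci.

Class labels are assigned by exact quota, not Bernoulli draws, so recovery
tests have fixed denominators.  All randomness flows from one seed; the
same (config, seed) reproduces byte-identical files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .motifs import (
    IUPAC,
    MSE_CONSENSUS,
    URS1_CONSENSUS,
    FivePrimeEnd,
    GeneModel,
    reverse_complement,
)
from .stages import DEFAULT_STAGE_LABELS, StageSeries
from .structure import ReactivityProfile


def _default_interval_mass(stages: StageSeries) -> dict[tuple[str, str], float]:
    """78% of activation mass on P→T0 and T0→T1, the rest uniform over the
    later intervals."""
    intervals = [iv for iv in stages.intervals() if iv[0] != "V"]
    major = [("P", "T0"), ("T0", "T1")]
    minor = [iv for iv in intervals if iv not in major]
    mass = {iv: 0.39 for iv in major}
    for iv in minor:
        mass[iv] = 0.22 / len(minor)
    return mass


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the study conditions."""

    stage_labels: tuple[str, ...] = DEFAULT_STAGE_LABELS
    seed: int = 0

    # reactivity series
    n_transcripts: int = 500
    transcript_length: int = 200
    fraction_dsrna_targets: float = 0.08
    fraction_intramolecular: float = 0.10
    suppression_fraction: float = 0.6  # f: multiplicative reactivity loss
    suppression_window: tuple[str, str] = ("T1", "T4")
    intramolecular_delta: float = 0.2
    baseline_median: float = 0.5  # A/C-restricted baseline median, exact
    baseline_shape: float = 2.0  # gamma shape of the right-skewed baseline
    noise_sd: float = 0.05
    missing_rate: float = 0.10

    # stranded counts
    n_genes: int = 1000
    antisense_background: float = 0.15
    induced_ratio_level: float = 0.45
    fraction_nat_genes: float = 0.30
    fraction_early_antisense: float = 0.03  # high at V/P then dropping
    activation_interval_mass: dict[tuple[str, str], float] | None = None
    dispersion: float = 0.3  # NB overdispersion: var = mu + disp * mu^2
    mean_depth: float = 1000.0  # median reads per gene per stage (both strands)
    depth_log_sd: float = 0.5  # lognormal spread of per-gene depth
    pulse_genes_fraction: float = 0.10
    pulse_amplitude: float = 5.0  # fold bump of total expression at the peak
    post_pulse_level: float = 0.3

    # pulse z-track cohort
    n_pulse_tracks: int = 200
    pulse_amplitude_z: float = 2.0
    pulse_noise_sd: float = 0.2

    # genome / motif / TSS loci
    n_loci: int = 100
    gene_length: int = 1000
    region_length: int = 1000
    intergenic_gap: int = 100
    fraction_active_loci: float = 0.8
    fraction_convergent: float = 0.2
    tss_offset_mean: float = 40.0
    tss_offset_max: int = 100
    tss_jitter_sd: float = 5.0
    reads_per_tss: int = 20
    artifact_end_fraction: float = 0.10
    scrub_background_motifs: bool = True

    def __post_init__(self) -> None:
        self.stage_labels = tuple(self.stage_labels)
        for name in (
            "fraction_dsrna_targets", "fraction_intramolecular",
            "suppression_fraction", "missing_rate", "antisense_background",
            "induced_ratio_level", "fraction_nat_genes",
            "fraction_early_antisense", "pulse_genes_fraction",
            "fraction_active_loci", "fraction_convergent",
            "artifact_end_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_dsrna_targets > 0 and self.suppression_fraction == 0:
            raise ValueError(
                "suppression_fraction must be > 0 when intermolecular targets are requested"
            )
        if self.induced_ratio_level <= self.antisense_background:
            raise ValueError(
                "induced_ratio_level must exceed antisense_background "
                "(signal below the background floor is undetectable)"
            )
        if self.activation_interval_mass is None:
            self.activation_interval_mass = _default_interval_mass(self.stages)
        total = sum(self.activation_interval_mass.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"activation interval masses must sum to 1, got {total}")
        max_motif = max(len(URS1_CONSENSUS), len(MSE_CONSENSUS))
        if self.region_length < max_motif + self.tss_offset_max:
            raise ValueError(
                "region_length must be >= motif length + maximum TSS offset"
            )
        # window labels must exist
        self.stages.slice(*self.suppression_window)

    @property
    def stages(self) -> StageSeries:
        return StageSeries(self.stage_labels)


def _quota(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n items over label fractions."""
    raw = {k: f * n for k, f in fractions.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:short]:
        base[k] += 1
    return base


# ---------------------------------------------------------------------------
# reactivity series

def simulate_reactivity_series(
    config: SimulationConfig,
) -> tuple[dict[tuple[str, str], ReactivityProfile], pd.DataFrame]:
    """Per-(transcript, stage) reactivity profiles plus truth labels.

    Baselines are gamma-distributed (right-skewed, non-negative) and
    rescaled so the A/C-restricted median equals ``baseline_median``
    exactly; stage noise is Gaussian truncated at zero; missing positions
    are masked i.i.d.
    """
    stages = config.stages
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    n_inter = round(config.fraction_dsrna_targets * n)
    n_intra = round(config.fraction_intramolecular * n)
    if n_inter + n_intra > n:
        raise ValueError("class fractions exceed 1")
    classes = ["intermolecular"] * n_inter + ["intramolecular"] * n_intra
    classes += ["stable"] * (n - len(classes))
    classes = [classes[i] for i in rng.permutation(n)]

    w_lo = stages.rank(config.suppression_window[0])
    w_hi = stages.rank(config.suppression_window[1])
    L = config.transcript_length
    f = config.suppression_fraction
    delta = config.intramolecular_delta

    profiles: dict[tuple[str, str], ReactivityProfile] = {}
    truth_rows = []
    for i, cls in enumerate(classes):
        tid = f"tx{i:04d}"
        base_letters = rng.choice(list("ACGU"), size=L)
        baseline = rng.gamma(config.baseline_shape, 1.0, size=L)
        ac = np.isin(base_letters, ("A", "C"))
        med = np.median(baseline[ac]) if ac.any() else np.median(baseline)
        baseline *= config.baseline_median / med

        up_idx = down_idx = None
        if cls == "intramolecular":
            ac_idx = np.nonzero(ac)[0]
            eligible = ac_idx[baseline[ac_idx] >= delta]
            k = min(len(ac_idx) // 2, len(eligible))
            down_idx = rng.choice(eligible, size=k, replace=False)
            remaining = np.setdiff1d(ac_idx, down_idx)
            up_idx = rng.choice(remaining, size=k, replace=False)

        for s in stages:
            rank = stages.rank(s)
            values = baseline.copy()
            if w_lo <= rank <= w_hi:
                if cls == "intermolecular":
                    values = values * (1.0 - f)
                elif cls == "intramolecular":
                    values[up_idx] += delta
                    values[down_idx] -= delta
            if config.noise_sd > 0:
                values = np.maximum(
                    0.0, values + rng.normal(0.0, config.noise_sd, size=L)
                )
            missing = (
                rng.random(L) < config.missing_rate
                if config.missing_rate > 0
                else np.zeros(L, dtype=bool)
            )
            profiles[(tid, s)] = ReactivityProfile(
                transcript_id=tid, stage=s,
                reactivity=values, missing=missing, base=base_letters,
            )
        truth_rows.append(
            {
                "transcript_id": tid,
                "remodeling_class": cls,
                "window_start": config.suppression_window[0],
                "window_stop": config.suppression_window[1],
            }
        )
    truth = pd.DataFrame(truth_rows).sort_values("transcript_id", ignore_index=True)
    return profiles, truth


# ---------------------------------------------------------------------------
# stranded counts

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + disp*mu^2 (Poisson at 0)."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-9)
    if disp <= 0:
        return rng.poisson(mu)
    size = 1.0 / disp
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_stranded_counts(
    config: SimulationConfig,
) -> tuple[dataio.StrandedCounts, pd.DataFrame]:
    """Gene×stage×strand counts plus per-gene truth.

    Activated genes carry the antisense background fraction b up to the
    activation-interval start and the induced fraction from its end onward;
    pulsed genes (a subset of early-activated genes) additionally spike
    their total output at the activation-interval start and collapse after
    it, so the sharpest sense decline coincides with antisense activation.
    A small quota mimics early antisense (high at V/P, collapsing at T0).
    """
    stages = config.stages
    S = len(stages)
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_genes
    b = config.antisense_background
    induced = config.induced_ratio_level

    n_active = round(config.fraction_nat_genes * n)
    n_early = round(config.fraction_early_antisense * n)
    if n_active + n_early > n:
        raise ValueError("active + early-antisense quotas exceed n_genes")
    interval_counts = _quota(
        {f"{a}->{c}": m for (a, c), m in config.activation_interval_mass.items()},
        n_active,
    )
    intervals: list[str] = []
    for key in sorted(interval_counts, key=lambda k: stages.rank(k.split("->")[0])):
        intervals += [key] * interval_counts[key]

    # quota pulse flags among genes activated in the two early intervals
    n_pulse = round(config.pulse_genes_fraction * n)
    early_slots = [
        i for i, iv in enumerate(intervals) if iv in ("P->T0", "T0->T1")
    ]
    pulse_slots = set(early_slots[:n_pulse])

    perm = rng.permutation(n)
    roles: list[tuple[str, str | None, bool]] = []  # (role, interval, pulsed)
    slot = 0
    for _ in range(n_active):
        roles.append(("active", intervals[slot], slot in pulse_slots))
        slot += 1
    roles += [("early", None, False)] * n_early
    roles += [("background", None, False)] * (n - len(roles))
    roles = [roles[i] for i in np.argsort(perm, kind="stable")]

    gene_ids = [f"g{i:04d}" for i in range(n)]
    lengths = rng.integers(500, 3000, size=n)
    depth = rng.lognormal(np.log(config.mean_depth), config.depth_log_sd, size=n)

    sense = np.zeros((n, S), dtype=np.int64)
    anti = np.zeros((n, S), dtype=np.int64)
    truth_rows = []
    for i, (role, interval, pulsed) in enumerate(roles):
        phi = np.full(S, b)
        mult = np.ones(S)
        if role == "active":
            a_lab, c_lab = interval.split("->")
            start = stages.rank(a_lab)
            stop = stages.rank(c_lab)
            phi[stop:] = induced
            if pulsed:
                mult[:start] = 1.0
                mult[start] = config.pulse_amplitude
                mult[stop:] = config.post_pulse_level
        elif role == "early":
            phi[: stages.rank("T0")] = induced
        # biological overdispersion acts on the locus total; the strand
        # split is a binomial thinning, so each strand is marginally NB
        # with the same dispersion while the ratio stays binomial-tight
        total = _nb_draw(rng, depth[i] * mult, config.dispersion)
        anti[i] = rng.binomial(total, phi)
        sense[i] = total - anti[i]
        truth_rows.append(
            {
                "gene_id": gene_ids[i],
                "nat_active": role == "active",
                "interval": interval or "",
                "meiosis_specific": role == "active",
                "pulsed": pulsed,
                "early_antisense": role == "early",
            }
        )
    counts = dataio.StrandedCounts(
        gene_ids=gene_ids,
        stages=stages,
        sense=sense,
        antisense=anti,
        observed=np.ones((n, S), dtype=bool),
        lengths=np.asarray(lengths, dtype=np.int64),
    )
    truth = pd.DataFrame(truth_rows)
    return counts, truth


# ---------------------------------------------------------------------------
# pulse z-track cohort

def simulate_pulse_tracks(
    config: SimulationConfig,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Abundance-like trajectories for the pulse detector.

    Pulsed tracks spike by ``pulse_amplitude_z`` at a peak stage inside the
    P..T1 window; non-pulsed tracks are the other dynamic archetypes of the
    time course (rising, declining, rebound) at comparable amplitude, all
    with Gaussian noise ``pulse_noise_sd``.  Flat genes are not emulated:
    the detector runs on z-scored rows, which presuppose genuine dynamics.
    """
    stages = config.stages
    S = len(stages)
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_pulse_tracks
    amp = config.pulse_amplitude_z
    quotas = _quota(
        {"pulsed": 0.3, "rising": 0.3, "declining": 0.2, "rebound": 0.2}, n
    )
    shapes = [s for s in ("pulsed", "rising", "declining", "rebound") for _ in range(quotas[s])]
    shapes = [shapes[i] for i in rng.permutation(n)]

    window_ranks = [stages.rank("P"), stages.rank("T0"), stages.rank("T1")]
    tracks = np.zeros((n, S))
    truth_rows = []
    for i, shape in enumerate(shapes):
        x = np.zeros(S)
        peak = None
        if shape == "pulsed":
            peak = int(rng.choice(window_ranks))
            x[peak] = amp
        elif shape == "rising":
            x = np.linspace(0.0, amp, S)
        elif shape == "declining":
            x = np.linspace(amp, 0.0, S)
        else:  # rebound: early dip, late recovery
            x = np.concatenate([np.linspace(amp, 0.0, S // 2), np.linspace(0.0, amp, S - S // 2)])
        x = x + rng.normal(0.0, config.pulse_noise_sd, size=S)
        tracks[i] = x
        truth_rows.append(
            {
                "gene_id": f"p{i:04d}",
                "shape": shape,
                "pulsed": shape == "pulsed",
                "peak_stage": stages.labels[peak] if peak is not None else "",
            }
        )
    ids = [r["gene_id"] for r in truth_rows]
    return tracks, ids, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# genomes with motif / TSS architecture

_MOTIF_RES = {
    "URS1": URS1_CONSENSUS,
    "MSE": MSE_CONSENSUS,
}


def _iupac_regex(consensus: str) -> str:
    return "".join(
        b if len(IUPAC[b]) == 1 else "[" + IUPAC[b] + "]" for b in consensus
    )


def _realize(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        b if len(IUPAC[b]) == 1 else IUPAC[b][rng.integers(len(IUPAC[b]))]
        for b in consensus
    )


def _truncated_geometric(rng: np.random.Generator, mean: float, maximum: int) -> int:
    """Geometric offset (mean ≈ ``mean``) resampled until <= maximum."""
    p = 1.0 / (mean + 1.0)
    while True:
        v = int(rng.geometric(p)) - 1
        if v <= maximum:
            return v


@dataclass
class SimulatedLoci:
    """Genome + annotation + reads + truth from the locus generator."""

    genome: dict[str, str]
    genes: list[GeneModel]
    ends: list[FivePrimeEnd]
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_motif_tss_loci(config: SimulationConfig) -> SimulatedLoci:
    """One-chromosome genome of non-overlapping loci on both strands.

    Active loci carry a planted URS1 or MSE element in the 1-kb region past
    the gene's 3′ end, written on the antisense strand, with a true
    antisense TSS at a truncated-geometric offset downstream of the motif
    in the antisense transcription direction and jittered read 5′ ends
    around it; convergent loci additionally carry a sense-orientation URS1
    in the 1-kb upstream region.  Background sequence is uniform and, by
    default, scrubbed of chance URS1/MSE occurrences so planted sites are
    the only exact matches.
    """
    stages = config.stages  # noqa: F841  (stage series is part of the contract)
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_loci
    RL, GL, gap = config.region_length, config.gene_length, config.intergenic_gap
    pitch = 2 * RL + GL + gap
    genome_len = n * pitch + RL
    chrom = "chrI"
    seq = rng.choice(list("ACGT"), size=genome_len)

    n_active = round(config.fraction_active_loci * n)
    n_conv = round(config.fraction_convergent * n)
    # motif class alternates over active loci; convergent loci are MSE-bearing
    motif_classes = ["URS1" if i % 2 == 0 else "MSE" for i in range(n_active)]
    mse_slots = [i for i, m in enumerate(motif_classes) if m == "MSE"]
    conv_slots = set(mse_slots[:n_conv])

    order = rng.permutation(n)
    genes: list[GeneModel] = []
    ends: list[FivePrimeEnd] = []
    truth_rows = []
    planted: list[tuple[int, int]] = []

    for i in range(n):
        slot = int(order[i])  # which role this positional locus takes
        gs = i * pitch + RL
        ge = gs + GL
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"locus{i:03d}"
        genes.append(GeneModel(gid, chrom, gs, ge, strand))

        row = {
            "gene_id": gid, "strand": strand, "nat_active": False,
            "motif_id": "", "motif_start": -1, "motif_end": -1,
            "motif_strand": "", "tss_pos": -1, "tss_strand": "",
            "offset": -1, "convergent": False,
            "urs1_up_start": -1, "urs1_up_end": -1,
        }
        if slot < n_active:
            motif_id = motif_classes[slot]
            consensus = _realize(_MOTIF_RES[motif_id], rng)
            W = len(consensus)
            offset = _truncated_geometric(rng, config.tss_offset_mean, config.tss_offset_max)
            # distance of the motif's gene-proximal edge from the gene 3' end
            u = int(rng.integers(config.tss_offset_max + 1, RL - W))
            if strand == "+":
                m_start = ge + u
                m_end = m_start + W
                seq[m_start:m_end] = list(reverse_complement(consensus))
                m_strand = "-"
                tss = m_start - offset
            else:
                m_end = gs - u
                m_start = m_end - W
                seq[m_start:m_end] = list(consensus)
                m_strand = "+"
                tss = m_end - 1 + offset
            planted.append((m_start, m_end))
            nat_strand = "-" if strand == "+" else "+"
            for _ in range(config.reads_per_tss):
                pos = tss + int(np.rint(rng.normal(0.0, config.tss_jitter_sd)))
                pos = min(max(pos, 0), genome_len - 1)
                ends.append(FivePrimeEnd(chrom, pos, nat_strand, 1))
            row.update(
                nat_active=True, motif_id=motif_id,
                motif_start=int(m_start), motif_end=int(m_end),
                motif_strand=m_strand, tss_pos=int(tss),
                tss_strand=nat_strand, offset=int(offset),
            )
            if slot in conv_slots:
                urs1 = URS1_CONSENSUS  # invariant consensus
                Wu = len(urs1)
                uu = int(rng.integers(50, RL - Wu))
                if strand == "+":
                    u_start = gs - uu
                    seq[u_start : u_start + Wu] = list(urs1)
                else:
                    u_start = ge + uu - Wu
                    seq[u_start : u_start + Wu] = list(reverse_complement(urs1))
                planted.append((u_start, u_start + Wu))
                row.update(
                    convergent=True,
                    urs1_up_start=int(u_start), urs1_up_end=int(u_start + Wu),
                )
        truth_rows.append(row)

    # artifact 5' ends scattered uniformly
    n_art = round(config.artifact_end_fraction * len(ends))
    for _ in range(n_art):
        pos = int(rng.integers(genome_len))
        strand = "+" if rng.random() < 0.5 else "-"
        ends.append(FivePrimeEnd(chrom, pos, strand, 1))

    genome_seq = "".join(seq)
    if config.scrub_background_motifs:
        genome_seq = _scrub(genome_seq, planted, rng)

    truth = pd.DataFrame(truth_rows)
    return SimulatedLoci(
        genome={chrom: genome_seq}, genes=genes, ends=ends, truth=truth
    )


def _scrub(
    genome: str, planted: list[tuple[int, int]], rng: np.random.Generator
) -> str:
    """Mutate chance URS1/MSE occurrences (either orientation) outside the
    planted intervals so planted motifs are the only exact matches."""
    patterns = []
    for consensus in _MOTIF_RES.values():
        patterns.append((consensus, _iupac_regex(consensus)))
        patterns.append((reverse_complement(consensus),
                         _iupac_regex(reverse_complement(consensus))))
    seq = list(genome)
    planted_set = set(planted)
    in_planted = np.zeros(len(seq), dtype=bool)
    for ps, pe in planted:
        in_planted[ps:pe] = True

    for _ in range(10):
        dirty = False
        text = "".join(seq)
        for oriented, pat in patterns:
            for m in re.finditer(f"(?={pat})", text):
                s = m.start()
                e = s + len(oriented)
                if (s, e) in planted_set:
                    continue
                # break the match at a pattern-specific column that lies
                # outside every planted interval (N columns match any base
                # and cannot be broken)
                columns = [
                    j for j, ch in enumerate(oriented)
                    if len(IUPAC[ch]) < 4 and not in_planted[s + j]
                ]
                if not columns:
                    continue  # fully shadowed by a planted site
                j = columns[len(columns) // 2]
                allowed = set(IUPAC[oriented[j]])
                choices = sorted(set("ACGT") - allowed)
                seq[s + j] = choices[int(rng.integers(len(choices)))]
                dirty = True
        if not dirty:
            break
        # re-check in the next pass: a mutation may create a new match
    return "".join(seq)


# ---------------------------------------------------------------------------
# file emission

def write_reactivity_files(
    profiles, truth: pd.DataFrame, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_reactivity_table(profiles, out / "reactivity.tsv")
    truth.to_csv(out / "reactivity_truth.tsv", sep="\t", index=False)


def write_counts_files(counts, truth: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_stranded_counts(counts, out / "stranded_counts.tsv")
    truth.to_csv(out / "counts_truth.tsv", sep="\t", index=False)


def write_locus_files(sim: SimulatedLoci, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataio.write_fasta(sim.genome, out / "genome.fasta")
    dataio.write_gene_bed(sim.genes, out / "genes.bed")
    dataio.write_gff3_genes(sim.genes, out / "genes.gff3")
    dataio.write_5prime_bed(sim.ends, out / "five_prime_ends.bed")
    sim.truth.to_csv(out / "locus_truth.tsv", sep="\t", index=False)
    motif_rows = sim.truth[sim.truth["nat_active"]]
    with open(out / "motif_truth.bed", "w") as fh:
        for _, r in motif_rows.iterrows():
            fh.write(
                f"chrI\t{r['motif_start']}\t{r['motif_end']}\t"
                f"{r['motif_id']}\t0\t{r['motif_strand']}\n"
            )
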