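"""Readers and writers for the pipeline's external formats.

Formats handled: per-transcript reactivity tables (TSV, transcript-space
1-based positions), strand-specific gene×stage count tables (TSV), JASPAR
text PFMs (via Bio.motifs), BED6 read-5′-end files, BED6 gene models,
GFF3 gene annotation, FASTA genomes (via Bio.SeqIO).

All genomic coordinates are 0-based half-open internally; the only 1-based
column is ``position`` in the reactivity TSV, which lives in transcript
space.  Writers emit rows in sorted key order and shortest round-trip float
representations, so a write is byte-stable and write∘read is the identity
on valid files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import FivePrimeEnd, GeneModel, PositionWeightMatrix
from .stages import StageSeries
from .structure import ReactivityProfile

logger = logging.getLogger(__name__)

VALID_BASES = {"A", "C", "G", "U", "N"}

REACTIVITY_COLUMNS = ["transcript_id", "stage", "position", "base", "reactivity"]
COUNTS_COLUMNS = ["gene_id", "stage", "sense_count", "antisense_count", "length"]


# ---------------------------------------------------------------------------
# reactivity tables

def read_reactivity_table(
    path: str | Path, stages: StageSeries
) -> dict[tuple[str, str], ReactivityProfile]:
    """Parse a reactivity TSV into per-(transcript, stage) profiles.

    Columns: transcript_id, stage, position (1-based within transcript),
    base in {A,C,G,U,N}, reactivity (non-negative float or literal NA).
    Positions are sorted; NA reactivities set the missing mask.  Unknown
    stage labels, duplicate (transcript, stage, position) triples and
    malformed rows raise with the offending line number.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    if list(df.columns) != REACTIVITY_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {REACTIVITY_COLUMNS}, got {list(df.columns)}"
        )
    lines = df.index + 2  # 1-based file line numbers (header is line 1)
    for col in REACTIVITY_COLUMNS:
        bad = df.index[df[col].str.len() == 0]
        if len(bad):
            raise ValueError(f"{path}: line {lines[bad[0]]}: empty {col} field")
    unknown = ~df["stage"].isin(stages.labels)
    if unknown.any():
        i = df.index[unknown][0]
        raise ValueError(f"{path}: line {lines[i]}: unknown stage {df['stage'][i]!r}")
    badbase = ~df["base"].isin(VALID_BASES)
    if badbase.any():
        i = df.index[badbase][0]
        raise ValueError(f"{path}: line {lines[i]}: invalid base {df['base'][i]!r}")
    try:
        pos = df["position"].astype(int)
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer position column: {exc}") from exc
    if (pos < 1).any():
        i = df.index[pos < 1][0]
        raise ValueError(f"{path}: line {lines[i]}: position must be >= 1")
    def _parse_react(s: str) -> float:
        if s == "NA":
            return np.nan
        try:
            return float(s)  # exact round-trip of the writer's shortest repr
        except ValueError:
            return np.inf  # sentinel: flagged as malformed below
    react = df["reactivity"].map(_parse_react)
    malformed = np.isinf(react)
    if malformed.any():
        i = df.index[malformed][0]
        raise ValueError(
            f"{path}: line {lines[i]}: malformed reactivity {df['reactivity'][i]!r}"
        )
    if ((react < 0) & react.notna()).any():
        i = df.index[(react < 0) & react.notna()][0]
        raise ValueError(f"{path}: line {lines[i]}: negative reactivity")
    dup = df.duplicated(subset=["transcript_id", "stage", "position"], keep=False)
    if dup.any():
        i = df.index[dup][0]
        raise ValueError(
            f"{path}: line {lines[i]}: duplicate (transcript, stage, position)"
        )

    work = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "stage": df["stage"],
            "position": pos,
            "base": df["base"],
            "reactivity": react,
        }
    )
    profiles: dict[tuple[str, str], ReactivityProfile] = {}
    for (tid, stage), grp in work.groupby(["transcript_id", "stage"], sort=True):
        grp = grp.sort_values("position")
        n = int(grp["position"].max())
        reactivity = np.zeros(n)
        missing = np.ones(n, dtype=bool)
        base = np.full(n, "N", dtype="U1")
        idx = grp["position"].to_numpy() - 1
        vals = grp["reactivity"].to_numpy()
        obs = ~np.isnan(vals)
        reactivity[idx[obs]] = vals[obs]
        missing[idx] = ~obs
        base[idx] = grp["base"].to_numpy()
        profiles[(tid, stage)] = ReactivityProfile(
            transcript_id=tid, stage=stage,
            reactivity=reactivity, missing=missing, base=base,
        )
    logger.info("read %d reactivity profiles from %s", len(profiles), path)
    return profiles


def write_reactivity_table(
    profiles: dict[tuple[str, str], ReactivityProfile], path: str | Path
) -> None:
    """Inverse of :func:`read_reactivity_table`; rows in sorted key order."""
    rows = []
    for (tid, stage) in sorted(profiles):
        p = profiles[(tid, stage)]
        base = p.base if p.base is not None else np.full(len(p), "N", dtype="U1")
        for i in range(len(p)):
            val = "NA" if p.missing[i] else str(float(p.reactivity[i]))
            rows.append((tid, stage, i + 1, base[i], val))
    with open(path, "w") as fh:
        fh.write("\t".join(REACTIVITY_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ---------------------------------------------------------------------------
# stranded counts

@dataclass
class StrandedCounts:
    """Dense gene×stage count matrices for both strands.

    ``observed`` distinguishes true zeros from absent (gene, stage) rows:
    downstream TPM-floor filtering treats unobserved cells as missing, not
    as zero expression.
    """

    gene_ids: list[str]
    stages: StageSeries
    sense: np.ndarray  # int, genes × stages
    antisense: np.ndarray
    observed: np.ndarray  # bool
    lengths: np.ndarray  # int, per gene (shared by both strands)

    def __post_init__(self) -> None:
        G, S = len(self.gene_ids), len(self.stages)
        for name in ("sense", "antisense", "observed"):
            if getattr(self, name).shape != (G, S):
                raise ValueError(f"{name} matrix must be {G}×{S}")
        if self.lengths.shape != (G,):
            raise ValueError("lengths must be per-gene")
        if np.any(self.lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if np.any(self.sense < 0) or np.any(self.antisense < 0):
            raise ValueError("counts must be non-negative")


def read_stranded_counts(path: str | Path, stages: StageSeries) -> StrandedCounts:
    """Parse a stranded count TSV (gene_id, stage, sense_count,
    antisense_count, length) into dense matrices; absent (gene, stage)
    pairs become zero counts flagged unobserved."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "stage": str})
    if list(df.columns) != COUNTS_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {COUNTS_COLUMNS}, got {list(df.columns)}"
        )
    unknown = ~df["stage"].isin(stages.labels)
    if unknown.any():
        raise ValueError(
            f"{path}: unknown stage {df['stage'][df.index[unknown][0]]!r}"
        )
    if (df[["sense_count", "antisense_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative count")
    if (df["length"] <= 0).any():
        raise ValueError(f"{path}: gene length must be positive")
    if df.duplicated(subset=["gene_id", "stage"]).any():
        raise ValueError(f"{path}: duplicate (gene, stage) row")
    lens = df.groupby("gene_id")["length"].nunique()
    if (lens > 1).any():
        raise ValueError(f"{path}: inconsistent length for gene {lens.idxmax()!r}")

    gene_ids = sorted(df["gene_id"].unique())
    gidx = {g: i for i, g in enumerate(gene_ids)}
    G, S = len(gene_ids), len(stages)
    sense = np.zeros((G, S), dtype=np.int64)
    anti = np.zeros((G, S), dtype=np.int64)
    observed = np.zeros((G, S), dtype=bool)
    lengths = np.zeros(G, dtype=np.int64)
    gi = df["gene_id"].map(gidx).to_numpy()
    si = df["stage"].map(stages.index).to_numpy()
    sense[gi, si] = df["sense_count"].to_numpy()
    anti[gi, si] = df["antisense_count"].to_numpy()
    observed[gi, si] = True
    lengths[gi] = df["length"].to_numpy()
    logger.info("read stranded counts for %d genes from %s", G, path)
    return StrandedCounts(gene_ids, stages, sense, anti, observed, lengths)


def write_stranded_counts(counts: StrandedCounts, path: str | Path) -> None:
    """Inverse of :func:`read_stranded_counts`; unobserved cells omitted."""
    with open(path, "w") as fh:
        fh.write("\t".join(COUNTS_COLUMNS) + "\n")
        for i, g in enumerate(counts.gene_ids):
            for j, s in enumerate(counts.stages):
                if counts.observed[i, j]:
                    fh.write(
                        f"{g}\t{s}\t{counts.sense[i, j]}\t"
                        f"{counts.antisense[i, j]}\t{counts.lengths[i]}\n"
                    )


# ---------------------------------------------------------------------------
# JASPAR PFMs

def read_jaspar_pfm(path: str | Path, pseudocount: float = 1.0) -> PositionWeightMatrix:
    """Read the first motif of a JASPAR-format PFM file.

    Count columns get ``pseudocount`` added to every cell before
    normalization, so probabilities are strictly positive and columns sum
    to 1.  All-zero columns (before pseudocounts) are rejected.
    """
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
        motifs_list = list(records)
    if not motifs_list:
        raise ValueError(f"{path}: no motif records found")
    m = motifs_list[0]
    counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative count in PFM")
    colsum = counts.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError(f"{path}: all-zero PFM column")
    probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
    name = m.matrix_id or m.name or Path(path).stem
    return PositionWeightMatrix(matrix_id=name, probs=probs, source="pfm_file")


# ---------------------------------------------------------------------------
# BED6 5′ ends

def read_5prime_bed(path: str | Path) -> list[FivePrimeEnd]:
    """Read a BED6 of read records and reduce each to its 5′ end.

    For + records the 5′ end is chromStart; for − records it is
    chromEnd−1 (0-based).  Identical (chrom, position, strand) entries are
    aggregated with summed scores; a record's score is its read count
    (empty/"." = 1).
    """
    agg: dict[tuple[str, int, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: need 6 BED fields")
            chrom, start, end, _name, score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            start, end = int(start), int(end)
            if not 0 <= start < end:
                raise ValueError(f"{path}: line {lineno}: bad interval")
            count = 1 if score in (".", "") else int(float(score))
            pos = start if strand == "+" else end - 1
            key = (chrom, pos, strand)
            agg[key] = agg.get(key, 0) + count
    ends = [
        FivePrimeEnd(chrom, pos, strand, count)
        for (chrom, pos, strand), count in sorted(agg.items())
    ]
    logger.info("read %d distinct 5' ends from %s", len(ends), path)
    return ends


def write_5prime_bed(ends: list[FivePrimeEnd], path: str | Path) -> None:
    """Write 5′ ends as single-base BED6 records (score = count)."""
    with open(path, "w") as fh:
        for e in sorted(ends, key=lambda e: (e.chrom, e.position, e.strand)):
            fh.write(
                f"{e.chrom}\t{e.position}\t{e.position + 1}\t5p\t{e.count}\t{e.strand}\n"
            )


# ---------------------------------------------------------------------------
# gene models, genomes

def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read gene loci from BED6 (name column = gene id)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: need 6 BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneModel(name, chrom, int(start), int(end), strand))
    return genes


def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (type == 'gene', ID attribute)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: need 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID") or attr.get("Name")
            if gid is None:
                raise ValueError(f"{path}: line {lineno}: gene without ID")
            genes.append(GeneModel(gid, chrom, int(start) - 1, int(end), strand))
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tdsrna\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")
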