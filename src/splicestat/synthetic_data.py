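"""Synthetic inputs: transcriptomes, expression assignments, quantification
tables and simulated paired-end RNA-seq reads.

The read simulator emulates an idealized sequencing experiment: for a
transcript of length L with expression level E it draws
``R = int(E*L/100/2 + 0.5)`` read pairs (100 bp per mate, fixed 100 bp
insert) whose fragment start positions are uniform over the transcript,
so that coverage is flat and the implied expression equals E up to the
rounding granularity 200/L.  Expression levels are drawn per gene as M
independent values from either ``Weibull(a=0.39, b=10)`` (the splicing
model) or ``Normal(20, 2)`` truncated at zero (a negative control whose
frequency spectrum the Weibull model should *not* fit).

No error model, PCR duplication or positional bias is simulated.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from splicestat.weibull_model import WeibullParams, sample as weibull_sample

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReadSimConfig:
    """Geometry and bookkeeping of the paired-end read simulator."""

    read_length: int = 100
    insert_length: int = 100
    replicates: int = 10
    seed: int = 0
    quality_char: str = "I"  # Phred 40

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.insert_length < 0:
            raise ValueError("insert_length must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def fragment_length(self) -> int:
        return 2 * self.read_length + self.insert_length


@dataclass(frozen=True)
class SyntheticTranscriptome:
    """Genes with their isoform sequences, over the alphabet {A,C,G,T}."""

    genes: dict  # gene_id -> list of (transcript_id, sequence)

    @property
    def transcripts(self) -> dict[str, str]:
        return {tid: seq for isos in self.genes.values() for tid, seq in isos}

    @property
    def t2g(self) -> dict[str, str]:
        return {
            tid: gid for gid, isos in self.genes.items() for tid, _ in isos
        }

    def isoform_counts(self) -> dict[str, int]:
        return {gid: len(isos) for gid, isos in self.genes.items()}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gid in self.genes:
                for tid, seq in self.genes[gid]:
                    fh.write(f">{tid} gene={gid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")

    def write_annotation(self, path) -> None:
        rows = [
            {"transcript_id": tid, "gene_id": gid, "length": len(seq)}
            for gid, isos in self.genes.items()
            for tid, seq in isos
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _draw_M(M_distribution, rng: np.random.Generator) -> int:
    """Isoform count per gene: a constant, a {M: weight} dict, or a callable."""
    if isinstance(M_distribution, int):
        return M_distribution
    if isinstance(M_distribution, Mapping):
        ms = np.array(list(M_distribution.keys()))
        w = np.array(list(M_distribution.values()), dtype=float)
        return int(rng.choice(ms, p=w / w.sum()))
    if isinstance(M_distribution, Callable):
        return int(M_distribution(rng))
    raise ValueError(f"unsupported M distribution: {M_distribution!r}")


def synthetic_transcriptome(
    n_genes: int,
    M_distribution=2,
    length_range: tuple[int, int] = (300, 3000),
    seed: int = 0,
    allow_short: bool = False,
) -> SyntheticTranscriptome:
    """Random transcriptome with uniform base composition.

    Deterministic under ``seed``.  ``length_range`` is inclusive; by
    default lengths below 300 (the fragment size of the default read
    geometry) are rejected unless ``allow_short`` is set.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 300 and not allow_short:
        raise ValueError(
            "minimum transcript length below the read-pair fragment size "
            "(300); pass allow_short=True if intended"
        )
    rng = np.random.default_rng(seed)
    genes: dict[str, list[tuple[str, str]]] = {}
    for g in range(1, n_genes + 1):
        gid = f"G{g:05d}"
        M = _draw_M(M_distribution, rng)
        isos = []
        for t in range(1, M + 1):
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(BASES, size=L))
            isos.append((f"{gid}.T{t}", seq))
        genes[gid] = isos
    return SyntheticTranscriptome(genes)


def _parse_gtf_exons(path) -> pd.DataFrame:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    return df[df["Feature"] == "exon"].copy()


def _parse_gtf_records(path):
    """Yield per-exon dicts with gene_id/transcript_id from a GTF."""
    df = _parse_gtf_exons(path)
    for _, row in df.iterrows():
        yield {"gene_id": row["gene_id"], "transcript_id": row["transcript_id"]}


def extract_transcript_sequences(genome_fasta, annotation_gtf) -> dict[str, str]:
    """Spliced transcript sequences from a genome FASTA and a GTF.

    Exon sequences are concatenated in genomic order; minus-strand
    transcripts are reverse-complemented after concatenation.  GTF
    coordinates are 1-based inclusive.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True)
    exons = _parse_gtf_exons(annotation_gtf)
    if exons.empty:
        raise ValueError("annotation contains no exon records")
    out: dict[str, str] = {}
    for tid, sub in exons.groupby("transcript_id", sort=True):
        sub = sub.sort_values("Start")
        chrom = sub["Chromosome"].iloc[0]
        strand = sub["Strand"].iloc[0]
        chrom_len = len(genome[str(chrom)][:])
        parts = []
        for _, ex in sub.iterrows():
            start, end = int(ex["Start"]), int(ex["End"])  # 0-based half-open
            if start < 0 or end > chrom_len:
                raise ValueError(
                    f"exon of transcript {tid} ({start}-{end}) outside "
                    f"contig {chrom} of length {chrom_len}"
                )
            parts.append(str(genome[str(chrom)][start:end]))
        seq = "".join(parts)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[str(tid)] = seq
    return out


def parse_expression_law(law):
    """Normalize an expression-law spec to ``(family, param1, param2)``.

    Accepts "normal:20,2", "weibull:0.39,10", or a tuple of the same.
    """
    if isinstance(law, str):
        try:
            family, params = law.split(":")
            p1, p2 = (float(v) for v in params.split(","))
        except ValueError as exc:
            raise ValueError(f"cannot parse expression law {law!r}") from exc
    else:
        family, p1, p2 = law
    if family not in ("normal", "weibull"):
        raise ValueError(f"unknown expression law family {family!r}")
    return family, float(p1), float(p2)


def assign_expression(
    transcriptome: SyntheticTranscriptome, law, seed: int = 0
) -> dict[str, float]:
    """Draw per-gene expression vectors: M independent values per gene.

    Normal draws are truncated at 0 (negative expression is meaningless;
    at 10 sigma from the mean the truncated mass is negligible).
    """
    family, p1, p2 = parse_expression_law(law)
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for gid, isos in transcriptome.genes.items():
        M = len(isos)
        if family == "normal":
            vals = np.clip(rng.normal(p1, p2, size=M), 0.0, None)
        else:
            vals = weibull_sample(WeibullParams(p1, p2), M, rng=rng)
        for (tid, _), v in zip(isos, vals):
            out[tid] = float(v)
    return out


def read_pair_count(E: float, L: int) -> int:
    """Pair count ``R = int(E*L/100/2 + 0.5)`` — round half up for E,L >= 0."""
    if E < 0:
        raise ValueError("expression must be nonnegative")
    if L <= 0:
        raise ValueError("transcript length must be positive")
    return int(E * L / 100.0 / 2.0 + 0.5)


def generate_read_pairs(
    transcript_id: str,
    sequence: str,
    R: int,
    config: ReadSimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """R read pairs with uniform fragment starts over the transcript.

    Mate 1 is the fragment's 5' end; mate 2 is the reverse complement of
    its 3' end.  Returns ``(name, read1, read2)`` triples; names encode
    the source transcript and pair index for truth tracking.
    """
    L = len(sequence)
    frag = config.fragment_length
    if L < frag:
        raise ValueError(
            f"transcript {transcript_id} (length {L}) shorter than the "
            f"fragment size {frag}"
        )
    starts = rng.integers(0, L - frag + 1, size=R)
    rl = config.read_length
    pairs = []
    for i, s in enumerate(starts, start=1):
        fragment = sequence[s : s + frag]
        read1 = fragment[:rl]
        read2 = str(Seq(fragment[-rl:]).reverse_complement())
        pairs.append((f"{transcript_id}:pair{i}", read1, read2))
    return pairs


def _open_maybe_gz(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def simulate_fastq(
    transcriptome: SyntheticTranscriptome,
    expressions: Mapping[str, float],
    config: ReadSimConfig,
    outdir,
    prefix: str = "sim",
    gzip_output: bool = False,
) -> pd.DataFrame:
    """Write paired FASTQ files per replicate; return the truth table.

    Replicate r draws fresh fragment positions from sub-seed
    ``(config.seed, r)``.  Transcripts shorter than the fragment size are
    skipped with a warning and flagged in the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    qual = config.quality_char * config.read_length
    rows = []
    for r in range(1, config.replicates + 1):
        rng = np.random.default_rng((config.seed, r))
        f1 = _open_maybe_gz(outdir / f"{prefix}_rep{r}_R1{suffix}")
        f2 = _open_maybe_gz(outdir / f"{prefix}_rep{r}_R2{suffix}")
        with f1, f2:
            for gid, isos in transcriptome.genes.items():
                for tid, seq in isos:
                    E = expressions[tid]
                    R = read_pair_count(E, len(seq))
                    skipped = len(seq) < config.fragment_length
                    if skipped and R > 0:
                        logger.warning(
                            "skipping %s: length %d < fragment %d",
                            tid,
                            len(seq),
                            config.fragment_length,
                        )
                    elif R > 0:
                        for name, read1, read2 in generate_read_pairs(
                            tid, seq, R, config, rng
                        ):
                            f1.write(f"@{name}/1\n{read1}\n+\n{qual}\n")
                            f2.write(f"@{name}/2\n{read2}\n+\n{qual}\n")
                    rows.append(
                        {
                            "replicate": r,
                            "gene_id": gid,
                            "transcript_id": tid,
                            "length": len(seq),
                            "expression": E,
                            "pairs": 0 if skipped else R,
                            "skipped": skipped,
                        }
                    )
    return pd.DataFrame(rows)


def requantify_exact(fastq1, fastq2, transcriptome: SyntheticTranscriptome):
    """Truth-based quantification by exact substring matching.

    Each pair is assigned to a transcript whose sequence contains mate 1
    verbatim and the reverse complement of mate 2 (seeded by a 25-mer
    index; ambiguous pairs go to the lexicographically first match).
    Returns a DataFrame with pair counts and the implied expression
    ``E_hat = 200 * pairs / L``.
    """
    K = 25
    index: dict[str, list[str]] = {}
    seqs = transcriptome.transcripts
    for tid in sorted(seqs):
        seq = seqs[tid]
        for i in range(len(seq) - K + 1):
            index.setdefault(seq[i : i + K], []).append(tid)

    def read_records(path):
        with _open_maybe_gz(path, "rt") as fh:
            while True:
                header = fh.readline()
                if not header:
                    return
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                yield seq

    counts: dict[str, int] = {tid: 0 for tid in seqs}
    unassigned = 0
    for r1, r2 in zip(read_records(fastq1), read_records(fastq2)):
        r2rc = str(Seq(r2).reverse_complement())
        assigned = False
        for tid in index.get(r1[:K], []):
            if r1 in seqs[tid] and r2rc in seqs[tid]:
                counts[tid] += 1
                assigned = True
                break
        if not assigned:
            unassigned += 1
    rows = [
        {
            "transcript_id": tid,
            "pairs": n,
            "length": len(seqs[tid]),
            "E_hat": 200.0 * n / len(seqs[tid]),
        }
        for tid, n in counts.items()
    ]
    df = pd.DataFrame(rows)
    df.attrs["unassigned_pairs"] = unassigned
    return df


def expression_table(
    n_genes: int,
    M_distribution=2,
    law="weibull:0.39,10",
    seed: int = 0,
    length_range: tuple[int, int] = (300, 3000),
):
    """A ready-to-parse Salmon-dialect table plus its truth.

    Returns ``(table, t2g, truth)``: the quant.sf-layout DataFrame whose
    TPM column carries the assigned expression values, the transcript-to-
    gene mapping, and the per-transcript truth table.  Sequences are not
    materialized — lengths are drawn directly, which keeps table
    generation cheap at large gene counts.
    """
    rng = np.random.default_rng(seed)
    family, p1, p2 = parse_expression_law(law)
    lo, hi = length_range
    rows = []
    t2g: dict[str, str] = {}
    for g in range(1, n_genes + 1):
        gid = f"G{g:05d}"
        M = _draw_M(M_distribution, rng)
        if family == "normal":
            vals = np.clip(rng.normal(p1, p2, size=M), 0.0, None)
        else:
            vals = weibull_sample(WeibullParams(p1, p2), M, rng=rng)
        lengths = rng.integers(lo, hi + 1, size=M)
        for t, (E, L) in enumerate(zip(vals, lengths), start=1):
            tid = f"{gid}.T{t}"
            t2g[tid] = gid
            rows.append(
                {
                    "Name": tid,
                    "Length": int(L),
                    "EffectiveLength": max(int(L) - 200, 1),
                    "TPM": float(E),
                    "NumReads": read_pair_count(float(E), int(L)),
                }
            )
    table = pd.DataFrame(rows)
    truth = table.rename(columns={"Name": "transcript_id", "TPM": "expression"})[
        ["transcript_id", "length" if "length" in table else "Length", "expression"]
    ].rename(columns={"Length": "length"})
    truth["gene_id"] = truth["transcript_id"].map(t2g)
    return table, t2g, truth
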