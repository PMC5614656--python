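"""Parsing of isoform quantification tables and ranked frequency profiles.

Two TSV dialects are supported: the Cufflinks/Cuffdiff
``isoforms.fpkm_tracking`` layout (columns ``tracking_id``, ``gene_id``,
``FPKM``) and the Salmon ``quant.sf`` layout (``Name``, ``Length``,
``EffectiveLength``, ``TPM``, ``NumReads``; a transcript-to-gene mapping
is required since quant.sf has no gene column).

Profiles attach the *annotated* isoform count M to each gene — isoforms
missing from the table enter with expression zero — and compute the
descending frequency vector f(1..M).  Genes are kept only when their
total expression exceeds a threshold (default 1, i.e. FPKM > 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CUFFLINKS_REQUIRED = ("tracking_id", "gene_id", "FPKM")
SALMON_REQUIRED = ("Name", "Length", "EffectiveLength", "TPM", "NumReads")


class FormatError(ValueError):
    """A required column is missing or a file is malformed."""


@dataclass(frozen=True)
class GeneIsoformProfile:
    """One gene's ranked isoform expression in one sample/condition.

    ``expressions`` and ``frequencies`` have length M (the annotated
    isoform count) and are sorted descending; ``isoform_ids`` is aligned
    with them.  Rank ties are broken lexicographically by transcript id.
    """

    gene_id: str
    sample_id: str
    condition: str
    M: int
    isoform_ids: tuple
    expressions: np.ndarray
    frequencies: np.ndarray

    @property
    def E(self) -> float:
        """Total gene expression (sum over annotated isoforms)."""
        return float(np.sum(self.expressions))


def read_t2g(path) -> dict[str, str]:
    """Read a two-column TSV mapping transcript_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("transcript-to-gene map needs two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def annotation_isoform_counts(t2g: Mapping[str, str]) -> dict[str, int]:
    """Annotated isoform count M per gene from a transcript->gene mapping."""
    counts: dict[str, int] = {}
    for gene in t2g.values():
        counts[gene] = counts.get(gene, 0) + 1
    return counts


def isoform_counts_from_gtf(path) -> dict[str, int]:
    """Annotated isoform count per gene from a GTF file.

    Counts distinct ``transcript_id`` values per ``gene_id`` attribute
    (1-based inclusive coordinates; only the attribute column is used).
    """
    from splicestat.synthetic_data import _parse_gtf_records

    seen: dict[str, set] = {}
    for rec in _parse_gtf_records(path):
        gid, tid = rec["gene_id"], rec["transcript_id"]
        seen.setdefault(gid, set()).add(tid)
    return {g: len(ts) for g, ts in seen.items()}


def read_expression_table(
    path,
    dialect: str,
    t2g: Mapping[str, str] | None = None,
    sample_id: str = "sample",
    condition: str = "none",
) -> pd.DataFrame:
    """Read a quantification table into the long normalized layout.

    Returns a DataFrame with columns ``transcript_id``, ``gene_id``,
    ``expression``, ``sample_id``, ``condition``.  Expression comes from
    the FPKM column (cufflinks dialect) or the TPM column (salmon
    dialect, which requires ``t2g``).  Malformed rows are dropped and
    reported with their line numbers.
    """
    if dialect not in ("cufflinks", "salmon"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    required = CUFFLINKS_REQUIRED if dialect == "cufflinks" else SALMON_REQUIRED
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if dialect == "cufflinks":
        out = pd.DataFrame(
            {
                "transcript_id": df["tracking_id"].astype(str),
                "gene_id": df["gene_id"].astype(str),
                "expression": pd.to_numeric(df["FPKM"], errors="coerce"),
            }
        )
    else:
        if t2g is None:
            raise ValueError("salmon dialect requires a transcript-to-gene mapping")
        out = pd.DataFrame(
            {
                "transcript_id": df["Name"].astype(str),
                "gene_id": df["Name"].astype(str).map(t2g),
                "expression": pd.to_numeric(df["TPM"], errors="coerce"),
            }
        )
    bad = out.index[out["expression"].isna() | (out["expression"] < 0)]
    if len(bad):
        # +2: 1-based with a header line
        lines = [int(i) + 2 for i in bad]
        logger.warning("dropping %d malformed rows at lines %s", len(bad), lines)
        out = out.drop(index=bad)
    out = out.reset_index(drop=True)
    dup = out.duplicated(subset="transcript_id")
    if dup.any():
        raise FormatError(
            f"duplicate transcript ids in {path}: "
            f"{sorted(out.loc[dup, 'transcript_id'].unique()[:5])}"
        )
    out["sample_id"] = sample_id
    out["condition"] = condition
    return out


def build_gene_profiles(
    table: pd.DataFrame,
    annotation_counts: Mapping[str, int],
    min_gene_expr: float = 1.0,
) -> tuple[list[GeneIsoformProfile], dict]:
    """Rank isoforms into per-gene frequency profiles.

    For each (gene, sample): annotated isoforms absent from the table get
    expression 0 (placeholder ids), genes with total expression
    ``E <= min_gene_expr`` are excluded, frequencies are ranked descending
    with lexicographic transcript-id tie-break.  Transcripts whose gene is
    not in ``annotation_counts`` are dropped and counted in the summary.
    """
    profiles: list[GeneIsoformProfile] = []
    summary = {"unknown_gene_transcripts": 0, "filtered_genes": 0, "kept_genes": 0}
    unknown = ~table["gene_id"].isin(annotation_counts) | table["gene_id"].isna()
    summary["unknown_gene_transcripts"] = int(unknown.sum())
    if summary["unknown_gene_transcripts"]:
        logger.warning(
            "dropping %d transcripts with unannotated genes",
            summary["unknown_gene_transcripts"],
        )
    table = table[~unknown]

    for (gene, sample_id, condition), sub in sorted(
        table.groupby(["gene_id", "sample_id", "condition"], sort=False),
        key=lambda kv: kv[0],
    ):
        M = int(annotation_counts[gene])
        ids = list(sub["transcript_id"])
        expr = list(sub["expression"].astype(float))
        if len(ids) > M:
            logger.warning(
                "gene %s: %d observed isoforms exceed annotated M=%d; expanding",
                gene,
                len(ids),
                M,
            )
            M = len(ids)
        for i in range(M - len(ids)):
            ids.append(f"{gene}:unobserved{i + 1}")
            expr.append(0.0)
        E = float(np.sum(expr))
        if E <= min_gene_expr:
            summary["filtered_genes"] += 1
            continue
        order = sorted(range(M), key=lambda i: (-expr[i], ids[i]))
        expr_sorted = np.array([expr[i] for i in order])
        profiles.append(
            GeneIsoformProfile(
                gene_id=gene,
                sample_id=sample_id,
                condition=condition,
                M=M,
                isoform_ids=tuple(ids[i] for i in order),
                expressions=expr_sorted,
                frequencies=expr_sorted / E,
            )
        )
        summary["kept_genes"] += 1
    return profiles, summary


def group_by_isoform_count(
    profiles: Iterable[GeneIsoformProfile],
) -> dict[int, list[np.ndarray]]:
    """Pool frequency vectors by annotated isoform count M, across samples."""
    groups: dict[int, list[np.ndarray]] = {}
    for p in profiles:
        groups.setdefault(p.M, []).append(p.frequencies)
    return groups


def read_profiles_tsv(path) -> list[GeneIsoformProfile]:
    """Read the long layout written by :func:`write_profiles_tsv`.

    Expression levels are not stored in the long layout, so the profiles
    come back frequency-normalized (expressions equal frequencies, E = 1).
    """
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (gene, sample_id, condition), sub in df.groupby(
        ["gene_id", "sample_id", "condition"], sort=True
    ):
        sub = sub.sort_values("rank")
        freqs = sub["frequency"].to_numpy(dtype=float)
        profiles.append(
            GeneIsoformProfile(
                gene_id=str(gene),
                sample_id=str(sample_id),
                condition=str(condition),
                M=int(sub["M"].iloc[0]),
                isoform_ids=tuple(sub["transcript_id"].astype(str)),
                expressions=freqs,
                frequencies=freqs,
            )
        )
    return profiles


def write_profiles_tsv(profiles: Iterable[GeneIsoformProfile], path) -> None:
    """Emit the long normalized layout (gene, sample, M, rank, frequency)."""
    rows = []
    for p in profiles:
        for k, (tid, f) in enumerate(zip(p.isoform_ids, p.frequencies), start=1):
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "sample_id": p.sample_id,
                    "condition": p.condition,
                    "M": p.M,
                    "rank": k,
                    "transcript_id": tid,
                    "frequency": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
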