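"""Readers and writers for every external representation the tool touches.

All on-disk formats are plain delimited text:

* GWAS summary statistics: tab-separated with a header; columns for SNP id,
  effect size and (optionally) sample size, configurable via ``column_map``.
* eQTL weights: long-format table ``GENE  SNP  WEIGHT`` (one row per nonzero
  weight).  A directory of one-file-per-gene tables is accepted through
  :func:`read_weights_dir`.
* LD panel: square tab-separated matrix whose header row and first column
  carry SNP ids.
* Gene sets: GMT (MSigDB dialect) — ``set_id <TAB> description <TAB> genes...``
* Expression: gene x sample matrix, header row of sample ids, first column of
  gene ids; phenotype as a two-column ``SAMPLE  VALUE`` table.
* Enrichment results: tab-separated table sorted by ascending p-value.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ENRICHMENT_COLUMNS,
    EqtlWeightSet,
    ExpressionDataset,
    GeneSetCollection,
    GwasSummary,
    LdPanel,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SUMSTATS_COLUMNS = {"snp": "SNP", "beta": "BETA", "n": "N"}


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas_sumstats(
    path: str | os.PathLike,
    column_map: dict[str, str] | None = None,
    n_gwas: int | None = None,
) -> GwasSummary:
    """Read per-SNP standardized marginal effect sizes.

    ``column_map`` maps the logical names ``snp``, ``beta`` and (optionally)
    ``n`` to the column names used in the file.  If the file has no sample
    size column, ``n_gwas`` must be given.
    """
    cols = dict(DEFAULT_SUMSTATS_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for key in ("snp", "beta"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"{path}: missing column {cols[key]!r} (have {list(df.columns)})"
            )
    snp_ids = df[cols["snp"]].astype(str).tolist()
    dup = df[cols["snp"]][df[cols["snp"]].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicated SNP id {dup.iloc[0]!r}")
    if cols.get("n") in df.columns:
        n = int(df[cols["n"]].iloc[0])
    elif n_gwas is not None:
        n = int(n_gwas)
    else:
        raise FormatError(f"{path}: no sample-size column and n_gwas not given")
    return GwasSummary(snp_ids=snp_ids, beta=df[cols["beta"]].to_numpy(float), n_gwas=n)


def write_gwas_sumstats(gwas: GwasSummary, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"SNP": gwas.snp_ids, "BETA": gwas.beta, "N": gwas.n_gwas}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# eQTL weights


def read_weights(path: str | os.PathLike) -> EqtlWeightSet:
    """Read a long-format weight table with columns GENE, SNP, WEIGHT."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("GENE", "SNP", "WEIGHT"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return _weights_from_long(df, str(path))


def _weights_from_long(df: pd.DataFrame, source: str) -> EqtlWeightSet:
    if df.duplicated(subset=["GENE", "SNP"]).any():
        row = df[df.duplicated(subset=["GENE", "SNP"])].iloc[0]
        raise ValidationError(
            f"{source}: duplicate (gene, SNP) pair ({row['GENE']}, {row['SNP']})"
        )
    gene_ids = list(dict.fromkeys(df["GENE"].astype(str)))
    snp_ids = list(dict.fromkeys(df["SNP"].astype(str)))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    sidx = {s: i for i, s in enumerate(snp_ids)}
    weights = np.zeros((len(snp_ids), len(gene_ids)))
    weights[
        df["SNP"].astype(str).map(sidx).to_numpy(),
        df["GENE"].astype(str).map(gidx).to_numpy(),
    ] = df["WEIGHT"].to_numpy(float)
    return EqtlWeightSet(snp_ids=snp_ids, gene_ids=gene_ids, weights=weights)


def read_weights_dir(directory: str | os.PathLike) -> EqtlWeightSet:
    """Read a directory of one-file-per-gene weight tables (SNP, WEIGHT).

    The gene id is the file stem.  Equivalent to concatenating the files into
    one long-format table.
    """
    frames = []
    paths = sorted(Path(directory).glob("*.tsv")) + sorted(Path(directory).glob("*.txt"))
    if not paths:
        raise FormatError(f"{directory}: no .tsv or .txt weight files found")
    for p in paths:
        df = pd.read_csv(p, sep="\t", float_precision="round_trip")
        for col in ("SNP", "WEIGHT"):
            if col not in df.columns:
                raise FormatError(f"{p}: missing column {col!r}")
        df = df.assign(GENE=p.stem)
        frames.append(df[["GENE", "SNP", "WEIGHT"]])
    return _weights_from_long(pd.concat(frames, ignore_index=True), str(directory))


def write_weights(weights: EqtlWeightSet, path: str | os.PathLike) -> None:
    snp_idx, gene_idx = np.nonzero(weights.weights)
    df = pd.DataFrame(
        {
            "GENE": [weights.gene_ids[g] for g in gene_idx],
            "SNP": [weights.snp_ids[s] for s in snp_idx],
            "WEIGHT": weights.weights[snp_idx, gene_idx],
        }
    ).sort_values(["GENE", "SNP"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# LD panel


def read_ld(path: str | os.PathLike) -> LdPanel:
    """Read a square LD matrix with SNP ids in the header and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row and column SNP ids differ")
    sigma = df.to_numpy(float)
    np.fill_diagonal(sigma, 1.0)
    return LdPanel(snp_ids=list(df.columns.astype(str)), sigma=sigma)


def write_ld(ld: LdPanel, path: str | os.PathLike) -> None:
    df = pd.DataFrame(ld.sigma, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def ld_from_genotypes(
    genotypes: np.ndarray, snp_ids: list[str], ridge: float = 0.0
) -> LdPanel:
    """Pearson correlation of genotype columns (sample x SNP).

    ``ridge`` shrinks off-diagonals toward zero via (Sigma + ridge*I)/(1+ridge),
    a convex combination that keeps the unit diagonal; useful when the panel
    has fewer samples than SNPs.
    """
    geno = np.asarray(genotypes, dtype=float)
    if geno.ndim != 2 or geno.shape[1] != len(snp_ids):
        raise ValidationError("genotypes must be sample x SNP matching snp_ids")
    if geno.shape[0] < 2:
        raise ValidationError("need at least 2 samples to estimate LD")
    sd = geno.std(axis=0)
    if np.any(sd == 0):
        bad = [snp_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValidationError(f"monomorphic SNP(s): {bad}")
    centered = (geno - geno.mean(axis=0)) / sd
    sigma = centered.T @ centered / geno.shape[0]
    if ridge:
        sigma = (sigma + ridge * np.eye(sigma.shape[0])) / (1.0 + ridge)
    np.clip(sigma, -1.0, 1.0, out=sigma)
    sigma = (sigma + sigma.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    return LdPanel(snp_ids=list(snp_ids), sigma=sigma)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read gene sets in GMT format: ``set_id \\t description \\t genes...``."""
    set_ids: list[str] = []
    members: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields"
                )
            sid, desc, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "%s:%d: set %s contains duplicate genes; deduplicated",
                    path,
                    lineno,
                    sid,
                )
            if sid in members:
                raise ValidationError(f"{path}:{lineno}: duplicate set id {sid!r}")
            set_ids.append(sid)
            members[sid] = unique
            descriptions[sid] = desc
    return GeneSetCollection(set_ids=set_ids, members=members, descriptions=descriptions)


def write_gmt(sets: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sid in sets.set_ids:
            desc = sets.descriptions.get(sid, "na") or "na"
            fh.write("\t".join([sid, desc, *sets.members[sid]]) + "\n")


# ---------------------------------------------------------------------------
# Expression and phenotype


def read_expression(
    path: str | os.PathLike, phenotype_path: str | os.PathLike | None = None
) -> ExpressionDataset:
    """Read a gene x sample expression matrix and optionally join a phenotype.

    Phenotype samples are matched by id to expression columns; samples present
    in only one of the two files are dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    gene_ids = list(df.index.astype(str))
    sample_ids = list(df.columns.astype(str))
    values = df.to_numpy(float)
    phenotype = None
    if phenotype_path is not None:
        ph = pd.read_csv(phenotype_path, sep="\t", float_precision="round_trip")
        for col in ("SAMPLE", "VALUE"):
            if col not in ph.columns:
                raise FormatError(f"{phenotype_path}: missing column {col!r}")
        ph = ph.set_index(ph["SAMPLE"].astype(str))["VALUE"]
        keep = [s for s in sample_ids if s in ph.index]
        if not keep:
            raise ValidationError(
                f"{phenotype_path}: no samples overlap the expression matrix"
            )
        dropped = (len(sample_ids) - len(keep)) + (len(ph) - len(keep))
        if dropped:
            logger.warning(
                "dropped %d unmatched sample(s) joining phenotype to expression",
                dropped,
            )
        col_idx = [sample_ids.index(s) for s in keep]
        values = values[:, col_idx]
        sample_ids = keep
        phenotype = ph.loc[keep].to_numpy(float)
    return ExpressionDataset(
        gene_ids=gene_ids, sample_ids=sample_ids, values=values, phenotype=phenotype
    )


def write_expression(
    data: ExpressionDataset,
    path: str | os.PathLike,
    phenotype_path: str | os.PathLike | None = None,
) -> None:
    df = pd.DataFrame(data.values, index=data.gene_ids, columns=data.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")
    if phenotype_path is not None:
        if data.phenotype is None:
            raise ValidationError("dataset has no phenotype to write")
        pd.DataFrame({"SAMPLE": data.sample_ids, "VALUE": data.phenotype}).to_csv(
            phenotype_path, sep="\t", index=False, float_format="%.17g"
        )


# ---------------------------------------------------------------------------
# Enrichment results


def write_enrichment_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an enrichment table sorted by ascending p-value (ties by set_id)."""
    cols = [c for c in ENRICHMENT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra].sort_values(
        ["p_value", "set_id"], kind="stable", na_position="last"
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_enrichment_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Identifier alignment


def align_summary_inputs(
    weights: EqtlWeightSet, gwas: GwasSummary, ld: LdPanel
) -> tuple[EqtlWeightSet, GwasSummary, LdPanel]:
    """Restrict weights, summary statistics and LD panel to shared SNPs.

    SNPs present in the weights but absent from the LD panel or summary
    statistics are dropped with a logged count; genes losing all nonzero
    weights are excluded with a warning.  Output SNP order follows the weight
    set; downstream matrices are therefore invariant to input row order.
    """
    in_gwas = set(gwas.snp_ids)
    in_ld = set(ld.snp_ids)
    keep = [s for s in weights.snp_ids if s in in_gwas and s in in_ld]
    dropped = len(weights.snp_ids) - len(keep)
    if dropped:
        logger.warning("dropped %d SNP(s) absent from sumstats or LD panel", dropped)
    if not keep:
        raise ValidationError("no SNPs shared between weights, sumstats and LD panel")
    w_pos = {s: i for i, s in enumerate(weights.snp_ids)}
    w_rows = [w_pos[s] for s in keep]
    sub_w = weights.weights[w_rows, :]
    gene_keep = np.flatnonzero(np.any(sub_w != 0, axis=0))
    if len(gene_keep) < len(weights.gene_ids):
        lost = [weights.gene_ids[i] for i in range(len(weights.gene_ids)) if i not in set(gene_keep)]
        logger.warning("excluded %d gene(s) with no remaining weights: %s", len(lost), lost[:5])
    if gene_keep.size == 0:
        raise ValidationError("no genes retain nonzero weights after SNP alignment")
    aligned_w = EqtlWeightSet(
        snp_ids=keep,
        gene_ids=[weights.gene_ids[i] for i in gene_keep],
        weights=sub_w[:, gene_keep],
    )
    g_pos = {s: i for i, s in enumerate(gwas.snp_ids)}
    aligned_g = GwasSummary(
        snp_ids=keep,
        beta=gwas.beta[[g_pos[s] for s in keep]],
        n_gwas=gwas.n_gwas,
    )
    l_pos = {s: i for i, s in enumerate(ld.snp_ids)}
    rows = [l_pos[s] for s in keep]
    aligned_l = LdPanel(snp_ids=keep, sigma=ld.sigma[np.ix_(rows, rows)])
    return aligned_w, aligned_g, aligned_l
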