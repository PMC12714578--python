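"""Readers and writers for the exchanged tabular formats.

The native exchange format is TSV with documented column schemas; VCF is
accepted for variant ingestion (SNVs only; multi-allelic records are split,
indels skipped with a logged count) and BED for gene coding intervals.
Chromosome names are normalised to the no-"chr" convention internally.
Floats are serialised at 12 significant digits so that write → read round
trips are lossless at analysis precision.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .mutmodel import GeneModel, SITE_COLUMNS

log = logging.getLogger(__name__)

__all__ = [
    "read_sites", "write_sites",
    "read_denovo", "write_denovo",
    "read_popcounts", "write_popcounts",
    "read_genes_bed", "read_loeuf",
    "read_subcohort_counts", "read_shet_prior",
    "write_results",
]

FLOAT_FORMAT = "%.12g"
_SITE_KEY = ["chrom", "pos", "ref", "alt"]


def _norm_chrom(series: pd.Series) -> pd.Series:
    return series.astype(str).str.removeprefix("chr")


def _read_tsv(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    for col in numeric:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = (frame.index[bad] + 2).tolist()
            raise DataError(f"{path}: malformed numeric column {col!r} "
                            f"at line(s) {lines[:5]}")
        frame[col] = coerced
    return frame


def read_sites(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a site (rate) table from TSV or VCF.

    TSV requires the canonical site schema.  VCF records are decomposed into
    biallelic SNVs; annotations are taken from INFO keys matching the schema
    column names; indels are skipped (count logged).
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "tsv":
        frame = _read_tsv(path, SITE_COLUMNS, ["pos", "mu", "am_score"])
        if len(frame):
            frame["chrom"] = _norm_chrom(frame["chrom"])
            frame["pos"] = frame["pos"].astype(int)
            if (frame["pos"] < 1).any():
                raise DataError(f"{path}: positions must be 1-based (>= 1)")
            if (frame["mu"] <= 0).any():
                raise DataError(f"{path}: rates must be positive")
            if (frame["ref"] == frame["alt"]).any():
                raise DataError(f"{path}: ref == alt records")
        if "mu_gen" not in frame.columns:
            frame["mu_gen"] = np.nan
        return frame
    if fmt == "vcf":
        return _read_sites_vcf(path)
    raise DataError(f"unknown site format {fmt!r}")


def _read_sites_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    n_indels = 0
    info_keys = ["gene_id", "consequence", "lof_confidence", "quality",
                 "mu", "am_score", "mu_gen"]
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1:
                n_indels += 1
                continue
            row = {"chrom": str(rec.CHROM).removeprefix("chr"),
                   "pos": int(rec.POS), "ref": rec.REF, "alt": alt}
            for key in info_keys:
                row[key] = rec.INFO.get(key)
            rows.append(row)
    if n_indels:
        log.info("read_sites: skipped %d non-SNV allele(s) in %s", n_indels, path)
    frame = pd.DataFrame(rows, columns=_SITE_KEY + info_keys)
    for col in ("mu", "am_score", "mu_gen"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if frame["mu"].isna().any():
        raise DataError(f"{path}: VCF records missing the INFO mu field")
    return frame


def write_sites(frame: pd.DataFrame, path) -> None:
    cols = [c for c in SITE_COLUMNS + ["mu_gen"] if c in frame.columns]
    frame.to_csv(path, sep="\t", index=False, columns=cols,
                 float_format=FLOAT_FORMAT)


def read_denovo(path) -> pd.DataFrame:
    """Read a de novo count table (chrom, pos, ref, alt, n).

    An empty file yields an empty (zero-count) table; duplicate site rows
    are an error.
    """
    frame = _read_tsv(path, _SITE_KEY + ["n"], ["pos", "n"])
    if len(frame) == 0:
        return pd.DataFrame(columns=_SITE_KEY + ["n"])
    frame["chrom"] = _norm_chrom(frame["chrom"])
    if frame.duplicated(subset=_SITE_KEY).any():
        dup = frame.loc[frame.duplicated(subset=_SITE_KEY), _SITE_KEY]
        raise DataError(f"{path}: duplicate site rows, e.g. "
                        f"{dup.iloc[0].tolist()}")
    if (frame["n"] < 0).any():
        raise DataError(f"{path}: negative counts")
    frame["n"] = frame["n"].astype(int)
    return frame


def write_denovo(sites: pd.DataFrame, counts: pd.Series, path,
                 keep_zeros: bool = False) -> None:
    out = sites[_SITE_KEY].copy()
    out["n"] = counts.reindex(sites.index).fillna(0).astype(int).to_numpy()
    if not keep_zeros:
        out = out[out["n"] > 0]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_popcounts(path) -> pd.DataFrame:
    """Read a population allele-count table (gnomAD-style: site, AC, AN)."""
    frame = _read_tsv(path, _SITE_KEY + ["AC", "AN"], ["pos", "AC", "AN"])
    if len(frame) == 0:
        return pd.DataFrame(columns=_SITE_KEY + ["AC", "AN"])
    frame["chrom"] = _norm_chrom(frame["chrom"])
    if frame.duplicated(subset=_SITE_KEY).any():
        raise DataError(f"{path}: duplicate site rows")
    if (frame["AC"] < 0).any() or (frame["AN"] <= 0).any():
        raise DataError(f"{path}: AC must be >= 0 and AN positive")
    if (frame["AC"] > frame["AN"]).any():
        raise DataError(f"{path}: AC exceeds AN")
    return frame


def write_popcounts(pop: pd.DataFrame, path) -> None:
    out = pop.rename(columns={"k": "AC", "n_chrom": "AN"})
    cols = [c for c in _SITE_KEY + ["gene_id", "quality", "mu", "mu_gen",
                                    "AC", "AN"] if c in out.columns]
    out.to_csv(path, sep="\t", index=False, columns=cols,
               float_format=FLOAT_FORMAT)


def join_popcounts(pop: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Join an allele-count table to the rate table on the site key."""
    extra = [c for c in ("gene_id", "quality", "mu", "mu_gen", "consequence",
                         "lof_confidence") if c in sites.columns]
    annotated = pop.merge(sites[_SITE_KEY + extra], on=_SITE_KEY,
                          how="inner", validate="one_to_one")
    out = annotated.rename(columns={"AC": "k", "AN": "n_chrom"})
    return out


def read_genes_bed(path) -> list[GeneModel]:
    """Read gene CDS intervals from BED (chrom, start, end, gene_id)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{ln}: BED needs 4 columns "
                                "(chrom, start, end, gene_id)")
            chrom, start, end, gid = parts[:4]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: malformed coordinates") from exc
            intervals.setdefault(gid, []).append(
                (chrom.removeprefix("chr"), s, e))
    return [GeneModel(gene_id=gid, cds_intervals=ivals)
            for gid, ivals in sorted(intervals.items())]


def read_loeuf(path) -> pd.Series:
    frame = _read_tsv(path, ["gene_id", "loeuf"], ["loeuf"])
    if frame.duplicated(subset=["gene_id"]).any():
        raise DataError(f"{path}: duplicate gene_id rows")
    return frame.set_index("gene_id")["loeuf"]


def read_shet_prior(path) -> pd.Series:
    frame = _read_tsv(path, ["gene_id", "s_het_prior"], ["s_het_prior"])
    if frame.duplicated(subset=["gene_id"]).any():
        raise DataError(f"{path}: duplicate gene_id rows")
    return frame.set_index("gene_id")["s_het_prior"]


def read_subcohort_counts(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read per-gene × subcohort counts; the row with gene_id
    ``__synonymous__`` carries the per-subcohort synonymous totals."""
    frame = _read_tsv(path, ["gene_id"], [])
    cohort_cols = [c for c in frame.columns if c != "gene_id"]
    if not cohort_cols:
        raise DataError(f"{path}: no subcohort columns")
    syn_row = frame["gene_id"] == "__synonymous__"
    if not syn_row.any():
        raise DataError(f"{path}: missing __synonymous__ totals row")
    syn = frame.loc[syn_row, cohort_cols].iloc[0].to_numpy(dtype=float)
    counts = frame.loc[~syn_row].set_index("gene_id")[cohort_cols]
    return counts, syn


def write_results(obj, path) -> None:
    """Write a tidy result: DataFrames to TSV, mappings to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                   index=obj.index.name is not None)
        return
    import json

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            v = float(o)
            return v if math.isfinite(v) else str(v)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default, sort_keys=True)
        fh.write("\n")
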