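"""Readers and writers for the plain-text formats the pipeline exchanges.

Count tables, factor matrices, genotype dosages, and metadata travel as
TSV; QC reports, fit reports, and provenance as JSON; genotypes can also
be read from VCF (GT field) or written as a minimal VCF.  Taxonomy maps
accept either a two-column TSV (feature, genus) or QIIME-style
seven-rank lineage strings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CountTable, GenotypeMatrix, RelAbundanceMatrix

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "parse_lineage",
    "read_metadata",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "write_json",
    "read_json",
]

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")
_GENUS_PREFIX = "g__"


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_count_table(
    path,
    taxonomy: dict | None = None,
    orientation: str = "auto",
    known_sample_ids=None,
) -> CountTable:
    """Read a feature x sample count table from TSV/CSV.

    ``orientation`` is ``"features"`` (features in rows), ``"samples"``
    (transposed), or ``"auto"``: if ``known_sample_ids`` (e.g. from a
    metadata table) overlap the row index better than the columns, the
    table is transposed.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples":
        df = df.T
    elif orientation == "auto" and known_sample_ids is not None:
        ids = set(map(str, known_sample_ids))
        row_hits = sum(str(i) in ids for i in df.index)
        col_hits = sum(str(c) in ids for c in df.columns)
        if row_hits > col_hits:
            df = df.T
    counts = df.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("count table contains non-integer values")
    return CountTable.from_frame(df.astype(np.int64), taxonomy=taxonomy)


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="feature_id")


def parse_lineage(lineage: str) -> str:
    """Genus from a semicolon-separated lineage string.

    Rank prefixes like ``g__`` are stripped; if the genus rank is missing
    or empty the result is ``unclassified:<highest resolved rank>``.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    genus = ""
    last_resolved = ""
    for p in parts:
        name = p
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                name = p[len(pref) :]
                break
        if p.startswith(_GENUS_PREFIX):
            genus = name
        if name:
            last_resolved = name
    if genus:
        return genus
    if not any(p.startswith(_GENUS_PREFIX) for p in parts) and parts and parts[-1]:
        # plain name list without rank prefixes: last element is the genus
        return parts[-1]
    return f"unclassified:{last_resolved}" if last_resolved else "unclassified"


def read_taxonomy(path) -> dict:
    """Feature -> genus map from a two-column TSV.

    The second column may be a bare genus name or a QIIME lineage string.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs two columns: feature, genus/lineage")
    if df.iloc[0, 0].lower() in {"feature", "feature_id", "asv", "otu"}:
        df = df.iloc[1:]
    out = {}
    for fid, tax in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out[str(fid)] = parse_lineage(tax) if ";" in str(tax) else str(tax)
    return out


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix, path, index_label: str = "id") -> None:
    if isinstance(matrix, RelAbundanceMatrix):
        matrix = matrix.to_frame()
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Individuals x SNPs dosage matrix; empty/NA cells are missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=float),
        snp_ids=list(df.columns),
        individual_ids=list(df.index),
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.individual_ids, columns=geno.snp_ids)
    df.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Dosages (ALT allele count) from the GT field of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individual_ids = list(vcf.samples)
    snp_ids, rows = [], []
    for i, var in enumerate(vcf):
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan
        rows.append(g)
    vcf.close()
    return GenotypeMatrix(
        dosages=np.array(rows).T,
        snp_ids=snp_ids,
        individual_ids=individual_ids,
    )


def write_genotypes_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal diploid VCF 4.2 with GT-only records on a single contig."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        for j, sid in enumerate(geno.snp_ids):
            calls = [
                "./." if not np.isfinite(d) else gt_map[int(round(d))]
                for d in geno.dosages[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
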