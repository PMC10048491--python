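"""Standard-format I/O, gene lookup and report exports.

VCF v4.2 (GT-only) in and out, TSV summary statistics, GFF3/BED gene
annotation, BED export of QTL regions, Manhattan plot data and the
Table-style top-SNP summary. All internal coordinates are 1-based
inclusive; only the BED reader/writer converts to and from 0-based
half-open.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix
from .simdata import SimConfig
from .thresholds_qtl import QTLRegion

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# VCF
def read_vcf(path) -> GenotypeMatrix:
    """Read genotype dosages (GT field) from a VCF into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = np.array(vcf.samples)
    rows = []
    dosages = []
    for v in vcf:
        rows.append(
            {
                "id": v.ID if v.ID not in (None, ".") else f"var_{v.CHROM}_{v.POS}",
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": ",".join(v.ALT) if v.ALT else ".",
            }
        )
        gt = v.gt_types.astype(np.float32)
        gt[gt == 3] = np.nan
        dosages.append(gt)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosage = (
        np.stack(dosages, axis=1)
        if dosages
        else np.empty((len(ids), 0), dtype=np.float32)
    )
    logger.info("read VCF %s: %d samples x %d variants", path, len(ids), len(rows))
    return GenotypeMatrix(ids=ids, variants=variants, dosage=dosage)


_GT_CODES = np.array(["0/0", "0/1", "1/1"])


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF v4.2 (biallelic records only).

    Dosages oriented to the minor allele are converted back to ALT counts so
    a read/write round trip is lossless.
    """
    variants = geno.variants
    if variants["alt"].astype(str).str.contains(",").any():
        raise ValueError("VCF writer supports biallelic records only")
    dosage = geno.dosage
    if geno.counted == "minor":
        flip = (variants["minor_allele"] != variants["alt"]).to_numpy()
        dosage = dosage.copy()
        dosage[:, flip] = 2.0 - dosage[:, flip]

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["chrom"]):
            length = int(variants.loc[variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, geno.ids))
            + "\n"
        )
        missing = np.isnan(dosage)
        codes = np.where(missing, 0, dosage).astype(int)
        for j in range(geno.n_variants):
            gt = _GT_CODES[codes[:, j]].copy()
            gt[missing[:, j]] = "./."
            row = variants.iloc[j]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gt) + "\n"
            )
    logger.info("wrote VCF %s (%d variants)", path, geno.n_variants)


# ----------------------------------------------------------------------
# gene annotation
GENE_COLUMNS = ["gene_id", "name", "chrom", "start", "stop", "strand"]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records (type == "gene") from a GFF3 file; 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", "").removeprefix("gene:")
            rows.append(
                {
                    "gene_id": gid or attrs.get("Name", "?"),
                    "name": attrs.get("Name", gid),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "stop": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def read_bed_genes(path) -> pd.DataFrame:
    """Gene records from BED (0-based half-open -> 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}"
            rows.append(
                {
                    "gene_id": name,
                    "name": name,
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "stop": int(parts[2]),
                    "strand": parts[5] if len(parts) > 5 else "+",
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def genes_in_region(region: QTLRegion, annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping the region core by >= 1 bp, ordered by start.

    Overlap is inclusive on both ends and ignores strand.
    """
    if annotation.empty:
        warnings.warn("empty gene annotation; no genes reported")
        return annotation.copy()
    hit = (
        (annotation["chrom"].astype(str) == str(region.chrom))
        & (annotation["start"] <= region.stop)
        & (annotation["stop"] >= region.start)
    )
    return annotation.loc[hit].sort_values("start").reset_index(drop=True)


# ----------------------------------------------------------------------
# QTL region export
def regions_to_bed(regions, path=None) -> pd.DataFrame:
    """QTL cores as BED (0-based half-open). Returns the frame; optionally writes."""
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.stop for r in regions],
            "name": [f"qtl_{r.chrom}_{r.start}" for r in regions],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


def regions_from_bed(path) -> list:
    """Read QTL cores back from BED into minimal QTLRegion objects."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(
                QTLRegion(
                    chrom=chrom,
                    start=int(start) + 1,
                    stop=int(end),
                    display_start=max(1, int(start) + 1 - 100_000),
                    display_stop=int(end) + 100_000,
                    members=(),
                )
            )
    return out


def regions_table(regions, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summary table of QTL regions (top SNPs, bounds, length, genes)."""
    rows = []
    for r in regions:
        genes = ""
        n_genes = 0
        if annotation is not None and not annotation.empty:
            hits = genes_in_region(r, annotation)
            genes = ",".join(hits["name"].astype(str))
            n_genes = len(hits)
        for trait, (vid, pos, nlp) in sorted(r.top_snp.items()):
            rows.append(
                {
                    "trait": trait,
                    "top_snp": vid,
                    "chrom": r.chrom,
                    "top_pos": pos,
                    "qtl_start": r.start,
                    "qtl_stop": r.stop,
                    "length_mb": round(r.length_mb, 2),
                    "n_variants": r.n_variants,
                    "neg_log10_p": nlp,
                    "genes": genes,
                    "n_genes": n_genes,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# plot-ready exports
def export_manhattan(
    assoc: pd.DataFrame,
    thresholds: dict,
    out_tsv=None,
    figure_path=None,
) -> pd.DataFrame:
    """Manhattan plot data: cumulative coordinate, -log10 p, parity color key.

    ``thresholds`` maps alpha -> Threshold. Threshold rows are appended with
    ``row_type == "threshold"``.
    """
    chroms = list(dict.fromkeys(assoc["chrom"]))
    offsets = {}
    offset = 0
    for c in chroms:
        offsets[c] = offset
        offset += int(assoc.loc[assoc["chrom"] == c, "pos"].max())
    df = assoc.copy()
    df["cum_pos"] = df["pos"] + df["chrom"].map(offsets)
    df["color_key"] = df["chrom"].map({c: i % 2 for i, c in enumerate(chroms)})
    df["row_type"] = "variant"
    thr_rows = pd.DataFrame(
        {
            "row_type": "threshold",
            "alpha": [t.alpha for t in thresholds.values()],
            "neg_log10_p": [t.neg_log10_p for t in thresholds.values()],
        }
    )
    out = pd.concat([df, thr_rows], ignore_index=True)
    if out_tsv is not None:
        out.to_csv(out_tsv, sep="\t", index=False, float_format="%.6g")
    if figure_path is not None:
        _manhattan_figure(df, thresholds, figure_path)
    return out


def _manhattan_figure(df, thresholds, path):  # pragma: no cover - plumbing
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for key, color in ((0, "#33577b"), (1, "#8aa6c1")):
        sub = df.loc[df["color_key"] == key]
        ax.scatter(sub["cum_pos"], sub["neg_log10_p"], s=4, c=color)
    styles = {0.1: ":", 0.05: "-", 0.01: "--"}
    for alpha, t in thresholds.items():
        ax.axhline(t.neg_log10_p, ls=styles.get(alpha, "-"), c="grey", lw=1)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


TOP_SNP_COLUMNS = [
    "Trait", "rsID", "Chr", "Position", "MA", "MAF", "beta", "SE",
    "neg_log10_p",
]


def top_snp_table(assoc: pd.DataFrame, regions) -> pd.DataFrame:
    """Per (trait, region) top-SNP rows in the standard report layout."""
    lookup = assoc.set_index(["variant_id", "trait"])
    rows = []
    for r in regions:
        for trait, (vid, pos, nlp) in sorted(r.top_snp.items()):
            rec = lookup.loc[(vid, trait)]
            rows.append(
                {
                    "Trait": trait,
                    "rsID": vid,
                    "Chr": r.chrom,
                    "Position": pos,
                    "MA": rec["minor_allele"],
                    "MAF": rec["maf"],
                    "beta": rec["beta"],
                    "SE": rec["se"],
                    "neg_log10_p": nlp,
                }
            )
    return pd.DataFrame(rows, columns=TOP_SNP_COLUMNS)


# ----------------------------------------------------------------------
# config and tables
def load_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(raw)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
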