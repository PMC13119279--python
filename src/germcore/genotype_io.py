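"""Readers/writers: VCF genotypes, phenotype/population tables, Newick trees.

Only a VCFv4.2 subset is supported: biallelic SNP records with a GT sample
field.  Multiallelic and non-SNP records are skipped (and counted), INFO
annotations are read when present, contig lengths come from ``##contig``
header lines (a layout override may be supplied downstream).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    ANNOTATION_FIELDS,
    FormatError,
    GenomeLayout,
    GenotypeMatrix,
    new_variant_table,
    validate_phenotypes,
)

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


@dataclass
class VcfReadReport:
    """Bookkeeping for a VCF read: retained + skipped record counts."""

    n_records: int = 0
    n_retained: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_multiallelic + self.n_skipped_non_snp


def read_vcf(
    path: str, contig_filter: Optional[Iterable[str]] = None
) -> Tuple[GenotypeMatrix, pd.DataFrame, GenomeLayout, VcfReadReport]:
    """Load biallelic SNPs from a VCF into the in-memory data model.

    Dosage is the ALT-allele count per diploid call; ``./.`` and half-calls
    become NaN.  Returns the genotype matrix, its variant table, a genome
    layout built from header contig lengths (empty if absent), and a read
    report with skip counters.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: no samples (GT field required)")
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate accession IDs in header")

    lengths = {}
    try:
        for name, ln in zip(vcf.seqnames, vcf.seqlens):
            lengths[name] = int(ln)
    except (AttributeError, Exception):  # header without contig lengths
        lengths = {}

    report = VcfReadReport()
    rows = []
    dosage_rows = []
    keep = None if contig_filter is None else set(contig_filter)
    for var in vcf:
        report.n_records += 1
        if keep is not None and var.CHROM not in keep:
            continue
        if len(var.ALT) != 1:
            report.n_skipped_multiallelic += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            report.n_skipped_non_snp += 1
            continue
        if "GT" not in (var.FORMAT or []):
            raise FormatError(f"{path}: record {var.CHROM}:{var.POS} lacks GT")
        gts = var.genotypes
        dose = np.full(len(samples), np.nan)
        for i, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                dose[i] = alleles[0] + alleles[1]
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": ref,
            "alt": alt,
            "qual": np.nan if var.QUAL is None else float(var.QUAL),
        }
        for ann in ANNOTATION_FIELDS:
            val = var.INFO.get(ann)
            row[ann] = np.nan if val is None else float(val)
        rows.append(row)
        dosage_rows.append(dose)
    report.n_retained = len(rows)
    if not rows:
        raise FormatError(f"{path}: no biallelic SNP records retained")
    sites = new_variant_table(rows)
    dosages = np.column_stack(dosage_rows) if dosage_rows else np.empty((len(samples), 0))
    geno = GenotypeMatrix(samples, dosages, sites)
    layout = GenomeLayout({c: L for c, L in lengths.items() if c in set(sites["chrom"])})
    log.info(
        "read %d records from %s: retained %d, skipped %d",
        report.n_records, path, report.n_retained, report.n_skipped,
    )
    return geno, sites, layout, report


_VCF_FLOAT_FMT = "%.6g"


def write_vcf(path: str, geno: GenotypeMatrix, layout: Optional[GenomeLayout] = None) -> None:
    """Write the genotype matrix back out as minimal VCFv4.2 text.

    Round-trips losslessly through :func:`read_vcf` for dosages, positions
    and annotations (at 6 significant digits).
    """
    sites = geno.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if layout is not None:
            for chrom, ln in layout.to_dict().items():
                fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        for ann in ANNOTATION_FIELDS:
            fh.write(f'##INFO=<ID={ann},Number=1,Type=Float,Description="{ann}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.accession_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(geno.n_sites):
            row = sites.iloc[j]
            qual = "." if np.isnan(row["qual"]) else _VCF_FLOAT_FMT % row["qual"]
            info_parts = [
                f"{ann}={_VCF_FLOAT_FMT % row[ann]}"
                for ann in ANNOTATION_FIELDS
                if not np.isnan(row[ann])
            ]
            info = ";".join(info_parts) if info_parts else "."
            gts = "\t".join(
                gt_map.get(d, "./.") for d in geno.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t{info}\tGT\t{gts}\n"
            )


def _read_delimited(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_tables(pheno_path: str, popmap_path: str) -> Tuple[pd.DataFrame, pd.Series]:
    """Read the phenotype table and the accession -> population map.

    Both are delimited text with a header whose first column identifies the
    accession.  IDs are cross-checked; accessions present in one table but
    not the other trigger a warning listing the offenders.
    """
    pheno = _read_delimited(pheno_path)
    pheno = pheno.set_index(pheno.columns[0])
    pheno.index = pheno.index.astype(str)
    pheno = validate_phenotypes(pheno)

    pops = _read_delimited(popmap_path)
    if pops.shape[1] < 2:
        raise FormatError(f"{popmap_path}: expected accession and population columns")
    popmap = pops.set_index(pops.columns[0]).iloc[:, 0].astype(str)
    popmap.index = popmap.index.astype(str)
    if popmap.index.has_duplicates:
        dups = popmap.index[popmap.index.duplicated()].unique().tolist()
        raise FormatError(f"{popmap_path}: duplicate accessions {dups[:5]}")

    only_pheno = sorted(set(pheno.index) - set(popmap.index))
    only_pop = sorted(set(popmap.index) - set(pheno.index))
    if only_pheno:
        warnings.warn(f"accessions only in phenotype table: {only_pheno}")
    if only_pop:
        warnings.warn(f"accessions only in population map: {only_pop}")
    return pheno, popmap


_NEEDS_QUOTE = re.compile(r"[\s,:;()\[\]']")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick text.

    Branch lengths are written with Python float ``repr`` (shortest exact
    form, always >= 6 significant digits of fidelity); labels containing
    Newick metacharacters are single-quoted.  Raises on duplicate leaf
    labels.
    """
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon is not None]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in tree")

    def render(node: dendropy.Node) -> str:
        if node.is_leaf():
            name = node.taxon.label if node.taxon is not None else (node.label or "")
            out = _quote_label(name)
        else:
            out = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
            if node.label:
                out += _quote_label(node.label)
        if node.edge.length is not None and node.parent_node is not None:
            out += f":{float(node.edge.length)!r}"
        return out

    return render(tree.seed_node) + ";"


def read_newick(text: str) -> dendropy.Tree:
    """Parse Newick text into a dendropy tree (round-trip of write_newick)."""
    return dendropy.Tree.get(data=text, schema="newick")
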