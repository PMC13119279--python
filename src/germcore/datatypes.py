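"""In-memory data model shared by all pipeline stages.

Genotypes are stored as an accessions x sites dosage matrix (count of ALT
alleles, 0/1/2) with ``numpy.nan`` as the missing-call sentinel.  Per-site
metadata travels alongside in a :class:`pandas.DataFrame` (the "variant
table"); chromosome lengths live in a :class:`GenomeLayout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

#: INFO annotations consumed by the hard filter (absent values stay NaN).
ANNOTATION_FIELDS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

#: Canonical variant-table columns.
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "qual") + ANNOTATION_FIELDS

#: The four measured traits, in report order.
TRAITS = ("BNMS", "NNMS", "SD", "PH")


class GermcoreError(Exception):
    """Base class for pipeline errors."""


class FormatError(GermcoreError):
    """A malformed or unsupported input file."""


def new_variant_table(records: Iterable[dict] | pd.DataFrame | None = None) -> pd.DataFrame:
    """Build a variant table with the canonical column set and dtypes."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records) if records is not None else [])
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(VARIANT_COLUMNS)]
    if len(df):
        df["pos"] = df["pos"].astype(np.int64)
        if (df["pos"] < 1).any():
            raise FormatError("variant positions must be >= 1")
        if (df["ref"] == df["alt"]).any():
            raise FormatError("ref and alt alleles must differ")
    for col in ("qual",) + ANNOTATION_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return df.reset_index(drop=True)


@dataclass
class GenomeLayout:
    """Chromosome name -> length in bp."""

    lengths: Dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for contig {chrom!r}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def to_dict(self) -> Dict[str, int]:
        return dict(self.lengths)


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic-SNP dosage matrix with site metadata.

    ``dosages`` holds ALT-allele counts as floats so that missing calls can
    be NaN; every non-missing entry must be 0, 1 or 2.
    """

    accession_ids: List[str]
    dosages: np.ndarray
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.accession_ids = list(self.accession_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise FormatError("duplicate accession IDs")
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if self.dosages.shape[0] != len(self.accession_ids):
            raise ValueError("row count does not match accession count")
        if self.dosages.shape[1] != len(self.sites):
            raise ValueError("site count does not match variant table length")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def accession_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise KeyError(f"unknown accession IDs: {missing[:5]}")
        return np.array([lookup[a] for a in ids], dtype=int)

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx], self.dosages[idx], self.sites
        )

    def subset_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(
            self.accession_ids,
            self.dosages[:, arr],
            self.sites.iloc[arr].reset_index(drop=True),
        )


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table: unique accession index, positive numeric traits."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate accessions in phenotype table: {dups[:5]}")
    for col in table.columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()]
        if len(bad):
            raise FormatError(
                f"non-numeric value for trait {col!r} at accession {bad[0]!r}"
            )
        table[col] = vals.astype(float)
    return table
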