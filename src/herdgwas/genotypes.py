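"""In-memory genotype container shared by every pipeline stage.

A :class:`GenotypeMatrix` holds an individuals x variants dosage matrix
(``float32``; ``NaN`` marks a missing call) together with ordered variant
metadata. Before variant QC the dosage counts copies of the ALT allele; after
QC (:func:`herdgwas.genotype_qc.filter_variants`) it counts copies of the
minor allele and the metadata gains ``minor_allele`` / ``maf`` columns.

Coordinates are 1-based inclusive (VCF convention) throughout the package;
only the BED writer converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: required variant metadata columns, in order
VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor/alt-allele dosage matrix with metadata.

    Parameters
    ----------
    ids
        Ordered individual identifiers, shape ``(n,)``.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (``alt`` holds a
        comma-joined string for multi-allelic records). Positions must be
        strictly increasing within each chromosome.
    dosage
        ``(n, m)`` float array of allele counts in ``{0, 1, 2}`` with ``NaN``
        for missing calls.
    counted
        Which allele the dosage counts: ``"alt"`` (raw input) or ``"minor"``
        (after QC orientation).
    """

    ids: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray
    counted: str = "alt"
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosage = np.asarray(self.dosage)
        if not self.validate:
            return
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x variants)")
        n, m = self.dosage.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids but {n} dosage rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variants but {m} dosage columns")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        if self.counted not in ("alt", "minor"):
            raise ValueError("counted must be 'alt' or 'minor'")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same_chrom = chrom[1:] == chrom[:-1]
        if np.any(same_chrom & (np.diff(pos) <= 0)):
            bad = int(np.nonzero(same_chrom & (np.diff(pos) <= 0))[0][0])
            raise ValueError(
                f"positions not strictly increasing within chromosome near "
                f"{chrom[bad]}:{pos[bad]}"
            )
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")
        self.variants = self.variants.reset_index(drop=True)

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.variants["chrom"]))

    # ------------------------------------------------------------------
    def subset_variants(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given variant positions/boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return replace(
            self,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            validate=False,
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        """New matrix restricted to the given individual ids (in that order)."""
        lookup = {v: i for i, v in enumerate(self.ids)}
        missing = [str(v) for v in ids if v not in lookup]
        if missing:
            raise KeyError(f"individuals absent from genotype matrix: {missing[:5]}")
        rows = np.array([lookup[v] for v in ids])
        return replace(
            self, ids=self.ids[rows], dosage=self.dosage[rows], validate=False
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            ids=self.ids.copy(),
            variants=self.variants.copy(),
            dosage=self.dosage.copy(),
            validate=False,
        )
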