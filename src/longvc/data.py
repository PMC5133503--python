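"""In-memory containers for phenotypes, genotypes, and genomic regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LongitudinalPhenotypes", "GenotypeMatrix", "RegionSpec"]


@dataclass
class LongitudinalPhenotypes:
    """Repeated measurements of one quantitative trait plus covariates.

    ``values`` is (n_individuals, k) with NaN marking a missing visit.
    ``covariates`` is indexed by individual id and holds per-individual
    (not per-visit) covariates: age at the first visit, a 0/1 sex
    indicator (1 = female), a 0/1 smoking indicator, and any extras.
    """

    ids: list[str]
    trait: str
    values: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != len(self.ids):
            raise ValueError("values rows must match number of ids")
        self.covariates = self.covariates.loc[self.ids]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n(self) -> int:
        return len(self.ids)

    def visit_mean(self) -> np.ndarray:
        """Per-individual mean over non-missing visits (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def to_frame(self) -> pd.DataFrame:
        wide = pd.DataFrame(
            self.values,
            index=pd.Index(self.ids, name="id"),
            columns=[f"{self.trait}_{t + 1}" for t in range(self.k)],
        )
        return pd.concat([wide, self.covariates], axis=1)


@dataclass
class GenotypeMatrix:
    """Additive dosages (ALT-allele counts) for biallelic SNVs.

    ``dosages`` is (n_individuals, n_variants) in {0, 1, 2, NaN}.
    ``variants`` has columns chrom, pos (1-based), id, ref, alt, af where
    ``af`` is the ALT frequency among non-missing calls.
    """

    ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.variants)):
            raise ValueError("dosage matrix shape mismatch")
        if "af" not in self.variants.columns:
            self.variants = self.variants.assign(af=self.allele_frequencies())
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def dosage(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) == 0:
            raise KeyError(f"unknown variant id {variant_id!r}")
        return self.dosages[:, int(j[0])]

    def in_region(self, region: "RegionSpec") -> "GenotypeMatrix":
        v = self.variants
        mask = (
            (v["chrom"].astype(str) == str(region.chrom))
            & (v["pos"] - 1 >= region.start)
            & (v["pos"] - 1 < region.end)
        )
        keep = np.nonzero(mask.to_numpy())[0]
        return GenotypeMatrix(
            self.ids, v.iloc[keep].reset_index(drop=True), self.dosages[:, keep]
        )


@dataclass(frozen=True)
class RegionSpec:
    """Half-open, zero-based genomic interval with a label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"region start must precede end (got {self.start}..{self.end})"
            )

    @classmethod
    def from_string(cls, text: str, label: str = "") -> "RegionSpec":
        """Parse ``chrom:start-end`` with 1-based inclusive coordinates."""
        chrom, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        return cls(chrom, int(lo) - 1, int(hi), label or text)
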