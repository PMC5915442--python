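"""In-memory containers for phased variant panels and allele-count tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "ancestral", "derived"]
SAMPLE_COLUMNS = ["sample", "dataset", "region"]


@dataclass
class HaplotypePanel:
    """Phased diploid panel polarized to derived-allele orientation.

    Attributes
    ----------
    sites:
        One row per biallelic site: ``chrom``, ``pos`` (1-based),
        ``ancestral``, ``derived`` alleles. Positions strictly increase
        within a chromosome.
    haplotypes:
        ``(n_sites, n_samples, 2)`` int8 array of derived-allele indicators
        per haplotype; genotype = sum over the last axis.
    samples:
        One row per sample: ``sample`` id, ``dataset`` label, ``region``
        label.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if list(self.sites.columns[:4]) != SITE_COLUMNS:
            raise ValueError(f"sites must have columns {SITE_COLUMNS}")
        if self.haplotypes.shape != (len(self.sites), len(self.samples), 2):
            raise ValueError(
                f"haplotype array shape {self.haplotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples x 2"
            )
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype values must be 0/1")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample identifiers")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def genotypes(self) -> np.ndarray:
        """(n_sites, n_samples) derived-allele dosage in {0,1,2}."""
        return self.haplotypes.sum(axis=2, dtype=np.int16)

    def site_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)

    def sample_indices(
        self, subset: list[str] | None = None, dataset: str | None = None
    ) -> np.ndarray:
        """Column indices for a sample-id subset and/or dataset label."""
        mask = np.ones(self.n_samples, dtype=bool)
        if dataset is not None:
            mask &= (self.samples["dataset"] == dataset).to_numpy()
            if not mask.any():
                raise ValueError(f"unknown dataset label {dataset!r}")
        if subset is not None:
            if len(subset) == 0:
                raise ValueError("sample subset is empty")
            known = set(self.samples["sample"])
            missing = [s for s in subset if s not in known]
            if missing:
                raise ValueError(f"unknown samples: {missing[:5]}")
            mask &= self.samples["sample"].isin(subset).to_numpy()
        return np.flatnonzero(mask)

    def daf(
        self, subset: list[str] | None = None, dataset: str | None = None
    ) -> np.ndarray:
        """Derived allele frequency per site over a sample subset."""
        cols = self.sample_indices(subset, dataset)
        if cols.size == 0:
            raise ValueError("empty sample subset")
        counts = self.haplotypes[:, cols, :].sum(axis=(1, 2))
        return counts / (2.0 * cols.size)

    def maf(self, subset: list[str] | None = None) -> np.ndarray:
        d = self.daf(subset)
        return np.minimum(d, 1.0 - d)

    def sfs(self) -> dict[int, int]:
        """Site frequency spectrum: derived-allele count -> number of sites.

        Keys run over 1..2n-1 (segregating classes); monomorphic sites
        contribute nothing. The total equals the polymorphic-site count.
        """
        n_hap = 2 * self.n_samples
        counts = self.haplotypes.sum(axis=(1, 2))
        hist = np.bincount(counts, minlength=n_hap + 1)
        return {k: int(hist[k]) for k in range(1, n_hap)}

    def subset_samples(self, mask_or_ids) -> "HaplotypePanel":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            cols = np.flatnonzero(mask_or_ids)
        elif isinstance(mask_or_ids, np.ndarray):
            cols = mask_or_ids
        else:
            cols = self.sample_indices(list(mask_or_ids))
        if cols.size == 0:
            raise ValueError("empty sample subset")
        return HaplotypePanel(
            sites=self.sites.copy(),
            haplotypes=self.haplotypes[:, cols, :].copy(),
            samples=self.samples.iloc[cols].reset_index(drop=True),
        )

    def flip_polarity(self, site_indices=None) -> "HaplotypePanel":
        """Swap ancestral/derived orientation at the given sites (all by default)."""
        sites = self.sites.copy()
        haps = self.haplotypes.copy()
        if site_indices is None:
            site_indices = np.arange(self.n_sites)
        site_indices = np.asarray(site_indices)
        haps[site_indices] = 1 - haps[site_indices]
        anc = sites.loc[site_indices, "ancestral"].copy()
        sites.loc[site_indices, "ancestral"] = sites.loc[site_indices, "derived"].to_numpy()
        sites.loc[site_indices, "derived"] = anc.to_numpy()
        return HaplotypePanel(sites=sites, haplotypes=haps, samples=self.samples.copy())


@dataclass
class SubpopCountTable:
    """Derived/ancestral allele counts per subpopulation for one variant."""

    variant_id: str
    counts: pd.DataFrame  # index: subpopulation; columns: derived, ancestral

    def __post_init__(self) -> None:
        if list(self.counts.columns) != ["derived", "ancestral"]:
            raise ValueError("counts must have columns ['derived', 'ancestral']")
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("allele counts must be non-negative integers")

    @property
    def total_alleles(self) -> int:
        return int(self.counts.to_numpy().sum())

    def pooled_daf(self) -> float:
        n = self.total_alleles
        if n == 0:
            raise ValueError("table has zero total alleles")
        return float(self.counts["derived"].sum()) / n
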