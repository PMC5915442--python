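"""Singleton/private-doubleton identification and the two pre-scoring filters.

A singleton is a site whose derived allele occurs on exactly one haplotype
within a dataset; a private doubleton carries the derived allele twice, both
copies in the same individual. The gap model downstream treats both as one
mutational event at one position on one individual.

Filtering never deletes catalog rows: entries are flagged with
``retained=False`` and a removal reason (``mask`` or ``density``), so the
catalog cardinality is conserved through the module and provenance stays
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet
from .panel import HaplotypePanel

CATALOG_COLUMNS = ["chrom", "pos", "carrier", "vclass", "dataset", "retained", "reason"]


@dataclass
class SingletonCatalog:
    """Flat table of singleton/private-doubleton events with filter provenance."""

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"catalog missing columns {missing}")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def retained(self, dataset: str | None = None) -> pd.DataFrame:
        df = self.entries
        # to_numpy may be a view of the column; never modify it in place
        mask = df["retained"].to_numpy(dtype=bool).copy()
        if dataset is not None:
            mask &= (df["dataset"] == dataset).to_numpy()
        return df[mask]

    def datasets(self) -> list[str]:
        return sorted(self.entries["dataset"].unique())

    @staticmethod
    def concat(catalogs: list["SingletonCatalog"]) -> "SingletonCatalog":
        return SingletonCatalog(
            pd.concat([c.entries for c in catalogs], ignore_index=True)
        )


def extract_singletons(panel: HaplotypePanel, dataset: str) -> SingletonCatalog:
    """Catalog the AC=1 and same-individual AC=2 derived alleles of one dataset."""
    cols = panel.sample_indices(dataset=dataset)
    haps = panel.haplotypes[:, cols, :]
    ac = haps.sum(axis=(1, 2))
    geno = haps.sum(axis=2)
    sample_ids = panel.samples["sample"].to_numpy()[cols]

    rows: list[tuple] = []
    singles = np.flatnonzero(ac == 1)
    for j in singles:
        carrier = int(np.flatnonzero(geno[j] == 1)[0])
        rows.append(
            (panel.sites.at[j, "chrom"], int(panel.sites.at[j, "pos"]),
             sample_ids[carrier], "singleton")
        )
    doubles = np.flatnonzero(ac == 2)
    for j in doubles:
        hom = np.flatnonzero(geno[j] == 2)
        if hom.size == 1:  # both copies in one individual: private doubleton
            rows.append(
                (panel.sites.at[j, "chrom"], int(panel.sites.at[j, "pos"]),
                 sample_ids[int(hom[0])], "private-doubleton")
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "carrier", "vclass"])
    df["dataset"] = dataset
    df["retained"] = True
    df["reason"] = "none"
    return SingletonCatalog(df[CATALOG_COLUMNS])


def apply_mask(catalog: SingletonCatalog, mask: IntervalSet) -> SingletonCatalog:
    """Flag entries inside the exclusion mask (half-open BED membership)."""
    df = catalog.entries.copy()
    if len(df) and len(mask):
        hit = np.zeros(len(df), dtype=bool)
        for chrom, grp in df.groupby("chrom", sort=False):
            hit[grp.index] = mask.contains_pos1(str(chrom), grp["pos"].to_numpy())
        removed = hit & df["retained"].to_numpy(dtype=bool)
        df.loc[removed, "retained"] = False
        df.loc[removed, "reason"] = "mask"
    return SingletonCatalog(df)


@dataclass
class DensityReport:
    """Per-dataset sliding-window density statistics and removal decisions."""

    window_bp: int
    step_bp: int
    window_counts: pd.DataFrame  # dataset, chrom, start, end, count
    stats: pd.DataFrame  # dataset, mean, sd, threshold, n_windows, n_removed_windows

    def removed_windows(self, dataset: str) -> pd.DataFrame:
        thr = float(self.stats.set_index("dataset").at[dataset, "threshold"])
        wc = self.window_counts
        return wc[(wc["dataset"] == dataset) & (wc["count"] > thr)]


def _enumerate_windows(layout: GenomeLayout, window_bp: int, step_bp: int) -> pd.DataFrame:
    """Windows tiling each chromosome from 0, kept if they intersect any arm."""
    rows = []
    for chrom, length in layout.chromosomes:
        arms = layout.arms_of(chrom)
        start = 0
        while start < length:
            end = start + window_bp
            if any(a.start < end and start < a.end for a in arms):
                rows.append((chrom, start, min(end, length)))
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def density_filter(
    catalog: SingletonCatalog,
    layout: GenomeLayout,
    window_bp: int = 20_000,
    step_bp: int = 10_000,
    k_sd: float = 4.0,
) -> tuple[SingletonCatalog, DensityReport]:
    """Remove singletons in excess-density windows.

    Half-overlapping windows (window = 2 x step by default) tile each
    chromosome from coordinate 0. Counts of retained entries are computed
    per dataset over all windows genome-wide, including empty windows that
    intersect analyzable arms; entries in any window whose count strictly
    exceeds ``mean + k_sd * SD`` (population SD) are flagged ``density``.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    if window_bp != 2 * step_bp:
        raise ValueError("windows must be half-overlapping (window_bp = 2 * step_bp)")
    windows = _enumerate_windows(layout, window_bp, step_bp)
    # map (chrom, window start) -> row index in the window table
    w_row = {
        (c, int(s)): r
        for r, (c, s) in enumerate(zip(windows["chrom"], windows["start"]))
    }
    df = catalog.entries.copy()
    count_frames, stat_rows = [], []
    kill = np.zeros(len(df), dtype=bool)
    for dataset in catalog.datasets():
        sel = df["retained"].to_numpy(dtype=bool) & (df["dataset"] == dataset).to_numpy()
        idx = np.flatnonzero(sel)
        counts = np.zeros(len(windows), dtype=np.int64)
        pos0 = df["pos"].to_numpy()[idx] - 1  # 0-based
        chroms = df["chrom"].to_numpy()[idx]
        # a point at p is covered by windows starting at floor(p/step)*step
        # and one step before (half-overlap); missing windows map to -1
        i_hi = pos0 // step_bp
        rows_hi = np.fromiter(
            (w_row.get((c, int(i * step_bp)), -1) for c, i in zip(chroms, i_hi)),
            dtype=np.int64, count=idx.size,
        )
        rows_lo = np.fromiter(
            (
                w_row.get((c, int((i - 1) * step_bp)), -1) if i >= 1 else -1
                for c, i in zip(chroms, i_hi)
            ),
            dtype=np.int64, count=idx.size,
        )
        np.add.at(counts, rows_hi[rows_hi >= 0], 1)
        np.add.at(counts, rows_lo[rows_lo >= 0], 1)
        mean = float(counts.mean()) if len(counts) else 0.0
        sd = float(counts.std()) if len(counts) else 0.0
        threshold = mean + k_sd * sd
        over = counts > threshold
        bad = np.zeros(idx.size, dtype=bool)
        bad[rows_hi >= 0] |= over[rows_hi[rows_hi >= 0]]
        bad[rows_lo >= 0] |= over[rows_lo[rows_lo >= 0]]
        kill[idx[bad]] = True
        wc = windows.copy()
        wc["count"] = counts
        wc["dataset"] = dataset
        count_frames.append(wc)
        stat_rows.append(
            (dataset, mean, sd, threshold, len(counts), int(over.sum()))
        )
    df.loc[kill, "retained"] = False
    df.loc[kill, "reason"] = "density"
    report = DensityReport(
        window_bp=window_bp,
        step_bp=step_bp,
        window_counts=pd.concat(count_frames, ignore_index=True)[
            ["dataset", "chrom", "start", "end", "count"]
        ],
        stats=pd.DataFrame(
            stat_rows,
            columns=["dataset", "mean", "sd", "threshold", "n_windows", "n_removed_windows"],
        ),
    )
    return SingletonCatalog(df), report
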