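"""Enrichment of selection signatures in trait-associated variant sets.

Genome-wide final selection z-scores are rank-normalized to exact standard
normal quantiles, each trait's variants (or best LD proxies with r^2 above
a threshold) are mapped onto scored variants, and the sum of squared
normalized scores S = sum(z'^2) is referred to the chi-square distribution
with k = |set| degrees of freedom. Inflation S/k is 1 under the null. The
chi-square reference assumes independence among a trait's variants, which
LD violates; results are reported as-is with this caveat documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import IntervalSet
from .panel import HaplotypePanel


@dataclass
class TraitVariantSet:
    """A named set of trait-associated variants given as (chrom, pos) pairs."""

    name: str
    category: str  # disease / quantitative / eQTL
    variants: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.variants = sorted(set((str(c), int(p)) for c, p in self.variants))
        if not self.variants:
            raise ValueError(f"trait set {self.name!r} is empty")

    def ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in self.variants]


def rank_normalize(z: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles by rank: z' = Phi^-1((r - 0.5) / M).

    Average ranks for ties (tied values get identical z'); order-preserving;
    exactly mean-0 by symmetry in the absence of ties.
    """
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 values to rank-normalize")
    r = stats.rankdata(z, method="average")
    return stats.norm.ppf((r - 0.5) / z.size)


def haplotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared haplotype correlation r^2 = D^2 / (p(1-p) q(1-q)).

    ``x`` and ``y`` are 0/1 haplotype vectors of equal length; monomorphic
    input returns 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    p, q = x.mean(), y.mean()
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return 0.0
    d = (x * y).mean() - p * q
    return float(d * d / (p * (1 - p) * q * (1 - q)))


@dataclass
class ProxyReport:
    n_direct: int = 0
    n_proxied: int = 0
    n_dropped: int = 0


def ld_proxy_expand(
    trait_set: TraitVariantSet,
    panel: HaplotypePanel,
    scored_ids: set[str],
    r2_min: float = 0.5,
    window_bp: int = 1_000_000,
) -> tuple[list[str], ProxyReport]:
    """Map trait variants onto scored variants, via LD proxies when needed.

    A trait variant maps to itself when scored; otherwise to the scored
    variant with maximal haplotype r^2 within ``window_bp``, provided
    r^2 > ``r2_min``. Unmapped variants are dropped and counted; variants
    landing on the same proxy collapse to one.
    """
    site_ids = panel.site_ids()
    id_to_idx = {v: i for i, v in enumerate(site_ids)}
    chrom_arr = panel.sites["chrom"].to_numpy()
    pos_arr = panel.sites["pos"].to_numpy()
    scored_mask = site_ids.isin(scored_ids).to_numpy()
    report = ProxyReport()
    mapped: list[str] = []
    for chrom, pos in trait_set.variants:
        vid = f"{chrom}:{pos}"
        if vid in scored_ids:
            mapped.append(vid)
            report.n_direct += 1
            continue
        if vid not in id_to_idx:
            report.n_dropped += 1
            continue
        j = id_to_idx[vid]
        cand = np.flatnonzero(
            (chrom_arr == chrom)
            & (np.abs(pos_arr - pos) <= window_bp)
            & scored_mask
        )
        if cand.size == 0:
            report.n_dropped += 1
            continue
        x = panel.haplotypes[j].reshape(-1)
        best_r2, best = -1.0, None
        for k in cand:
            r2 = haplotype_r2(x, panel.haplotypes[k].reshape(-1))
            if r2 > best_r2:
                best_r2, best = r2, k
        if best is not None and best_r2 > r2_min:
            mapped.append(site_ids.iloc[best])
            report.n_proxied += 1
        else:
            report.n_dropped += 1
    # collapse duplicate targets, preserving order
    seen: dict[str, None] = {}
    for v in mapped:
        seen.setdefault(v)
    return list(seen), report


@dataclass
class EnrichmentRecord:
    trait: str
    category: str
    k: int
    statistic: float  # S = sum(z'^2)
    inflation: float  # S / k
    p: float
    bonferroni_significant: bool = False
    q_value: float = np.nan
    skipped_reason: str | None = None


def chi2_sum_test(zprime: np.ndarray, trait: str = "", category: str = "") -> EnrichmentRecord:
    """S = sum(z'^2) referred to chi-square with k = len(z') df."""
    zprime = np.asarray(zprime, dtype=float)
    k = zprime.size
    if k < 1:
        raise ValueError("empty mapped variant set")
    s = float((zprime**2).sum())
    p = float(stats.chi2.sf(s, df=k))
    return EnrichmentRecord(
        trait=trait, category=category, k=k, statistic=s, inflation=s / k,
        p=max(p, np.nextafter(0, 1)),
    )


def multiple_testing(
    p_values: np.ndarray, n_tests: int | None = None, method: str = "bonferroni",
    alpha: float = 0.05,
):
    """Bonferroni flags (``P < alpha / n_tests``) or Benjamini-Hochberg q-values."""
    p_values = np.asarray(p_values, dtype=float)
    if n_tests is None:
        n_tests = p_values.size
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if method == "bonferroni":
        return p_values < (alpha / n_tests)
    if method == "bh":
        return multipletests(p_values, alpha=alpha, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def enrich_traits(
    trait_sets: list[TraitVariantSet],
    sds_table: pd.DataFrame,
    panel: HaplotypePanel | None = None,
    r2_min: float = 0.5,
    window_bp: int = 1_000_000,
    alpha: float = 0.05,
    exclude: IntervalSet | None = None,
) -> pd.DataFrame:
    """Chi-square enrichment of every trait set against the selection scan.

    ``exclude`` drops scored variants inside the given loci before rank
    normalization and mapping (sensitivity rerun removing genome-wide
    significant selection loci); BH q-values are computed in that mode,
    Bonferroni flags always (threshold alpha / number of trait sets).
    """
    table = sds_table
    if exclude is not None and len(exclude):
        keep = np.ones(len(table), dtype=bool)
        for chrom, grp in table.groupby("chrom", sort=False):
            inside = exclude.contains_pos1(str(chrom), grp["pos"].to_numpy())
            keep[grp.index.to_numpy()] = ~inside
        table = table[keep].reset_index(drop=True)
    zprime_all = rank_normalize(table["final_z"].to_numpy())
    variant_ids = (
        table["chrom"].astype(str) + ":" + table["pos"].astype(str)
    ).to_numpy()
    z_of = dict(zip(variant_ids, zprime_all))
    scored = set(variant_ids)
    records: list[EnrichmentRecord] = []
    for ts in trait_sets:
        if panel is not None:
            mapped, _ = ld_proxy_expand(ts, panel, scored, r2_min=r2_min, window_bp=window_bp)
        else:
            mapped = [v for v in ts.ids() if v in scored]
            mapped = list(dict.fromkeys(mapped))
        if not mapped:
            records.append(
                EnrichmentRecord(
                    trait=ts.name, category=ts.category, k=0, statistic=np.nan,
                    inflation=np.nan, p=np.nan, skipped_reason="no_mapped_variants",
                )
            )
            continue
        rec = chi2_sum_test(np.array([z_of[v] for v in mapped]), ts.name, ts.category)
        records.append(rec)
    df = pd.DataFrame([r.__dict__ for r in records])
    tested = df["p"].notna()
    n_tests = int(tested.sum())
    if n_tests:
        df.loc[tested, "bonferroni_significant"] = multiple_testing(
            df.loc[tested, "p"].to_numpy(), n_tests, "bonferroni", alpha
        )
        df.loc[tested, "q_value"] = multiple_testing(
            df.loc[tested, "p"].to_numpy(), method="bh", alpha=alpha
        )
    return df
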