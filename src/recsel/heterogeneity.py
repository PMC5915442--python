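"""Derived-allele-frequency heterogeneity across subpopulations.

The heterogeneity index of a variant is Pearson's chi-square statistic of
its subpopulations x {derived, ancestral} allele-count table divided by the
total allele count N. The index lies in [0, 1]: 0 for identical frequencies
everywhere, 1 for complete separation (it equals the squared phi
coefficient for two subpopulations, and the squared Cramer's V generally,
since the allele axis has df = 1).

Enrichment of a focal variant is judged against the empirical distribution
of indices from variants in the same pooled-DAF bin (+/- 0.005 by default):
fold change = observed / null mean, and a one-tailed add-one exceedance
P-value in which ties count against enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SubpopCountTable


def heterogeneity_index(table: SubpopCountTable) -> float:
    """Chi-square over total allele count for one variant's count table.

    Subpopulations with zero total alleles are dropped; monomorphic tables
    (all derived or all ancestral) return 0 by convention.
    """
    der = table.counts["derived"].to_numpy(dtype=float)
    anc = table.counts["ancestral"].to_numpy(dtype=float)
    return float(heterogeneity_index_many(der[None, :], anc[None, :])[0])


def heterogeneity_index_many(der: np.ndarray, anc: np.ndarray) -> np.ndarray:
    """Vectorized index for many variants: rows = variants, cols = subpops."""
    der = np.asarray(der, dtype=float)
    anc = np.asarray(anc, dtype=float)
    row_n = der + anc  # alleles per subpopulation
    n = row_n.sum(axis=1)
    if np.any(n <= 0):
        raise ValueError("table with zero total alleles")
    d_tot = der.sum(axis=1)
    a_tot = anc.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (d_tot / n)[:, None]
        q = (a_tot / n)[:, None]
        e_der = row_n * p
        e_anc = row_n * q
        chi2 = np.where(e_der > 0, (der - e_der) ** 2 / np.where(e_der > 0, e_der, 1), 0).sum(axis=1)
        chi2 += np.where(e_anc > 0, (anc - e_anc) ** 2 / np.where(e_anc > 0, e_anc, 1), 0).sum(axis=1)
    h = chi2 / n
    # monomorphic tables: expected counts vanish on one side -> define 0
    h = np.where((d_tot == 0) | (a_tot == 0), 0.0, h)
    return h


def binned_null(
    h_values: np.ndarray,
    dafs: np.ndarray,
    focal_daf: float,
    focal_index: int | None = None,
    half_width: float = 0.005,
    min_size: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """Empirical null: indices of variants within the focal pooled-DAF bin.

    The focal variant itself (``focal_index``) is excluded. If the bin
    holds fewer than ``min_size`` variants it is widened symmetrically in
    ``half_width`` steps until it does; the returned flag records widening.

    Returns ``(null_values, used_half_width, widened)``.
    """
    h_values = np.asarray(h_values, dtype=float)
    dafs = np.asarray(dafs, dtype=float)
    keep = np.ones(len(h_values), dtype=bool)
    if focal_index is not None:
        keep[focal_index] = False
    hw = half_width
    widened = False
    while True:
        sel = keep & (np.abs(dafs - focal_daf) <= hw + 1e-12)
        if sel.sum() >= min_size or hw >= 0.5:
            break
        hw += half_width
        widened = True
    if sel.sum() == 0:
        raise ValueError("empty null distribution even after widening")
    return h_values[sel], hw, widened


def enrichment(h_obs: float, null: np.ndarray) -> tuple[float, float]:
    """Fold change and one-tailed add-one exceedance P against the null.

    fold = h_obs / mean(null) (NaN when the null mean is 0);
    P = (1 + #{null >= h_obs}) / (1 + |null|).
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    mean = null.mean()
    fold = h_obs / mean if mean > 0 else np.nan
    p = (1 + int((null >= h_obs).sum())) / (1 + null.size)
    return fold, p


@dataclass
class HeterogeneityRecord:
    variant_id: str
    pooled_daf: float
    h: float
    half_width: float
    widened: bool
    null_mean: float
    null_size: int
    fold: float
    p: float


def score_heterogeneity(
    tables: dict[str, SubpopCountTable],
    focal_ids: list[str],
    half_width: float = 0.005,
    min_null_size: int = 100,
) -> pd.DataFrame:
    """Heterogeneity enrichment of focal variants against all scored variants."""
    ids = list(tables)
    der = np.array([tables[v].counts["derived"].to_numpy() for v in ids], dtype=float)
    anc = np.array([tables[v].counts["ancestral"].to_numpy() for v in ids], dtype=float)
    h = heterogeneity_index_many(der, anc)
    n = (der + anc).sum(axis=1)
    daf = der.sum(axis=1) / n
    index_of = {v: i for i, v in enumerate(ids)}
    records = []
    for v in focal_ids:
        i = index_of[v]
        null, hw, widened = binned_null(
            h, daf, daf[i], focal_index=i, half_width=half_width, min_size=min_null_size
        )
        fold, p = enrichment(h[i], null)
        records.append(
            HeterogeneityRecord(
                variant_id=v,
                pooled_daf=float(daf[i]),
                h=float(h[i]),
                half_width=hw,
                widened=widened,
                null_mean=float(null.mean()),
                null_size=int(null.size),
                fold=float(fold),
                p=float(p),
            )
        )
    return pd.DataFrame([r.__dict__ for r in records])
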