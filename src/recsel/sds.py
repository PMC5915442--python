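"""Singleton-density selection scoring.

The score contrasts, at each common test variant, the distances from the
variant to the nearest singletons carried by each individual, between
haplotypes carrying the derived versus the ancestral allele. An allele that
rose in frequency recently sits on haplotypes with shortened terminal
genealogy branches, hence fewer nearby singletons and longer gaps.

Model
-----
Each haplotype carries an independent Poisson singleton process. For an
individual with ``n_der`` derived and ``n_anc = 2 - n_der`` ancestral
haplotypes at the test variant, the nearest-singleton distance on each side
is exponential with the summed rate ``lam(i) = n_anc * lam_a + n_der *
lam_d``, so the total two-sided gap ``g = d_up + d_down`` is Gamma(shape 2,
rate lam(i)). The per-variant log-likelihood is::

    sum_i [ 2 * log lam(i) - lam(i) * g_i ]

maximized over ``(lam_a, lam_d) > 0``. The raw score is ``log(lam_a_hat) -
log(lam_d_hat)``: positive when derived haplotypes are singleton-poor.
Because the likelihood is concave in ``(lam_a, lam_d)`` (log of a linear
form plus linear terms), coordinate ascent with exact per-coordinate
quadratic solutions converges to the global maximum; homozygous-only
instances have the closed form ``lam_hat = 1 / mean(g)`` per class.

Raw scores are computed separately per chromosome arm and per dataset,
standardized genome-wide within derived-allele-frequency bins per dataset,
meta-analyzed across datasets with square-root-of-sample-size weights, and
re-standardized genome-wide to yield the final z and its two-tailed normal
P-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Arm, GenomeLayout
from .panel import HaplotypePanel
from .singletons import SingletonCatalog

GENOME_WIDE_ALPHA = 5.0e-8

# reason codes for unscored variants
REASON_CLASS_COUNT = "class_count"
REASON_EDGE = "arm_edge"
REASON_CAP = "rate_cap"
REASON_NO_CONVERGE = "no_convergence"

_LAM_LO, _LAM_HI = 1e-12, 1e12


def two_tailed_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-tailed standard-normal P for a (final) z-score: 2 * Phi(-|z|)."""
    return 2 * stats.norm.sf(np.abs(z))


@dataclass
class GapObservation:
    """Per-individual flanking-singleton gaps at one test variant."""

    variant_id: str
    n_der: np.ndarray  # derived-allele dosage per individual, 0/1/2
    d_up: np.ndarray  # distance to nearest singleton before the variant (bp)
    d_down: np.ndarray  # distance to nearest singleton after the variant (bp)
    censored: np.ndarray  # no flanking singleton on one side within the arm

    @property
    def gap(self) -> np.ndarray:
        return self.d_up + self.d_down


@dataclass
class BinScheme:
    """Derived-allele-frequency bins for raw-score standardization.

    Width 0.005 below DAF 0.1 and above 0.9, width 0.01 in between; bins are
    half-open ``[lo, hi)`` and partition (0, 1). Bins holding fewer than
    ``min_occupancy`` scores are merged with their neighbors before
    standardization.
    """

    edges: np.ndarray = field(default_factory=lambda: _default_edges())
    min_occupancy: int = 20

    def bin_of(self, daf: np.ndarray) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.edges, daf, side="right") - 1, 0, len(self.edges) - 2
        )


def _default_edges() -> np.ndarray:
    edges = np.concatenate(
        [
            np.arange(0, 100, 5),  # 0.000-0.100 in 0.005 steps (x1000)
            np.arange(100, 900, 10),  # 0.100-0.900 in 0.01 steps
            np.arange(900, 1001, 5),  # 0.900-1.000 in 0.005 steps
        ]
    )
    return edges / 1000.0


def gap_lengths(
    panel: HaplotypePanel,
    catalog: SingletonCatalog,
    variant_index: int,
    arm: Arm,
    dataset: str,
) -> GapObservation:
    """Nearest flanking singleton distances for every individual of a dataset.

    For each individual, the nearest retained singleton carried by that
    individual strictly before and strictly after the variant position,
    both within the arm. Individuals lacking a flanking singleton on either
    side are censored.
    """
    site = panel.sites.iloc[variant_index]
    if not arm.contains_pos1(int(site.pos)) or arm.chrom != site.chrom:
        raise ValueError(f"variant {site.chrom}:{site.pos} outside arm {arm.label}")
    cols = panel.sample_indices(dataset=dataset)
    sample_ids = panel.samples["sample"].to_numpy()[cols]
    n_der = panel.genotypes[variant_index, cols].astype(np.int8)
    ent = catalog.retained(dataset)
    ent = ent[
        (ent["chrom"] == arm.chrom)
        & arm.contains_pos1(ent["pos"].to_numpy())
    ]
    pos_by_carrier = {
        c: np.sort(g["pos"].to_numpy()) for c, g in ent.groupby("carrier", sort=False)
    }
    n = cols.size
    d_up = np.zeros(n)
    d_down = np.zeros(n)
    censored = np.zeros(n, dtype=bool)
    vpos = int(site.pos)
    for i, sid in enumerate(sample_ids):
        pos = pos_by_carrier.get(sid, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(pos, vpos, side="left")
        hi = np.searchsorted(pos, vpos, side="right")
        if lo == 0 or hi == len(pos):
            censored[i] = True
            continue
        d_up[i] = vpos - pos[lo - 1]
        d_down[i] = pos[hi] - vpos
    return GapObservation(
        variant_id=f"{site.chrom}:{site.pos}",
        n_der=n_der,
        d_up=d_up,
        d_down=d_down,
        censored=censored,
    )


def _fit_many(
    n0: np.ndarray,
    s0: np.ndarray,
    n1: np.ndarray,
    s1: np.ndarray,
    n2: np.ndarray,
    s2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MLE of (lam_a, lam_d) from per-class sufficient statistics.

    Classes: 0 = homozygous ancestral, 1 = heterozygous, 2 = homozygous
    derived; ``n_k`` individual counts, ``s_k`` summed gaps. Coordinate
    ascent with exact quadratic-root updates; returns (lam_a, lam_d,
    converged).
    """
    n0, s0, n1, s1, n2, s2 = (np.asarray(x, dtype=float) for x in (n0, s0, n1, s1, n2, s2))
    m = n0.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_all = (2 * s0 + s1 + 2 * s2) / (2 * (n0 + n1 + n2))
        lam_a = np.where(n0 > 0, n0 / np.where(s0 > 0, s0, 1.0), 1.0 / mean_all)
        lam_d = np.where(n2 > 0, n2 / np.where(s2 > 0, s2, 1.0), 1.0 / mean_all)
    lam_a = np.clip(lam_a, _LAM_LO, _LAM_HI)
    lam_d = np.clip(lam_d, _LAM_LO, _LAM_HI)

    def loglik(la, ld):
        with np.errstate(divide="ignore"):
            return (
                2 * n0 * np.log(2 * la)
                - 2 * la * s0
                + 2 * n1 * np.log(la + ld)
                - (la + ld) * s1
                + 2 * n2 * np.log(2 * ld)
                - 2 * ld * s2
            )

    def coord_update(n_own, s_own, n_het, other, c):
        # solve 2*n_own/x + 2*n_het/(x + other) = c for x > 0:
        # c*x^2 + (c*other - 2*n_own - 2*n_het)*x - 2*n_own*other = 0
        b = c * other - 2 * n_own - 2 * n_het
        disc = b * b + 8 * c * n_own * other
        x = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2 * c)
        return np.clip(x, _LAM_LO, _LAM_HI)

    ll = loglik(lam_a, lam_d)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        ca = 2 * s0 + s1
        cd = 2 * s2 + s1
        lam_a = np.where(active, coord_update(n0, s0, n1, lam_d, np.maximum(ca, 1e-300)), lam_a)
        lam_d = np.where(active, coord_update(n2, s2, n1, lam_a, np.maximum(cd, 1e-300)), lam_d)
        new_ll = loglik(lam_a, lam_d)
        converged |= np.abs(new_ll - ll) < tol
        ll = new_ll
    return lam_a, lam_d, converged


@dataclass
class FitResult:
    raw: float
    lam_a: float
    lam_d: float
    reason: str | None  # None when scored


def fit_raw_sds(obs: GapObservation, min_class_count: int = 10) -> FitResult:
    """Maximum-likelihood raw score for one variant's gap observations."""
    keep = ~obs.censored
    n_der = obs.n_der[keep]
    g = obs.gap[keep]
    n_with_anc = int((n_der <= 1).sum())
    n_with_der = int((n_der >= 1).sum())
    if n_with_anc < min_class_count or n_with_der < min_class_count:
        return FitResult(np.nan, np.nan, np.nan, REASON_CLASS_COUNT)
    stats_ = [
        ((n_der == k).sum(), g[n_der == k].sum()) for k in (0, 1, 2)
    ]
    (n0, s0), (n1, s1), (n2, s2) = stats_
    la, ld, ok = _fit_many(
        *(np.array([v], dtype=float) for v in (n0, s0, n1, s1, n2, s2))
    )
    la, ld, ok = float(la[0]), float(ld[0]), bool(ok[0])
    if la <= _LAM_LO or la >= _LAM_HI or ld <= _LAM_LO or ld >= _LAM_HI:
        return FitResult(np.nan, la, ld, REASON_CAP)
    if not ok:
        return FitResult(np.nan, la, ld, REASON_NO_CONVERGE)
    return FitResult(np.log(la) - np.log(ld), la, ld, None)


def score_dataset(
    panel: HaplotypePanel,
    catalog: SingletonCatalog,
    dataset: str,
    layout: GenomeLayout,
    maf_min: float = 0.01,
    min_class_count: int = 10,
) -> pd.DataFrame:
    """Raw scores for all common variants of one dataset, arm by arm.

    Returns a frame indexed like ``panel.sites`` rows with columns
    ``raw``, ``daf`` (within-dataset), and ``reason`` (NaN raw when
    unscored). Variants within one median total gap of an arm end are
    skipped, as edge censoring biases the gap distribution there.
    """
    cols = panel.sample_indices(dataset=dataset)
    sample_ids = panel.samples["sample"].to_numpy()[cols]
    geno = panel.genotypes[:, cols]
    daf_ds = panel.daf(dataset=dataset)
    maf = panel.maf()
    common = maf >= maf_min

    ent = catalog.retained(dataset)
    pos_by = {
        (str(c), car): np.sort(g["pos"].to_numpy())
        for (c, car), g in ent.groupby(["chrom", "carrier"], sort=False)
    }

    n_sites = panel.n_sites
    out_raw = np.full(n_sites, np.nan)
    out_reason = np.array([None] * n_sites, dtype=object)
    site_chrom = panel.sites["chrom"].to_numpy()
    site_pos = panel.sites["pos"].to_numpy()

    for arm in layout.arms:
        vmask = (site_chrom == arm.chrom) & arm.contains_pos1(site_pos) & common
        vidx = np.flatnonzero(vmask)
        if vidx.size == 0:
            continue
        vpos = site_pos[vidx]
        nv = vidx.size
        # per-class sufficient statistics accumulated over individuals
        n_cls = np.zeros((3, nv))
        s_cls = np.zeros((3, nv))
        cens_any = np.zeros(nv, dtype=int)
        gaps_all: list[np.ndarray] = []
        for i, sid in enumerate(sample_ids):
            pos = pos_by.get((arm.chrom, sid))
            if pos is None:
                cens_any += 1
                continue
            lo_b = np.searchsorted(pos, arm.start + 1)  # first within arm (1-based)
            hi_b = np.searchsorted(pos, arm.end, side="right")
            pos = pos[lo_b:hi_b]
            if pos.size == 0:
                cens_any += 1
                continue
            lo = np.searchsorted(pos, vpos, side="left")
            hi = np.searchsorted(pos, vpos, side="right")
            ok = (lo > 0) & (hi < pos.size)
            cens_any += (~ok).astype(int)
            d_up = np.where(ok, vpos - pos[np.clip(lo - 1, 0, pos.size - 1)], 0)
            d_down = np.where(ok, pos[np.clip(hi, 0, pos.size - 1)] - vpos, 0)
            g = (d_up + d_down).astype(float)
            cls = geno[vidx, i]
            for k in (0, 1, 2):
                sel = ok & (cls == k)
                n_cls[k, sel] += 1
                s_cls[k, sel] += g[sel]
            gaps_all.append(g[ok])
        # skip variants too close to arm ends (edge censoring bias)
        med_gap = float(np.median(np.concatenate(gaps_all))) if gaps_all else 0.0
        edge = (vpos - (arm.start + 1) < med_gap) | ((arm.end - vpos) < med_gap)

        n_with_anc = n_cls[0] + n_cls[1]
        n_with_der = n_cls[1] + n_cls[2]
        fit_ok = (
            ~edge
            & (n_with_anc >= min_class_count)
            & (n_with_der >= min_class_count)
        )
        la, ld, conv = _fit_many(
            n_cls[0, fit_ok], s_cls[0, fit_ok],
            n_cls[1, fit_ok], s_cls[1, fit_ok],
            n_cls[2, fit_ok], s_cls[2, fit_ok],
        )
        capped = (la <= _LAM_LO) | (la >= _LAM_HI) | (ld <= _LAM_LO) | (ld >= _LAM_HI)
        raw = np.where(conv & ~capped, np.log(la) - np.log(ld), np.nan)
        out_raw[vidx[fit_ok]] = raw
        sub_reason = np.array([None] * int(fit_ok.sum()), dtype=object)
        sub_reason[capped] = REASON_CAP
        sub_reason[~conv & ~capped] = REASON_NO_CONVERGE
        out_reason[vidx[fit_ok]] = sub_reason
        out_reason[vidx[edge]] = REASON_EDGE
        out_reason[vidx[~edge & ~((n_with_anc >= min_class_count) & (n_with_der >= min_class_count))]] = REASON_CLASS_COUNT

    return pd.DataFrame(
        {"raw": out_raw, "daf": daf_ds, "reason": out_reason},
        index=np.arange(n_sites),
    )


def bin_standardize(
    raw: np.ndarray, daf: np.ndarray, scheme: BinScheme | None = None
) -> np.ndarray:
    """Z-standardize raw scores within DAF bins (NaN-preserving).

    Bins with fewer than ``scheme.min_occupancy`` scored variants are merged
    with adjacent bins (left-to-right accumulation; a short trailing group
    joins its predecessor). Within each merged group, z = (raw - mean) / SD
    with the population SD, so each group has mean 0 and SD exactly 1.
    """
    scheme = scheme or BinScheme()
    raw = np.asarray(raw, dtype=float)
    scored = ~np.isnan(raw)
    if scored.sum() < 2:
        raise ValueError("fewer than 2 scored variants to standardize")
    bins = scheme.bin_of(np.asarray(daf, dtype=float))
    n_bins = len(scheme.edges) - 1
    occ = np.bincount(bins[scored], minlength=n_bins)
    # greedy left-to-right merge into groups of >= min_occupancy
    group = np.zeros(n_bins, dtype=int)
    gid, acc = 0, 0
    for b in range(n_bins):
        group[b] = gid
        acc += occ[b]
        if acc >= scheme.min_occupancy:
            gid, acc = gid + 1, 0
    if acc > 0 and gid > 0:  # merge trailing underfilled group backwards
        group[group == gid] = gid - 1
    z = np.full(raw.shape, np.nan)
    g_of = group[bins]
    for g in np.unique(g_of[scored]):
        sel = scored & (g_of == g)
        vals = raw[sel]
        if vals.size < 2:
            raise ValueError("standardization group with fewer than 2 scores")
        sd = vals.std()
        if sd == 0:
            raise ValueError("zero variance in standardization group")
        z[sel] = (vals - vals.mean()) / sd
    return z


def meta_analyze(
    z_by_dataset: pd.DataFrame, n_by_dataset: dict[str, int]
) -> pd.DataFrame:
    """Sample-size-weighted z meta-analysis with genome-wide re-normalization.

    ``meta_z = sum(w_i z_i) / sqrt(sum(w_i^2))`` with ``w_i = sqrt(n_i)``;
    variants lacking a score in any dataset are excluded. The meta z is
    re-standardized genome-wide (single mean/SD) to the final z, and
    ``P = 2 * Phi(-|final_z|)``.
    """
    datasets = list(z_by_dataset.columns)
    w = np.array([np.sqrt(n_by_dataset[d]) for d in datasets])
    zmat = z_by_dataset.to_numpy(dtype=float)
    complete = ~np.isnan(zmat).any(axis=1)
    meta = np.full(len(z_by_dataset), np.nan)
    meta[complete] = zmat[complete] @ w / np.sqrt((w**2).sum())
    mu, sd = np.nanmean(meta), np.nanstd(meta, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot re-normalize: degenerate meta z distribution")
    final = (meta - mu) / sd
    p = two_tailed_p(final)
    return pd.DataFrame(
        {
            "meta_z": meta,
            "final_z": final,
            "p": p,
            "significant": p < GENOME_WIDE_ALPHA,
        },
        index=z_by_dataset.index,
    )


def compute_sds(
    panel: HaplotypePanel,
    catalog: SingletonCatalog,
    layout: GenomeLayout,
    scheme: BinScheme | None = None,
    maf_min: float = 0.01,
    min_class_count: int = 10,
) -> pd.DataFrame:
    """End-to-end scoring: raw per dataset/arm, bin z, meta, final z, P.

    Returns one row per variant scored in every dataset, with columns
    ``chrom, pos, daf`` (pooled), per-dataset ``raw_<ds>`` / ``z_<ds>``,
    ``meta_z, final_z, p, significant``.
    """
    scheme = scheme or BinScheme()
    datasets = catalog.datasets()
    n_by = {
        d: int((panel.samples["dataset"] == d).sum()) for d in datasets
    }
    z_cols, raw_cols = {}, {}
    for d in datasets:
        scored = score_dataset(
            panel, catalog, d, layout, maf_min=maf_min, min_class_count=min_class_count
        )
        raw_cols[d] = scored["raw"].to_numpy()
        z_cols[d] = bin_standardize(
            scored["raw"].to_numpy(), scored["daf"].to_numpy(), scheme
        )
    zdf = pd.DataFrame({d: z_cols[d] for d in datasets})
    meta = meta_analyze(zdf, n_by)
    out = pd.DataFrame(
        {
            "variant": panel.site_ids(),
            "chrom": panel.sites["chrom"],
            "pos": panel.sites["pos"],
            "daf": panel.daf(),
        }
    )
    for d in datasets:
        out[f"raw_{d}"] = raw_cols[d]
        out[f"z_{d}"] = z_cols[d]
    out = pd.concat([out, meta], axis=1)
    return out[~out["final_z"].isna()].reset_index(drop=True)
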