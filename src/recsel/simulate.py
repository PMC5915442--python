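"""Seeded synthetic data emulating the statistical structure of a
whole-genome-sequenced cohort scanned for very recent selection.

What is emulated
----------------
* Three phased WGS datasets of unequal size, with common variants at
  configurable derived-allele frequencies and haplotypes assigned
  independently (no background LD).
* Singletons as a per-haplotype Poisson process of rate ``singleton_rate``
  per bp; inside the window of a selected locus, haplotypes carrying the
  derived core allele are thinned to rate ``rho * singleton_rate``. This
  haplotype-class-specific rate drop is the exact generative counterpart of
  the Gamma(2) gap likelihood used by the scoring engine, so parameter
  recovery is exact in expectation without coalescent machinery.
* Regional allele-frequency structure via the Balding-Nichols model:
  per-region frequencies Beta(daf (1-F)/F, (1-daf)(1-F)/F) around the
  pooled DAF with drift F, counts binomial given region sizes; selection is
  modeled as an inflated F.
* Introgression-tract interval sets (uniform-random, non-overlapping) and
  trait-associated variant sets, optionally enriched near selected loci.

Every generator is a pure function of (config, seed): fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet, default_layout
from .panel import SAMPLE_COLUMNS, SITE_COLUMNS, HaplotypePanel, SubpopCountTable
from .singletons import CATALOG_COLUMNS, SingletonCatalog
from .traits import TraitVariantSet

#: the seven geographic regions used for regional-heterogeneity emulation,
#: with cohort proportions of a nation-wide biobank recruitment
JAPAN_REGION_LABELS = (
    "Hokkaido", "Tohoku", "Kanto-Koshinetsu", "Chubu-Hokuriku",
    "Kinki", "Kyushu", "Okinawa",
)
JAPAN_REGION_COUNTS = (7910, 10907, 95272, 9390, 26160, 15818, 5719)


@dataclass(frozen=True)
class SelectedLocus:
    """A core variant under recent selection with a singleton-depleted window."""

    chrom: str
    pos: int
    daf: float
    rho: float  # singleton-rate multiplier on derived haplotypes, in (0, 1]
    half_width: int = 50_000

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if not (0 < self.daf < 1):
            raise ValueError("selected locus DAF must be in (0, 1)")


@dataclass(frozen=True)
class RegionScheme:
    labels: tuple[str, ...] = JAPAN_REGION_LABELS
    proportions: tuple[float, ...] = tuple(
        c / sum(JAPAN_REGION_COUNTS) for c in JAPAN_REGION_COUNTS
    )
    f_drift: float = 0.005
    selected_f_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("region proportions must sum to 1")
        if not (0 <= self.f_drift < 1):
            raise ValueError("drift F must be in [0, 1)")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated study design."""

    seed: int = 0
    layout: GenomeLayout = field(default_factory=default_layout)
    dataset_sizes: tuple[int, ...] = (1276, 492, 466)
    n_common_sites: int = 2500
    singleton_rate: float = 1e-4  # per bp per haplotype
    selected_loci: tuple[SelectedLocus, ...] = ()
    regions: RegionScheme = field(default_factory=RegionScheme)
    daf_range: tuple[float, float] = (0.01, 0.99)
    gwas_total: int = 171_176
    #: per selected locus, add this many linked sites copying the core
    #: haplotype (flip noise ld_noise) inside the window — induces the LD
    #: that proxy mapping and locus-level trait enrichment rely on
    selected_ld_copies: int = 0
    ld_noise: float = 0.02

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.dataset_sizes):
            raise ValueError("dataset sizes must be >= 2")
        if self.singleton_rate <= 0:
            raise ValueError("singleton_rate must be positive")
        for locus in self.selected_loci:
            arm = self.layout.arm_of(locus.chrom, locus.pos)
            if arm is None:
                raise ValueError(f"selected locus {locus.chrom}:{locus.pos} outside arms")
            if (locus.pos - 1 - locus.half_width < arm.start
                    or locus.pos - 1 + locus.half_width > arm.end):
                raise ValueError(
                    f"selection window at {locus.chrom}:{locus.pos} exceeds arm bounds"
                )

    def dataset_labels(self) -> list[str]:
        return [f"d{i + 1}" for i in range(len(self.dataset_sizes))]


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests."""

    selected: pd.DataFrame  # chrom, pos, daf, rho, half_width, site_index
    trait_enriched: pd.DataFrame | None = None  # trait, enriched flag


def _arm_spans(layout: GenomeLayout) -> tuple[np.ndarray, list]:
    arms = list(layout.arms)
    cum = np.concatenate([[0], np.cumsum([a.length for a in arms])])
    return cum, arms


def _draw_positions(rng, layout: GenomeLayout, n: int) -> pd.DataFrame:
    """Distinct uniform positions over analyzable arms, sorted genome order."""
    cum, arms = _arm_spans(layout)
    total = int(cum[-1])
    u = rng.choice(total, size=min(n, total), replace=False)
    arm_idx = np.searchsorted(cum, u, side="right") - 1
    rows = []
    for k, a in zip(u, arm_idx):
        arm = arms[a]
        rows.append((arm.chrom, int(arm.start + (k - cum[a]) + 1)))  # 1-based
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    chrom_order = {c: i for i, c in enumerate(layout.chrom_names())}
    return (
        df.assign(_o=df["chrom"].map(chrom_order))
        .sort_values(["_o", "pos"])
        .drop(columns="_o")
        .drop_duplicates()
        .reset_index(drop=True)
    )


def simulate_panel(
    config: SimulationConfig,
) -> tuple[HaplotypePanel, SingletonCatalog, TruthRecord]:
    """Generate a phased common-variant panel plus its singleton catalog.

    Common sites live in the panel's genotype matrix; singleton events are
    returned directly as a :class:`SingletonCatalog` (one row per event,
    all retained), which is what singleton extraction from a full panel
    would produce.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    labels = config.dataset_labels()

    # --- common sites ---------------------------------------------------
    sites = _draw_positions(rng, layout, config.n_common_sites)
    daf = rng.uniform(*config.daf_range, size=len(sites))
    # insert selected core loci at their exact positions
    for locus in config.selected_loci:
        hit = (sites["chrom"] == locus.chrom) & (sites["pos"] == locus.pos)
        if not hit.any():
            sites = pd.concat(
                [sites, pd.DataFrame({"chrom": [locus.chrom], "pos": [locus.pos]})],
                ignore_index=True,
            )
            daf = np.append(daf, locus.daf)
        else:
            daf[hit.to_numpy().nonzero()[0][0]] = locus.daf
    chrom_order = {c: i for i, c in enumerate(layout.chrom_names())}
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].map(chrom_order).to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    daf = daf[order]

    n_samples = int(sum(config.dataset_sizes))
    haps = (rng.random((len(sites), n_samples, 2)) < daf[:, None, None]).astype(np.int8)

    # --- linked copies of selected cores (optional LD blocks) -----------
    core_index = {}
    for locus in config.selected_loci:
        idx = int(
            sites.index[(sites["chrom"] == locus.chrom) & (sites["pos"] == locus.pos)][0]
        )
        core_index[(locus.chrom, locus.pos)] = idx
    if config.selected_ld_copies > 0 and config.selected_loci:
        add_rows, add_haps = [], []
        for locus in config.selected_loci:
            core = haps[core_index[(locus.chrom, locus.pos)]]
            taken = set(
                sites.loc[sites["chrom"] == locus.chrom, "pos"].tolist()
            ) | {r[1] for r in add_rows}
            lo, hi = locus.pos - locus.half_width, locus.pos + locus.half_width
            for _ in range(config.selected_ld_copies):
                while True:
                    p = int(rng.integers(lo, hi + 1))
                    if p != locus.pos and p not in taken:
                        break
                taken.add(p)
                flips = rng.random(core.shape) < config.ld_noise
                add_rows.append((locus.chrom, p))
                add_haps.append(np.where(flips, 1 - core, core).astype(np.int8))
        sites = pd.concat(
            [sites, pd.DataFrame(add_rows, columns=["chrom", "pos"])], ignore_index=True
        )
        haps = np.concatenate([haps, np.stack(add_haps)], axis=0)
        daf = np.append(daf, [h.mean() for h in add_haps])
        order = np.lexsort(
            (sites["pos"].to_numpy(), sites["chrom"].map(chrom_order).to_numpy())
        )
        sites = sites.iloc[order].reset_index(drop=True)
        haps = haps[order]
        daf = daf[order]
        core_index = {
            (l.chrom, l.pos): int(
                sites.index[(sites["chrom"] == l.chrom) & (sites["pos"] == l.pos)][0]
            )
            for l in config.selected_loci
        }

    sites["ancestral"] = "A"
    sites["derived"] = "G"
    sample_ids = []
    dataset_col = []
    for lab, n in zip(labels, config.dataset_sizes):
        sample_ids += [f"{lab}_s{i:05d}" for i in range(n)]
        dataset_col += [lab] * n
    regions = rng.choice(
        config.regions.labels, size=n_samples, p=config.regions.proportions
    )
    samples = pd.DataFrame(
        {"sample": sample_ids, "dataset": dataset_col, "region": regions}
    )
    panel = HaplotypePanel(
        sites=sites[SITE_COLUMNS], haplotypes=haps, samples=samples[SAMPLE_COLUMNS]
    )

    # --- singleton events ------------------------------------------------
    cum, arms = _arm_spans(layout)
    frames = []
    sample_arr = np.asarray(sample_ids)
    dataset_arr = np.asarray(dataset_col)
    for arm_i, arm in enumerate(arms):
        counts = rng.poisson(config.singleton_rate * arm.length, size=2 * n_samples)
        total = int(counts.sum())
        pos = arm.start + 1 + rng.integers(0, arm.length, size=total)  # 1-based
        hap_of = np.repeat(np.arange(2 * n_samples), counts)
        keep = np.ones(total, dtype=bool)
        for locus in config.selected_loci:
            if locus.chrom != arm.chrom:
                continue
            core = haps[core_index[(locus.chrom, locus.pos)]].reshape(-1)  # per haplotype
            in_win = np.abs(pos - locus.pos) <= locus.half_width
            derived_hap = core[hap_of] == 1
            thin = in_win & derived_hap
            keep &= ~thin | (rng.random(total) < locus.rho)
        pos, hap_of = pos[keep], hap_of[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": arm.chrom,
                    "pos": pos,
                    "carrier": sample_arr[hap_of // 2],
                    "vclass": "singleton",
                    "dataset": dataset_arr[hap_of // 2],
                }
            )
        )
    cat = pd.concat(frames, ignore_index=True)
    cat["retained"] = True
    cat["reason"] = "none"
    chrom_o = cat["chrom"].map(chrom_order)
    cat = cat.iloc[np.lexsort((cat["pos"].to_numpy(), chrom_o.to_numpy()))].reset_index(
        drop=True
    )
    catalog = SingletonCatalog(cat[CATALOG_COLUMNS])

    truth = TruthRecord(
        selected=pd.DataFrame(
            [
                {
                    "chrom": l.chrom,
                    "pos": l.pos,
                    "daf": l.daf,
                    "rho": l.rho,
                    "half_width": l.half_width,
                    "site_index": core_index[(l.chrom, l.pos)],
                }
                for l in config.selected_loci
            ],
            columns=["chrom", "pos", "daf", "rho", "half_width", "site_index"],
        )
    )
    return panel, catalog, truth


def simulate_regional_counts(
    config: SimulationConfig,
    variant_daf: float,
    selected: bool = False,
    rng: np.random.Generator | None = None,
    variant_id: str = "v",
) -> SubpopCountTable:
    """Balding-Nichols regional allele counts around a pooled DAF.

    Per-region frequency ~ Beta(daf (1-F)/F, (1-daf)(1-F)/F) with
    F = ``f_drift`` (times ``selected_f_multiplier`` for selected
    variants, capped below 1); counts binomial given 2 x region sizes.
    DAF of exactly 0 or 1 yields the degenerate all-ancestral /
    all-derived table.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scheme = config.regions
    sizes = np.round(np.asarray(scheme.proportions) * config.gwas_total).astype(int)
    alleles = 2 * sizes
    if variant_daf in (0.0, 1.0):
        der = alleles * int(variant_daf)
    else:
        f = scheme.f_drift * (scheme.selected_f_multiplier if selected else 1.0)
        f = min(f, 0.99)
        if f <= 0:
            p = np.full(len(sizes), variant_daf)
        else:
            a = variant_daf * (1 - f) / f
            b = (1 - variant_daf) * (1 - f) / f
            p = rng.beta(a, b, size=len(sizes))
        der = rng.binomial(alleles, p)
    counts = pd.DataFrame(
        {"derived": der, "ancestral": alleles - der},
        index=pd.Index(scheme.labels, name="subpop"),
    )
    return SubpopCountTable(variant_id=variant_id, counts=counts)


def simulate_tracts(
    config: SimulationConfig,
    total_bp: int,
    n_tracts: int,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Uniform-random non-overlapping tracts totalling ``total_bp``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.layout.total_length
    if total_bp > L:
        raise ValueError(f"requested {total_bp} bp of tracts exceeds genome length {L}")
    if n_tracts == 0:
        return IntervalSet()
    tract_len = total_bp // n_tracts
    slack = L - n_tracts * tract_len
    gaps = np.sort(rng.integers(0, slack + 1, size=n_tracts))
    starts = gaps + np.arange(n_tracts) * tract_len
    from .introgression import ConcatMap

    cmap = ConcatMap(config.layout)
    intervals = []
    for s in starts:
        intervals.extend(cmap.intervals_from_global(int(s), int(s) + tract_len))
    return IntervalSet(intervals).normalized()


def simulate_trait_sets(
    config: SimulationConfig,
    scored_sites: pd.DataFrame,
    n_traits: int,
    k_per_trait: int,
    enriched_fraction: float,
    rng: np.random.Generator | None = None,
    in_window_fraction: float = 0.5,
) -> tuple[list[TraitVariantSet], pd.DataFrame]:
    """Trait-associated variant sets drawn from scored variants.

    Null traits sample uniformly; enriched traits draw
    ``round(k * in_window_fraction)`` of their variants from inside
    selected-locus windows (the rest uniformly outside). Returns the sets
    and a truth table of enrichment flags.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = scored_sites["chrom"].to_numpy()
    pos = scored_sites["pos"].to_numpy()
    in_window = np.zeros(len(scored_sites), dtype=bool)
    for locus in config.selected_loci:
        in_window |= (chrom == locus.chrom) & (
            np.abs(pos - locus.pos) <= locus.half_width
        )
    win_idx = np.flatnonzero(in_window)
    out_idx = np.flatnonzero(~in_window)
    n_enriched = int(round(n_traits * enriched_fraction))
    sets, flags = [], []
    for t in range(n_traits):
        enriched = t < n_enriched and win_idx.size > 0
        if enriched:
            k_in = min(int(round(k_per_trait * in_window_fraction)), win_idx.size)
            pick = np.concatenate(
                [
                    rng.choice(win_idx, size=k_in, replace=False),
                    rng.choice(out_idx, size=k_per_trait - k_in, replace=False),
                ]
            )
        else:
            pick = rng.choice(out_idx, size=min(k_per_trait, out_idx.size), replace=False)
        sets.append(
            TraitVariantSet(
                name=f"trait_{t:03d}",
                category="quantitative",
                variants=[(chrom[i], int(pos[i])) for i in pick],
            )
        )
        flags.append({"trait": f"trait_{t:03d}", "enriched": bool(enriched)})
    return sets, pd.DataFrame(flags)
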