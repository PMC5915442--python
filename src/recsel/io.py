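"""Readers and writers: phased VCF panels, BED interval sets, TSV tables.

Panels are read with cyvcf2 and polarized on the fly: sites whose ancestral
annotation (INFO key, default ``AA``) equals ALT are flipped to derived
orientation; sites where it matches neither allele, or is absent, are
dropped and counted. Multi-allelic records are excluded so that polarity
stays well defined. Ancestral annotations are assumed to already be on the
reference strand; no complementation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import IntervalSet
from .panel import SAMPLE_COLUMNS, SITE_COLUMNS, HaplotypePanel


@dataclass
class PanelReadReport:
    """Per-file accounting of retained and dropped records."""

    n_retained: int = 0
    drop_no_polarity: int = 0
    drop_polarity_mismatch: int = 0
    drop_multiallelic: int = 0

    @property
    def drop_count(self) -> int:
        return self.drop_no_polarity + self.drop_polarity_mismatch + self.drop_multiallelic


def read_panel(
    path: str,
    polarity_key: str = "AA",
    sample_metadata: pd.DataFrame | None = None,
    default_dataset: str = "d1",
) -> tuple[HaplotypePanel, PanelReadReport]:
    """Read a phased VCF into a derived-allele-oriented :class:`HaplotypePanel`.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped).
    polarity_key:
        INFO key holding the ancestral allele.
    sample_metadata:
        Optional table with columns ``sample``, ``dataset``, ``region``;
        samples absent from it get ``default_dataset`` and region ``"all"``.

    Raises
    ------
    OSError
        If the file cannot be opened.
    ValueError
        On an unphased heterozygous genotype, naming the offending record.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    report = PanelReadReport()
    chroms, poss, ancs, ders = [], [], [], []
    hap_rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            report.drop_multiallelic += 1
            continue
        aa = v.INFO.get(polarity_key)
        if aa is None:
            report.drop_no_polarity += 1
            continue
        aa = str(aa).upper()
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if aa == ref:
            flip = False
        elif aa == alt:
            flip = True
        else:
            report.drop_polarity_mismatch += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        row = np.empty((len(samples), 2), dtype=np.int8)
        for i, (a0, a1, *rest) in enumerate(gts):
            phased = bool(rest[0]) if rest else False
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype at {v.CHROM}:{v.POS} sample {samples[i]}"
                )
            if not phased and a0 != a1:
                raise ValueError(
                    f"unphased heterozygote at {v.CHROM}:{v.POS} sample {samples[i]}"
                )
            row[i, 0], row[i, 1] = a0, a1
        if flip:
            row = 1 - row
            anc, der = alt, ref
        else:
            anc, der = ref, alt
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ancs.append(anc)
        ders.append(der)
        hap_rows.append(row)
        report.n_retained += 1

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ancestral": ancs, "derived": ders},
        columns=SITE_COLUMNS,
    )
    haps = (
        np.stack(hap_rows)
        if hap_rows
        else np.zeros((0, len(samples), 2), dtype=np.int8)
    )
    meta = pd.DataFrame({"sample": samples})
    meta["dataset"] = default_dataset
    meta["region"] = "all"
    if sample_metadata is not None:
        lookup = sample_metadata.set_index("sample")
        for col in ("dataset", "region"):
            if col in lookup.columns:
                meta[col] = (
                    meta["sample"].map(lookup[col]).fillna(meta[col]).to_numpy()
                )
    panel = HaplotypePanel(sites=sites, haplotypes=haps, samples=meta[SAMPLE_COLUMNS])
    return panel, report


def write_panel(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a minimal phased VCF (ancestral allele as REF + AA tag)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample"])
            + "\n"
        )
        for j in range(panel.n_sites):
            site = panel.sites.iloc[j]
            gts = "\t".join(
                f"{a}|{b}" for a, b in panel.haplotypes[j]
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.chrom}:{site.pos}\t"
                f"{site.ancestral}\t{site.derived}\t.\tPASS\t"
                f"AA={site.ancestral}\tGT\t{gts}\n"
            )


def read_intervals(path: str) -> IntervalSet:
    """Read a 3+ column BED file into a normalized :class:`IntervalSet`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start} >= {end})")
            intervals.append((chrom, start, end))
    return IntervalSet(intervals).normalized()


def write_intervals(intervals: IntervalSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.normalized():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_table(df: pd.DataFrame, path: str, header_lines: list[str] | None = None) -> None:
    """Write a TSV with optional ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
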