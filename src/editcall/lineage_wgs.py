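"""Three-line whole-genome lineage analysis.

The study design is a chain of three clonal cell lines — an ancestral WT
clone, its descendant KR clone, and KR's descendant KR-KSC clone — sequenced
to moderate coverage.  Variants that appear in both descendants but not in
the ancestor arose during the WT era of culture; variants private to the last
clone arose during the KR era.  After strict site filtering (mappability
masks, a coverage corridor in all three lines, and a minimum spread of
alt-allele frequencies across the lines), the count of novel variants per era
is extrapolated from the surveyed fraction of the genome to a whole-genome
mutation-fixation rate per passage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

LINES = ("WT", "KR", "KR-KSC")

LINEAGES = ("ancestral", "wt_era", "kr_era", "unassigned")


class LineageError(ValueError):
    pass


@dataclass(frozen=True)
class LineCall:
    """One cell line's evidence at a site."""

    depth: int
    genotype: str  # e.g. "0/0", "0/1", "1/1"
    alt_af: float

    def has_alt(self) -> bool:
        return "1" in self.genotype


@dataclass(frozen=True)
class VariantSite:
    """One genomic position's evidence across the three cell lines.

    ``pos`` is 0-based internally; the VCF boundary converts from 1-based.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    lines: Mapping[str, LineCall]
    filter_status: str = "unfiltered"
    lineage: str = "unassigned"


@dataclass(frozen=True)
class LineageConfig:
    """Filtering and extrapolation parameters.

    ``surveyed_bp`` is the number of bases passing all site filters (the
    denominator of the extrapolation); ``genome_bp`` must be supplied
    explicitly for any rate report.
    """

    cov_min: int = 30
    cov_max: int = 50
    af_spread_min: float = 0.30
    window_bp: int = 1_000_000
    surveyed_bp: float | None = None
    genome_bp: float | None = None

    def __post_init__(self) -> None:
        if self.cov_min > self.cov_max:
            raise LineageError("cov_min must be <= cov_max")
        if not 0 <= self.af_spread_min <= 1:
            raise LineageError("af_spread_min must be in [0, 1]")


# ---------------------------------------------------------------------------
# region masks

def read_mask_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees."""
    masks: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LineageError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise LineageError(f"{path}:{lineno}: non-integer coordinates") from None
            if s > e:
                raise LineageError(f"{path}:{lineno}: start > end")
            if s < e:
                masks.setdefault(chrom, IntervalTree()).addi(s, e)
    return masks


def merge_masks(mask_sets: Iterable[Mapping[str, IntervalTree]]) -> dict[str, IntervalTree]:
    merged: dict[str, IntervalTree] = {}
    for masks in mask_sets:
        for chrom, tree in masks.items():
            dest = merged.setdefault(chrom, IntervalTree())
            for iv in tree:
                dest.addi(iv.begin, iv.end)
    for tree in merged.values():
        tree.merge_overlaps()
    return merged


def _is_masked(masks: Mapping[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = masks.get(chrom)
    return bool(tree is not None and tree.overlaps(pos))


def _masked_length(masks: Mapping[str, IntervalTree], chrom: str, start: int, end: int) -> int:
    tree = masks.get(chrom)
    if tree is None:
        return 0
    covered = IntervalTree()
    for iv in tree.overlap(start, end):
        covered.addi(max(iv.begin, start), min(iv.end, end))
    covered.merge_overlaps()
    return sum(iv.end - iv.begin for iv in covered)


# ---------------------------------------------------------------------------
# VCF boundary

def read_sites_vcf(path: str | Path, sample_names: Sequence[str] = LINES) -> list[VariantSite]:
    """Read a three-sample VCF into :class:`VariantSite` records.

    Uses per-sample GT, DP and AD; alt-allele frequency is ``AD[1] / DP``.
    Multi-allelic records are rejected (the filtering model is biallelic).
    """
    import pysam

    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        missing = [s for s in sample_names if s not in vcf_samples]
        if missing:
            raise LineageError(f"{path}: samples {missing} not in VCF header {vcf_samples}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise LineageError(
                    f"{path}:{rec.chrom}:{rec.pos}: exactly one ALT allele required"
                )
            lines = {}
            for name in sample_names:
                smp = rec.samples[name]
                depth = int(smp.get("DP") or 0)
                gt = smp.get("GT")
                gt_str = "/".join("." if a is None else str(a) for a in (gt or (None, None)))
                ad = smp.get("AD")
                alt_depth = int(ad[1]) if ad is not None and len(ad) > 1 and ad[1] is not None else 0
                af = alt_depth / depth if depth > 0 else 0.0
                lines[name] = LineCall(depth=depth, genotype=gt_str, alt_af=af)
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    lines=lines,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# filtering and lineage assignment

def apply_site_filters(
    sites: Sequence[VariantSite],
    masks: Mapping[str, IntervalTree],
    config: LineageConfig,
) -> list[VariantSite]:
    """Keep sites that are unmasked, in the coverage corridor, and AF-spread-positive.

    A site survives iff (a) it overlaps no mask region, (b) every line's depth
    lies in ``[cov_min, cov_max]`` inclusive, and (c) the difference between
    the maximum and minimum alt-allele frequency across the lines is at least
    ``af_spread_min``.  Surviving sites are annotated ``filter_status="pass"``.
    """
    kept: list[VariantSite] = []
    for site in sites:
        if _is_masked(masks, site.chrom, site.pos):
            continue
        depths = [site.lines[l].depth for l in LINES]
        if any(d < config.cov_min or d > config.cov_max for d in depths):
            continue
        afs = [site.lines[l].alt_af for l in LINES]
        if max(afs) - min(afs) < config.af_spread_min:
            continue
        kept.append(replace(site, filter_status="pass"))
    return kept


def assign_lineage(site: VariantSite) -> str:
    """Era assignment from the presence pattern of the alt allele.

    Alt in KR and KR-KSC but not WT → ``wt_era`` (the mutation arose while the
    ancestral line was growing); alt only in KR-KSC → ``kr_era``; alt in all
    three → ``ancestral``; any other pattern → ``unassigned``.
    """
    wt, kr, ksc = (site.lines[l].has_alt() for l in LINES)
    if wt and kr and ksc:
        return "ancestral"
    if not wt and kr and ksc:
        return "wt_era"
    if not wt and not kr and ksc:
        return "kr_era"
    return "unassigned"


def assign_lineages(sites: Sequence[VariantSite]) -> tuple[list[VariantSite], dict[str, int]]:
    """Annotate filtered sites with lineage labels and tally them."""
    annotated = [replace(s, lineage=assign_lineage(s)) for s in sites]
    counts = {label: 0 for label in LINEAGES}
    for s in annotated:
        counts[s.lineage] += 1
    return annotated, counts


# ---------------------------------------------------------------------------
# coverage and rates

def coverage_windows(
    depth_records: Iterable[tuple[str, int, int, float]],
    masks: Mapping[str, IntervalTree],
    window_bp: int = 1_000_000,
    min_unmasked_fraction: float = 0.10,
) -> pd.DataFrame:
    """Mean depth over unmasked bases in non-overlapping genomic windows.

    ``depth_records`` are bedgraph-style ``(chrom, start, end, depth)``
    intervals (0-based half-open), sorted within each chromosome.  Windows
    whose unmasked fraction falls below ``min_unmasked_fraction`` are reported
    with ``NaN`` mean depth.
    """
    spans: dict[str, int] = {}
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, depth in depth_records:
        by_chrom.setdefault(chrom, []).append((start, end, depth))
        spans[chrom] = max(spans.get(chrom, 0), end)
    rows = []
    for chrom in sorted(by_chrom):
        n_windows = math.ceil(spans[chrom] / window_bp)
        sums = [0.0] * n_windows
        covered = [0] * n_windows
        for start, end, depth in by_chrom[chrom]:
            w = start // window_bp
            while w < n_windows and w * window_bp < end:
                w0, w1 = w * window_bp, (w + 1) * window_bp
                s, e = max(start, w0), min(end, w1)
                if s < e:
                    masked = _masked_length(masks, chrom, s, e)
                    sums[w] += depth * (e - s - masked)
                    covered[w] += e - s - masked
                w += 1
        for w in range(n_windows):
            w0, w1 = w * window_bp, (w + 1) * window_bp
            size = min(w1, spans[chrom]) - w0
            unmasked = size - _masked_length(masks, chrom, w0, w0 + size)
            mean = sums[w] / unmasked if unmasked >= min_unmasked_fraction * size and unmasked > 0 else float("nan")
            rows.append(
                {"chrom": chrom, "start": w0, "end": w0 + size, "mean_depth": mean, "unmasked_bp": unmasked}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_depth", "unmasked_bp"])


def mutation_rate_per_passage(
    n_novel: int, passages: int, surveyed_bp: float, genome_bp: float
) -> float:
    """Whole-genome mutation-fixation rate per passage.

    ``(n_novel / passages) * (genome_bp / surveyed_bp)``: the per-passage
    count of novel fixed variants in the surveyed fraction, extrapolated to
    the full genome.
    """
    if passages <= 0:
        raise LineageError("passages must be positive")
    if surveyed_bp <= 0:
        raise LineageError("surveyed_bp must be positive")
    if genome_bp <= 0:
        raise LineageError("genome_bp must be positive")
    return (n_novel / passages) * (genome_bp / surveyed_bp)


def loh_runs(sites: Sequence[VariantSite], min_run: int = 10) -> list[dict]:
    """Runs of consecutive sites heterozygous in WT but homozygous in both descendants.

    A reporting query for loss-of-heterozygosity scans (e.g. a chromosome-arm
    conversion event); no mechanistic inference is attempted.
    """

    def _is_loh(site: VariantSite) -> bool:
        def het(gt: str) -> bool:
            alleles = gt.replace("|", "/").split("/")
            return len(set(alleles)) > 1 and "." not in alleles

        return (
            het(site.lines["WT"].genotype)
            and not het(site.lines["KR"].genotype)
            and not het(site.lines["KR-KSC"].genotype)
        )

    runs = []
    current: list[VariantSite] = []
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    for site in ordered:
        if current and (site.chrom != current[-1].chrom or not _is_loh(site)):
            if len(current) >= min_run:
                runs.append(
                    {
                        "chrom": current[0].chrom,
                        "start": current[0].pos,
                        "end": current[-1].pos + 1,
                        "n_sites": len(current),
                    }
                )
            current = []
        if _is_loh(site):
            current.append(site)
    if len(current) >= min_run:
        runs.append(
            {
                "chrom": current[0].chrom,
                "start": current[0].pos,
                "end": current[-1].pos + 1,
                "n_sites": len(current),
            }
        )
    return runs
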