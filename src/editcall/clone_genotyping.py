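"""Genotyping of single-cell-derived colonies from per-colony amplicon reads.

Reads from one colony are collapsed into alleles by their windowed alignment
signature (indels plus the programmed-substitution pattern), so that isolated
sequencing errors never split an allele.  A colony is called homozygous when a
clear majority of reads carry a single allele, heterozygous when two alleles
of similar abundance together form a clear majority, and otherwise not clonal.

Across colonies and targets, the fraction of colonies homozygous for the HDR
allele at every target is compared with the product of the per-target
homozygous frequencies — the expectation if edits at different genes were
independent — to quantify the enrichment of jointly edited clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod
from typing import Iterable, Mapping, Sequence

from .alignment import IndelEvent
from .target_model import ClassifierConfig, TargetSpec, build_expected_hdr


class GenotypingError(ValueError):
    pass


@dataclass(frozen=True)
class Allele:
    """Canonical allele reconstructed from a windowed alignment signature."""

    sequence: str
    label: str  # WT | HDR | PARTIAL | INDEL(<events>)


@dataclass(frozen=True)
class CloneCall:
    """Zygosity call for one colony at one target."""

    status: str  # homozygous | heterozygous | not_clonal | low_depth
    alleles: tuple[Allele, ...] = ()
    depth: int = 0

    def is_homozygous_hdr(self) -> bool:
        return self.status == "homozygous" and self.alleles[0].label == "HDR"


def _signature_sequence(
    spec: TargetSpec, indels: Sequence[IndelEvent], present_subs: Sequence[int]
) -> str:
    seq = list(spec.reference)
    for i in present_subs:
        sub = spec.substitutions[i]
        seq[sub.position] = sub.alt_base
    for ev in sorted(indels, key=lambda e: e.ref_start, reverse=True):
        if ev.kind == "deletion":
            seq[ev.ref_start : ev.ref_end] = []
        else:
            seq[ev.ref_start : ev.ref_start] = list(ev.inserted_seq)
    return "".join(seq)


def _allele_label(spec: TargetSpec, indels: Sequence[IndelEvent], status: str) -> str:
    if indels:
        desc = ",".join(
            f"{ev.ref_start}{'I' if ev.kind == 'insertion' else 'D'}{ev.length}"
            for ev in indels
        )
        return f"INDEL({desc})"
    if status == "all" and spec.substitutions:
        return "HDR"
    if status == "some":
        return "PARTIAL"
    return "WT"


def collapse_alleles(
    reads: Iterable[str], spec: TargetSpec, config: ClassifierConfig | None = None
) -> dict[Allele, int]:
    """Group reads into alleles by windowed alignment signature.

    Reads failing the similarity filter are dropped.  Differences confined to
    unprogrammed substitutions (sequencing errors) collapse onto the same
    allele because the signature records only windowed indels and the
    programmed-substitution presence pattern.
    """
    if config is None:
        config = ClassifierConfig()
    from .alignment import align_read, normalize_deletions, read_base_at, similarity_filter
    from .target_model import quantification_window

    windows = quantification_window(spec, config.window_bp)
    windowed_subs = [
        (i, sub)
        for i, sub in enumerate(spec.substitutions)
        if any(a <= sub.position < b for a, b in windows)
    ]
    counts: dict[Allele, int] = {}
    for read in reads:
        aln = normalize_deletions(align_read(read, spec.reference, config))
        if not similarity_filter(aln, config):
            continue
        indels = tuple(
            ev
            for ev in aln.indels
            if any(
                (a <= ev.ref_start <= b)
                if ev.kind == "insertion"
                else (ev.ref_start < b and ev.ref_end > a)
                for a, b in windows
            )
        )
        present = tuple(
            i for i, sub in windowed_subs if read_base_at(aln, sub.position) == sub.alt_base
        )
        if not windowed_subs:
            status = "none"
        elif len(present) == len(windowed_subs):
            status = "all"
        else:
            status = "some" if present else "none"
        allele = Allele(
            sequence=_signature_sequence(spec, indels, present),
            label=_allele_label(spec, indels, status),
        )
        counts[allele] = counts.get(allele, 0) + 1
    return counts


def call_clone_genotype(
    allele_counts: Mapping[Allele, int],
    depth_floor: int = 50,
    majority: float = 0.80,
    het_minor: float = 0.25,
) -> CloneCall:
    """Zygosity call from allele counts.

    Below ``depth_floor`` reads the colony is ``low_depth``.  A single allele
    holding at least ``majority`` of reads is homozygous.  Two alleles each
    holding strictly more than ``het_minor`` and jointly at least ``majority``
    are heterozygous.  Anything else — including three substantial alleles —
    is ``not_clonal``.  Ties between equally abundant alleles are broken
    lexicographically by allele sequence, making the call order-independent.
    """
    total = sum(allele_counts.values())
    if total < depth_floor:
        return CloneCall(status="low_depth", depth=total)
    ranked = sorted(allele_counts.items(), key=lambda kv: (-kv[1], kv[0].sequence))
    top, top_n = ranked[0]
    if top_n >= majority * total:
        return CloneCall(status="homozygous", alleles=(top,), depth=total)
    if len(ranked) >= 2:
        second, second_n = ranked[1]
        if (
            top_n > het_minor * total
            and second_n > het_minor * total
            and top_n + second_n >= majority * total
        ):
            pair = tuple(sorted((top, second), key=lambda a: a.sequence))
            return CloneCall(status="heterozygous", alleles=pair, depth=total)
    return CloneCall(status="not_clonal", depth=total)


def genotype_colony(
    reads_by_target: Mapping[str, Iterable[str]],
    specs: Mapping[str, TargetSpec],
    config: ClassifierConfig | None = None,
    depth_floor: int = 50,
    majority: float = 0.80,
    het_minor: float = 0.25,
) -> dict[str, CloneCall]:
    """Per-target zygosity calls for one colony."""
    calls = {}
    for target, reads in reads_by_target.items():
        counts = collapse_alleles(reads, specs[target], config)
        calls[target] = call_clone_genotype(counts, depth_floor, majority, het_minor)
    return calls


def all_homozygous_fraction(
    genotypes: Sequence[Mapping[str, CloneCall]], targets: Sequence[str]
) -> float:
    """Fraction of clonal colonies homozygous for the HDR allele at every target.

    Colonies with any ``low_depth`` or ``not_clonal`` call are excluded from
    the denominator.
    """
    if not genotypes:
        raise GenotypingError("no colonies")
    usable = 0
    hits = 0
    for colony in genotypes:
        calls = [colony[t] for t in targets]
        if any(c.status in ("low_depth", "not_clonal") for c in calls):
            continue
        usable += 1
        if all(c.is_homozygous_hdr() for c in calls):
            hits += 1
    if usable == 0:
        raise GenotypingError("no clonal colonies")
    return hits / usable


def per_target_homozygous_hdr_freqs(
    genotypes: Sequence[Mapping[str, CloneCall]], targets: Sequence[str]
) -> list[float]:
    """Per-target frequency of homozygous-HDR calls among clonal colonies."""
    freqs = []
    for t in targets:
        calls = [
            g[t] for g in genotypes if g[t].status in ("homozygous", "heterozygous")
        ]
        if not calls:
            raise GenotypingError(f"no clonal colonies for target {t!r}")
        freqs.append(sum(c.is_homozygous_hdr() for c in calls) / len(calls))
    return freqs


def independence_expectation(per_gene_hom_freqs: Sequence[float]) -> float:
    """Expected all-homozygous fraction if per-gene edits were independent."""
    for f in per_gene_hom_freqs:
        if not 0 <= f <= 1:
            raise GenotypingError(f"frequency {f} outside [0, 1]")
    return prod(per_gene_hom_freqs)


def enrichment(observed: float, expected: float) -> float:
    """Fold enrichment of the observed joint frequency over the expectation."""
    if expected == 0:
        raise GenotypingError("expected frequency is zero")
    return observed / expected
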