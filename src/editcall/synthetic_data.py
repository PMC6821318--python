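"""Synthetic inputs with known truth for every pipeline stage.

Real amplicon sequencing of edited cell pools is emulated by three
generators:

* amplicon read sets drawn from specified outcome proportions
  (WT/HDR/mix/NHEJ/MMEJ) over a designed amplicon that carries repeat pairs
  near the cut site, so MMEJ deletions with exact, known microhomology
  lengths can be planted;
* per-colony read sets with known diploid genotypes, for the clone-genotyping
  stage;
* three-line genotype tables with planted ancestral / WT-era / KR-era
  variants plus noise sites that each violate one site filter, for the
  lineage stage.

Every generator is a pure function of its seed and recipe; planted NHEJ
deletions are verified to have microhomology <= 1 and planted MMEJ deletions
>= 2 against the classifier's own microhomology measure before emission.

The error model is independent uniform base substitutions (default
0.001/base); no error indels are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .lineage_wgs import LINES, LineCall, VariantSite
from .outcome_classifier import microhomology_length
from .target_model import (
    ClassifierConfig,
    GuideSite,
    Substitution,
    TargetSpec,
    build_expected_hdr,
    quantification_window,
)

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedDeletion:
    """A repeat-bounded deletable segment with known junction microhomology."""

    start: int
    end: int
    microhomology: int


@dataclass(frozen=True)
class SimulationRecipe:
    """Everything needed to draw one amplicon read set reproducibly."""

    spec: TargetSpec
    planted_deletions: tuple[PlantedDeletion, ...]
    proportions: Mapping[str, float]
    n_reads: int
    seed: int
    error_rate: float = 0.001
    nhej_max_indel: int = 10
    nhej_geom_p: float = 0.5
    mmej_mh_weights: Mapping[int, float] | None = None
    window_bp: int = 20

    def __post_init__(self) -> None:
        allowed = {"WT", "HDR", "MIX", "NHEJ", "MMEJ"}
        extra = set(self.proportions) - allowed
        if extra:
            raise SimulationError(f"unknown outcome categories {sorted(extra)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"proportions sum to {total}, expected 1")
        if not 0 <= self.error_rate <= 0.05:
            raise SimulationError("error_rate must be in [0, 0.05]")
        if self.n_reads < 0:
            raise SimulationError("n_reads must be >= 0")
        if self.proportions.get("MMEJ", 0) > 0 and not self.planted_deletions:
            raise SimulationError("MMEJ proportion requires planted deletions")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def design_mmej_amplicon(
    base_length: int = 200,
    mh_lengths: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    name: str = "synthetic_locus",
    spacer_len: int = 1,
    max_attempts: int = 500,
) -> tuple[TargetSpec, tuple[PlantedDeletion, ...]]:
    """Design an amplicon with repeat pairs planted near the cut site.

    For each requested microhomology length ``L >= 1`` a block
    ``repeat + spacer + repeat`` is placed near the guide cut; deleting the
    first repeat plus the spacer leaves a junction with microhomology exactly
    ``L``.  Each planted deletion is verified against
    :func:`~editcall.outcome_classifier.microhomology_length` and the whole
    amplicon is redrawn if flanking sequence accidentally extends a junction.
    The target also carries one targeted and one blocking substitution inside
    the quantification window, clear of the planted blocks.

    Returns the :class:`TargetSpec` and the planted deletions (truth).
    Lengths of 0 are skipped (no repeat planted); an empty list yields an
    amplicon without planted repeats.
    """
    if base_length < 60:
        raise SimulationError("base_length must be >= 60")
    lengths = [int(L) for L in mh_lengths if int(L) >= 1]
    cut = base_length // 2
    window = 20
    block_total = sum(2 * L + spacer_len for L in lengths)
    first_block = cut - 12
    if block_total > (cut + window) - first_block:
        raise SimulationError(
            f"cannot place repeats without collision: {block_total} bp of repeat "
            f"blocks exceed the space near the cut site"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        seq = list(_random_seq(rng, base_length))
        planted: list[PlantedDeletion] = []
        pos = first_block
        for L in lengths:
            repeat = _random_seq(rng, L)
            spacer = _random_seq(rng, spacer_len)
            block = repeat + spacer + repeat
            seq[pos : pos + len(block)] = list(block)
            planted.append(PlantedDeletion(pos, pos + L + spacer_len, L))
            pos += len(block)
        reference = "".join(seq)
        if any(
            microhomology_length(reference, d.start, d.end) != d.microhomology
            for d in planted
        ):
            continue  # flank extended a junction by chance; redraw
        targeted_pos = first_block - 3
        blocking_pos = first_block - 6
        substitutions = tuple(
            sorted(
                (
                    _substitute_other(rng, reference, targeted_pos, "targeted"),
                    _substitute_other(rng, reference, blocking_pos, "blocking"),
                ),
                key=lambda s: s.position,
            )
        )
        spec = TargetSpec(
            name=name,
            reference=reference,
            guides=(GuideSite(cut_position=cut, label="g1"),),
            substitutions=substitutions,
        )
        return spec, tuple(planted)
    raise SimulationError("could not design amplicon with exact microhomologies")


def _substitute_other(
    rng: np.random.Generator, reference: str, position: int, role: str
) -> Substitution:
    ref_base = reference[position]
    alt = rng.choice([b for b in "ACGT" if b != ref_base])
    return Substitution(position=position, ref_base=ref_base, alt_base=str(alt), role=role)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i].decode()
        arr[i] = rng.choice([b for b in "ACGT" if b != current]).encode()
    return arr.tobytes().decode()


def _draw_nhej_indel(
    rng: np.random.Generator,
    reference: str,
    window: tuple[int, int],
    recipe: SimulationRecipe,
    forbidden_positions: frozenset[int] = frozenset(),
    require_low_mh: bool = True,
) -> str:
    """Reference with one indel whose junction carries no real microhomology.

    Deletions are redrawn until their microhomology is <= 1 (when
    ``require_low_mh``) and they avoid ``forbidden_positions`` (used to keep
    MIX indels clear of the programmed substitutions).
    """
    a, b = window
    n = len(reference)
    for _ in range(1000):
        length = int(min(rng.geometric(recipe.nhej_geom_p), recipe.nhej_max_indel))
        if rng.random() < 0.5:  # insertion
            pos = int(rng.integers(a + 1, b))
            seq = _random_seq(rng, length)
            # left-normalize as the classifier will; redraw if the insertion
            # slides out of the window
            p, s = pos, seq
            while p > 0 and reference[p - 1] == s[-1]:
                s = s[-1] + s[:-1]
                p -= 1
            if not a <= p <= b:
                continue
            return reference[:pos] + seq + reference[pos:]
        start = int(rng.integers(a, b))
        end = start + length
        if end > n:
            continue
        if require_low_mh and microhomology_length(reference, start, end) > 1:
            continue
        s, e = start, end
        while s > 0 and reference[s - 1] == reference[e - 1]:
            s -= 1
            e -= 1
        if not (s < b and e > a):  # slid out of the window
            continue
        # keep every equivalent placement clear of the forbidden positions
        if any(s <= p < end for p in forbidden_positions):
            continue
        return reference[:start] + reference[end:]
    raise SimulationError("could not draw an NHEJ-style indel")


def simulate_amplicon_reads(
    recipe: SimulationRecipe,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw amplicon reads by outcome category, with per-read truth.

    WT reads are the reference; HDR reads the expected-HDR sequence; MIX
    reads the expected-HDR sequence with one NHEJ-style indel in the window
    (avoiding the programmed substitutions); NHEJ reads carry an indel with
    junction microhomology <= 1; MMEJ reads delete a planted repeat-bounded
    segment.  Uniform base-substitution errors are applied last.
    """
    rng = np.random.default_rng(recipe.seed)
    spec = recipe.spec
    hdr_seq = build_expected_hdr(spec)
    windows = quantification_window(spec, recipe.window_bp)
    window = windows[0]
    sub_positions = frozenset(s.position for s in spec.substitutions)

    categories = list(recipe.proportions)
    probs = np.array([recipe.proportions[c] for c in categories], dtype=float)
    draws = rng.choice(len(categories), size=recipe.n_reads, p=probs / probs.sum())

    mmej_choices = list(recipe.planted_deletions)
    if mmej_choices:
        if recipe.mmej_mh_weights is not None:
            w = np.array(
                [recipe.mmej_mh_weights.get(d.microhomology, 0.0) for d in mmej_choices],
                dtype=float,
            )
            if w.sum() <= 0:
                raise SimulationError("mmej_mh_weights give zero mass to planted deletions")
        else:
            w = np.ones(len(mmej_choices))
        mmej_probs = w / w.sum()

    reads: list[tuple[str, str]] = []
    truth_rows = []
    for i, k in enumerate(draws):
        category = categories[k]
        detail = ""
        if category == "WT":
            seq = spec.reference
        elif category == "HDR":
            seq = hdr_seq
        elif category == "MIX":
            seq = _draw_nhej_indel(
                rng, hdr_seq, window, recipe,
                forbidden_positions=sub_positions, require_low_mh=False,
            )
        elif category == "NHEJ":
            seq = _draw_nhej_indel(rng, spec.reference, window, recipe)
        else:  # MMEJ
            d = mmej_choices[int(rng.choice(len(mmej_choices), p=mmej_probs))]
            seq = spec.reference[: d.start] + spec.reference[d.end :]
            detail = f"mh={d.microhomology}"
        seq = _apply_errors(rng, seq, recipe.error_rate)
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        truth_rows.append({"read_id": rid, "category": category, "detail": detail})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "category", "detail"])
    return reads, truth


# ---------------------------------------------------------------------------
# colonies

ALLELE_CHOICES = ("HDR", "WT")


def draw_colony_genotypes(
    n_colonies: int,
    targets: Sequence[str],
    hom_hdr_p: float = 0.35,
    het_p: float = 0.40,
    seed: int = 0,
) -> dict[str, dict[str, tuple[str, str]]]:
    """Draw per-colony diploid genotypes independently per target.

    Each target is homozygous-HDR with probability ``hom_hdr_p``,
    heterozygous HDR/WT with probability ``het_p``, homozygous-WT otherwise.
    """
    rng = np.random.default_rng(seed)
    genotypes: dict[str, dict[str, tuple[str, str]]] = {}
    for c in range(n_colonies):
        colony = f"colony{c:04d}"
        per_target = {}
        for t in targets:
            u = rng.random()
            if u < hom_hdr_p:
                per_target[t] = ("HDR", "HDR")
            elif u < hom_hdr_p + het_p:
                per_target[t] = ("HDR", "WT")
            else:
                per_target[t] = ("WT", "WT")
        genotypes[colony] = per_target
    return genotypes


def allele_sequence(spec: TargetSpec, allele: str) -> str:
    """Sequence of a named allele: WT, HDR, or ``DEL:<start>-<end>``."""
    if allele == "WT":
        return spec.reference
    if allele == "HDR":
        return build_expected_hdr(spec)
    if allele.startswith("DEL:"):
        start, end = (int(x) for x in allele[4:].split("-"))
        return spec.reference[:start] + spec.reference[end:]
    raise SimulationError(f"unknown allele {allele!r}")


def simulate_clone_readsets(
    colony_genotypes: Mapping[str, Mapping[str, tuple[str, str]]],
    specs: Mapping[str, TargetSpec],
    depth: int = 100,
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], list[tuple[str, str]]], pd.DataFrame]:
    """Per-colony, per-target read sets from known diploid genotypes.

    Homozygous colonies emit one allele; heterozygous colonies draw the two
    alleles 50/50 binomially.  Returns reads keyed by ``(colony, target)``
    and a truth table with the planted zygosity.
    """
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    reads: dict[tuple[str, str], list[tuple[str, str]]] = {}
    rows = []
    for colony in colony_genotypes:
        for target, (a, b) in colony_genotypes[colony].items():
            spec = specs[target]
            seq_a = allele_sequence(spec, a)
            if a == b:
                pool = [seq_a] * depth
                zygosity = "homozygous"
            else:
                n_a = int(rng.binomial(depth, 0.5))
                pool = [seq_a] * n_a + [allele_sequence(spec, b)] * (depth - n_a)
                zygosity = "heterozygous"
            out = [
                (f"{colony}:{target}:r{i}", _apply_errors(rng, s, error_rate))
                for i, s in enumerate(pool)
            ]
            reads[(colony, target)] = out
            rows.append(
                {
                    "colony": colony,
                    "target": target,
                    "allele_a": a,
                    "allele_b": b,
                    "zygosity": zygosity,
                }
            )
    truth = pd.DataFrame(rows, columns=["colony", "target", "allele_a", "allele_b", "zygosity"])
    return reads, truth


# ---------------------------------------------------------------------------
# lineage tables

_PATTERNS = {
    # lineage label -> (GT per line, target alt AF per line)
    "ancestral": (("1/1", "0/1", "0/1"), (1.0, 0.5, 0.5)),
    "wt_era": (("0/0", "0/1", "0/1"), (0.0, 0.5, 0.5)),
    "kr_era": (("0/0", "0/0", "0/1"), (0.0, 0.0, 0.5)),
}


def _clamped_alt_depth(rng: np.random.Generator, depth: int, af: float) -> int:
    if af == 0.0:
        return 0
    if af == 1.0:
        return depth
    lo, hi = int(np.ceil(0.40 * depth)), int(np.floor(0.60 * depth))
    alt = int(rng.binomial(depth, af))
    return min(max(alt, lo), hi)


def simulate_lineage_sites(
    n_ancestral: int = 10,
    n_wt_era: int = 5,
    n_kr_era: int = 3,
    n_noise: int = 50,
    depth_range: tuple[int, int] = (30, 50),
    seed: int = 0,
    chrom: str = "chr1",
    spacing: int = 1000,
) -> tuple[list[VariantSite], dict[str, IntervalTree], pd.DataFrame]:
    """Three-line genotype table with planted lineage variants and noise.

    Planted sites pass all filters by construction (depths inside the
    corridor, alt-allele frequencies clamped so the cross-line spread stays
    >= 0.4).  Noise sites each violate exactly one filter, cycling through
    out-of-corridor depth, insufficient AF spread, and masked position.
    """
    rng = np.random.default_rng(seed)
    lo, hi = depth_range
    labels = (
        ["ancestral"] * n_ancestral + ["wt_era"] * n_wt_era + ["kr_era"] * n_kr_era
    )
    noise_kinds = [("bad_depth", "low_spread", "masked")[i % 3] for i in range(n_noise)]
    entries = [(label, None) for label in labels] + [("noise", kind) for kind in noise_kinds]
    order = rng.permutation(len(entries))

    sites: list[VariantSite] = []
    mask_regions: list[tuple[int, int]] = []
    rows = []
    for rank, idx in enumerate(order):
        label, noise_kind = entries[idx]
        pos = (rank + 1) * spacing
        ref, alt = "A", "G"
        if label != "noise":
            gts, afs = _PATTERNS[label]
            depths = [int(rng.integers(lo, hi + 1)) for _ in LINES]
            alt_depths = [_clamped_alt_depth(rng, d, af) for d, af in zip(depths, afs)]
        elif noise_kind == "bad_depth":
            gts, afs = _PATTERNS["kr_era"]
            depths = [int(rng.integers(lo, hi + 1)) for _ in LINES]
            bad_line = int(rng.integers(0, 3))
            depths[bad_line] = int(rng.choice([lo - 5, hi + 10]))
            alt_depths = [_clamped_alt_depth(rng, d, af) for d, af in zip(depths, afs)]
        elif noise_kind == "low_spread":
            gts = ("0/1", "0/1", "0/1")
            depths = [int(rng.integers(lo, hi + 1)) for _ in LINES]
            alt_depths = [_clamped_alt_depth(rng, d, 0.5) for d in depths]
        else:  # masked
            gts, afs = _PATTERNS["wt_era"]
            depths = [int(rng.integers(lo, hi + 1)) for _ in LINES]
            alt_depths = [_clamped_alt_depth(rng, d, af) for d, af in zip(depths, afs)]
            mask_regions.append((pos - 10, pos + 10))
        lines = {
            name: LineCall(depth=d, genotype=g, alt_af=(ad / d if d else 0.0))
            for name, d, g, ad in zip(LINES, depths, gts, alt_depths)
        }
        sites.append(VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, lines=lines))
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "label": label,
                "noise_kind": noise_kind or "",
            }
        )
    masks: dict[str, IntervalTree] = {}
    if mask_regions:
        tree = IntervalTree()
        for s, e in mask_regions:
            tree.addi(s, e)
        tree.merge_overlaps()
        masks[chrom] = tree
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "label", "noise_kind"])
    sites.sort(key=lambda s: (s.chrom, s.pos))
    truth = truth.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return sites, masks, truth


def write_lineage_vcf(sites: Sequence[VariantSite], path: str) -> None:
    """Write sites as a minimal three-sample VCF (GT:DP:AD per sample)."""
    import pysam

    header = pysam.VariantHeader()
    max_pos = {}
    for s in sites:
        max_pos[s.chrom] = max(max_pos.get(s.chrom, 0), s.pos + 1)
    for chrom, length in sorted(max_pos.items()):
        header.contigs.add(chrom, length=length + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for name in LINES:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            rec = out.new_record(
                contig=site.chrom, start=site.pos, alleles=(site.ref, site.alt)
            )
            for name in LINES:
                call = site.lines[name]
                gt = tuple(
                    None if a == "." else int(a)
                    for a in call.genotype.replace("|", "/").split("/")
                )
                rec.samples[name]["GT"] = gt
                rec.samples[name]["DP"] = call.depth
                alt_depth = int(round(call.alt_af * call.depth))
                rec.samples[name]["AD"] = (call.depth - alt_depth, alt_depth)
            out.write(rec)
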