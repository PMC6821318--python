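"""Editable-locus model.

A :class:`TargetSpec` describes one locus assayed by amplicon sequencing:
the wild-type reference amplicon, the guide cut sites, and the donor-programmed
nucleotide substitutions (the targeted change plus any silent blocking changes
that prevent re-cutting after successful homology-directed repair).

Coordinates are 0-based and half-open throughout; a guide's ``cut_position``
is an inter-base coordinate in ``[0, len(reference)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

_DNA = set("ACGT")

SUBSTITUTION_ROLES = ("targeted", "blocking")


class TargetSpecError(ValueError):
    """Raised when a target specification violates its invariants."""


@dataclass(frozen=True)
class GuideSite:
    """Expected cleavage (or nick) site of one guide on the reference amplicon."""

    cut_position: int
    label: str = "guide"


@dataclass(frozen=True)
class Substitution:
    """One donor-programmed base change.

    ``role`` is ``"targeted"`` for the intended edit and ``"blocking"`` for
    silent changes that destroy the protospacer/PAM after repair.
    """

    position: int
    ref_base: str
    alt_base: str
    role: str = "targeted"

    def __post_init__(self) -> None:
        if self.role not in SUBSTITUTION_ROLES:
            raise TargetSpecError(
                f"substitution role must be one of {SUBSTITUTION_ROLES}, got {self.role!r}"
            )
        for base, what in ((self.ref_base, "ref_base"), (self.alt_base, "alt_base")):
            if base not in _DNA:
                raise TargetSpecError(f"substitution {what} must be a single ACGT base, got {base!r}")
        if self.ref_base == self.alt_base:
            raise TargetSpecError(f"substitution at {self.position} does not change the base")


@dataclass(frozen=True)
class TargetSpec:
    """One editable locus: reference amplicon, guides and programmed substitutions."""

    name: str
    reference: str
    guides: tuple[GuideSite, ...]
    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference", str(self.reference).upper())
        object.__setattr__(self, "guides", tuple(self.guides))
        object.__setattr__(self, "substitutions", tuple(self.substitutions))
        if not self.reference:
            raise TargetSpecError(f"target {self.name!r}: empty reference")
        bad = set(self.reference) - _DNA
        if bad:
            raise TargetSpecError(
                f"target {self.name!r}: reference contains non-ACGT characters {sorted(bad)}"
            )
        if not self.guides:
            raise TargetSpecError(f"target {self.name!r}: at least one guide is required")
        n = len(self.reference)
        for g in self.guides:
            if not 0 <= g.cut_position <= n:
                raise TargetSpecError(
                    f"target {self.name!r}: guide {g.label!r} cut position {g.cut_position} "
                    f"outside [0, {n}]"
                )
        last = -1
        for sub in self.substitutions:
            if not 0 <= sub.position < n:
                raise TargetSpecError(
                    f"target {self.name!r}: substitution position {sub.position} outside reference"
                )
            if sub.position <= last:
                raise TargetSpecError(
                    f"target {self.name!r}: substitution positions must be strictly increasing"
                )
            last = sub.position
            if self.reference[sub.position] != sub.ref_base:
                raise TargetSpecError(
                    f"target {self.name!r}: substitution at position {sub.position} expects "
                    f"ref base {sub.ref_base!r} but reference has "
                    f"{self.reference[sub.position]!r}"
                )


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and alignment scoring for per-read outcome classification.

    Parameters
    ----------
    window_bp:
        Half-width of the quantification window around each guide cut site.
        Indels and programmed-substitution checks are restricted to the union
        of these windows.
    min_read_similarity:
        Minimum global-alignment identity to the wild-type amplicon for a read
        to be classified at all (inclusive; lower reads are discarded).
    hdr_homology:
        Minimum identity to the expected-HDR amplicon for an indel-free read
        carrying all programmed substitutions to be called HDR.
    mmej_min_mh:
        Minimum junction microhomology length (bp) for a windowed deletion to
        be called MMEJ rather than NHEJ.
    match, mismatch, gap_open, gap_extend:
        Global affine-gap alignment scores; ``gap_open`` is charged for the
        first base of a gap and ``gap_extend`` for each additional base.
    """

    window_bp: int = 20
    min_read_similarity: float = 0.70
    hdr_homology: float = 0.95
    mmej_min_mh: int = 2
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        for name in ("min_read_similarity", "hdr_homology"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise TargetSpecError(f"{name} must be in (0, 1], got {v}")
        if self.window_bp < 0:
            raise TargetSpecError(f"window_bp must be >= 0, got {self.window_bp}")
        if self.mmej_min_mh < 1:
            raise TargetSpecError(f"mmej_min_mh must be >= 1, got {self.mmej_min_mh}")


def build_expected_hdr(spec: TargetSpec) -> str:
    """Return the reference with every programmed substitution applied.

    Both targeted and blocking substitutions are applied; the result has the
    same length as the reference.
    """
    seq = list(spec.reference)
    for sub in spec.substitutions:
        if seq[sub.position] != sub.ref_base:  # defensive; TargetSpec validates
            raise TargetSpecError(
                f"substitution ref_base mismatch at position {sub.position}"
            )
        seq[sub.position] = sub.alt_base
    return "".join(seq)


def quantification_window(spec: TargetSpec, window_bp: int) -> list[tuple[int, int]]:
    """Union of half-open intervals ``[cut - window_bp, cut + window_bp)`` over guides.

    Intervals are clipped to ``[0, len(reference))``, merged when overlapping
    or adjacent, and returned sorted by start.
    """
    n = len(spec.reference)
    raw = sorted(
        (max(0, g.cut_position - window_bp), min(n, g.cut_position + window_bp))
        for g in spec.guides
    )
    merged: list[tuple[int, int]] = []
    for start, end in raw:
        if start >= end:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def load_target_spec(path: str | Path) -> TargetSpec:
    """Read a :class:`TargetSpec` from a YAML config file.

    Expected layout::

        name: KATNA1
        reference: ACGT...          # or: fasta: ref.fa  /  record: KATNA1
        guides:
          - {cut: 103, label: g1}
        substitutions:
          - {pos: 98, ref: C, alt: T, role: targeted}
          - {pos: 92, ref: G, alt: A, role: blocking}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TargetSpecError(f"{path}: target spec file must contain a mapping")
    if "reference" in doc:
        reference = doc["reference"]
    elif "fasta" in doc:
        from Bio import SeqIO

        fasta = Path(doc["fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
        record_id = doc.get("record")
        if record_id is None:
            if len(records) != 1:
                raise TargetSpecError(
                    f"{path}: FASTA has {len(records)} records; specify 'record'"
                )
            reference = next(iter(records.values()))
        else:
            try:
                reference = records[record_id]
            except KeyError:
                raise TargetSpecError(f"{path}: record {record_id!r} not in {fasta}") from None
    else:
        raise TargetSpecError(f"{path}: need 'reference' or 'fasta'")
    guides = tuple(
        GuideSite(cut_position=int(g["cut"]), label=str(g.get("label", f"guide{i + 1}")))
        for i, g in enumerate(doc.get("guides", []))
    )
    subs = tuple(
        sorted(
            (
                Substitution(
                    position=int(s["pos"]),
                    ref_base=str(s["ref"]).upper(),
                    alt_base=str(s["alt"]).upper(),
                    role=str(s.get("role", "targeted")),
                )
                for s in doc.get("substitutions", [])
            ),
            key=lambda s: s.position,
        )
    )
    return TargetSpec(
        name=str(doc.get("name", path.stem)),
        reference=reference,
        guides=guides,
        substitutions=subs,
    )


def with_config_overrides(config: ClassifierConfig, **overrides) -> ClassifierConfig:
    """Return a copy of *config* with the given fields replaced."""
    return replace(config, **overrides)
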