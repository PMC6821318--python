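"""Per-read editing-outcome classification: WT, HDR, mix, NHEJ or MMEJ.

Reads that survive a similarity filter against the wild-type amplicon are
classified from their windowed alignment evidence:

* no indels in the quantification window — HDR if all programmed
  substitutions are present and identity to the expected-HDR amplicon is high
  enough, otherwise WT (unexpected substitutions are ignored as putative
  sequencing errors);
* windowed indels together with all programmed substitutions — MIX
  (HDR that also acquired indels);
* windowed indels without the full substitution set — MMEJ if any windowed
  deletion is flanked by sufficient junction microhomology (>= 2 bp by
  default), otherwise NHEJ.

Microhomology is the longest identical sequence shared between one end of the
deleted segment and the retained sequence at the other end of the deletion;
it is measured on wild-type reference coordinates after left-normalizing the
deletion, and a deletion's score is the larger of its two one-sided extensions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .alignment import (
    AlignmentResult,
    IndelEvent,
    align_read,
    normalize_deletions,
    read_base_at,
    similarity_filter,
)
from .target_model import ClassifierConfig, TargetSpec, build_expected_hdr, quantification_window

CATEGORIES = ("WT", "HDR", "MIX", "NHEJ", "MMEJ", "DISCARDED")


@dataclass(frozen=True)
class ReadCall:
    """Outcome call for one read, with its supporting windowed evidence."""

    read_id: str
    category: str
    windowed_indels: tuple[IndelEvent, ...] = ()
    substitution_status: str = "none"  # all | some | none
    deletion_microhomologies: tuple[int, ...] = ()  # one per windowed deletion

    @property
    def max_microhomology(self) -> int:
        return max(self.deletion_microhomologies, default=0)


def microhomology_length(reference: str, del_start: int, del_end: int) -> int:
    """Junction microhomology of the deletion ``[del_start, del_end)``.

    Returns ``max(m_right, m_left)`` where ``m_right`` is the largest ``m``
    with ``reference[del_start:del_start+m] == reference[del_end:del_end+m]``
    and ``m_left`` the largest ``m`` with
    ``reference[del_start-m:del_start] == reference[del_end-m:del_end]``,
    each bounded by the deletion length and the distance to the nearer
    sequence end.
    """
    n = len(reference)
    if not (0 <= del_start < del_end <= n):
        raise ValueError(
            f"deletion [{del_start}, {del_end}) out of range for reference of length {n}"
        )
    del_len = del_end - del_start
    m_right = 0
    limit = min(del_len, n - del_end)
    while m_right < limit and reference[del_start + m_right] == reference[del_end + m_right]:
        m_right += 1
    m_left = 0
    limit = min(del_len, del_start)
    while m_left < limit and reference[del_start - 1 - m_left] == reference[del_end - 1 - m_left]:
        m_left += 1
    return max(m_right, m_left)


def _overlaps_window(ev: IndelEvent, windows: Sequence[tuple[int, int]]) -> bool:
    for a, b in windows:
        if ev.kind == "insertion":
            # inter-base coordinate: count the insertion if it sits inside the
            # window or exactly on either edge
            if a <= ev.ref_start <= b:
                return True
        elif ev.ref_start < b and ev.ref_end > a:
            return True
    return False


def _substitution_status(aln: AlignmentResult, spec: TargetSpec, windows: Sequence[tuple[int, int]]) -> str:
    """all / some / none over the programmed substitutions inside the windows."""
    checked = [s for s in spec.substitutions if any(a <= s.position < b for a, b in windows)]
    if not checked:
        return "none"
    present = sum(1 for s in checked if read_base_at(aln, s.position) == s.alt_base)
    if present == len(checked):
        return "all"
    return "some" if present else "none"


def classify_read(
    read: str,
    spec: TargetSpec,
    config: ClassifierConfig | None = None,
    read_id: str = "read",
) -> ReadCall:
    """Classify one read against a target specification.

    The read is aligned globally to the wild-type amplicon; reads below the
    similarity floor are DISCARDED.  Otherwise the read is also aligned to the
    expected-HDR amplicon and the better-scoring alignment serves as the call
    template (wild-type wins ties).  Indels and programmed-substitution checks
    are restricted to the quantification window; substitutions other than the
    programmed ones never change the category.
    """
    if config is None:
        config = ClassifierConfig()
    wt_aln = normalize_deletions(align_read(read, spec.reference, config))
    if not similarity_filter(wt_aln, config):
        return ReadCall(read_id=read_id, category="DISCARDED")

    hdr_reference = build_expected_hdr(spec)
    if hdr_reference != spec.reference:
        hdr_aln = normalize_deletions(align_read(read, hdr_reference, config))
    else:
        hdr_aln = wt_aln
    template_aln = hdr_aln if hdr_aln.score > wt_aln.score else wt_aln

    windows = quantification_window(spec, config.window_bp)
    windowed = tuple(ev for ev in template_aln.indels if _overlaps_window(ev, windows))
    status = _substitution_status(template_aln, spec, windows)

    # microhomology on wild-type reference coordinates (substitutions preserve
    # length, so template coordinates transfer directly)
    deletions = [ev for ev in windowed if ev.kind == "deletion"]
    mhs = tuple(
        microhomology_length(spec.reference, d.ref_start, d.ref_end) for d in deletions
    )
    max_mh = max(mhs, default=0)

    has_subs = bool(spec.substitutions)
    if not windowed:
        if has_subs and status == "all" and hdr_aln.identity >= config.hdr_homology:
            category = "HDR"
        else:
            category = "WT"
    elif has_subs and status == "all":
        category = "MIX"
    elif deletions and max_mh >= config.mmej_min_mh:
        category = "MMEJ"
    else:
        category = "NHEJ"
    return ReadCall(
        read_id=read_id,
        category=category,
        windowed_indels=windowed,
        substitution_status=status,
        deletion_microhomologies=mhs,
    )


def classify_reads(
    reads: Iterable[tuple[str, str]],
    spec: TargetSpec,
    config: ClassifierConfig | None = None,
) -> list[ReadCall]:
    """Classify ``(read_id, sequence)`` pairs; order is preserved."""
    if config is None:
        config = ClassifierConfig()
    return [classify_read(seq, spec, config, read_id=rid) for rid, seq in reads]


def microhomology_spectrum(
    calls: Iterable[ReadCall], mmej_min_mh: int = 2, max_class: int = 16
) -> tuple[dict[int, int], float]:
    """Histogram of windowed-deletion microhomology lengths across calls.

    Length classes run 0, 1, ..., ``max_class`` with longer homologies pooled
    into the top class.  Returns the histogram and the fraction of deletions
    at or above ``mmej_min_mh`` (0.0 when there are no deletions).
    """
    hist: Counter[int] = Counter()
    total = 0
    at_least = 0
    for call in calls:
        for mh in call.deletion_microhomologies:
            hist[min(mh, max_class)] += 1
            total += 1
            if mh >= mmej_min_mh:
                at_least += 1
    fraction = at_least / total if total else 0.0
    return dict(hist), fraction
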