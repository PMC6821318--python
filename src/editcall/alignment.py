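"""Global pairwise alignment of amplicon reads and indel-event extraction.

Each read is aligned end-to-end against an amplicon reference (wild-type or
expected-HDR) with affine gap scores.  The alignment is reduced to a list of
:class:`IndelEvent` in reference coordinates; deletions and insertions are
left-normalized so that equivalent placements inside repeated sequence always
report the same coordinates.  Identity is computed over all alignment columns,
with gap columns counting as non-matches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

from Bio import Align

from .target_model import ClassifierConfig


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class IndelEvent:
    """One insertion or deletion in reference coordinates (0-based, half-open).

    Insertions have ``ref_start == ref_end`` (the inter-base position where the
    extra sequence sits) and carry the inserted bases; deletions span the
    removed reference interval and have an empty ``inserted_seq``.
    """

    kind: str  # "insertion" | "deletion"
    ref_start: int
    ref_end: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise AlignmentError(f"unknown indel kind {self.kind!r}")
        if self.ref_start > self.ref_end:
            raise AlignmentError("ref_start must be <= ref_end")
        if self.kind == "insertion":
            if self.ref_start != self.ref_end or not self.inserted_seq:
                raise AlignmentError("insertions need ref_start == ref_end and bases")
        elif self.inserted_seq:
            raise AlignmentError("deletions carry no inserted sequence")

    @property
    def length(self) -> int:
        return len(self.inserted_seq) if self.kind == "insertion" else self.ref_end - self.ref_start


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one global read-vs-reference alignment."""

    reference: str
    read: str
    score: float
    identity: float
    indels: tuple[IndelEvent, ...]

    def aligned_strings(self) -> tuple[str, str]:
        """Project the alignment back to gapped (reference, read) strings."""
        return _project(self.reference, self.read, self.indels)


@lru_cache(maxsize=8)
def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_read(read: str, reference: str, config: ClassifierConfig | None = None) -> AlignmentResult:
    """Globally align *read* against *reference* and summarize the result.

    Returns a deterministic optimal alignment under the configured affine-gap
    scores; among co-optimal alignments the dynamic-programming traceback
    order of the aligner picks one, after which indels are left-normalized so
    the reported events are placement-canonical.  ``N`` in the read is
    tolerated and scores as a mismatch.
    """
    if config is None:
        config = ClassifierConfig()
    read = str(read).upper()
    reference = str(reference).upper()
    if not read or not reference:
        raise AlignmentError("cannot align empty sequences")
    aligner = _make_aligner(config.match, config.mismatch, config.gap_open, config.gap_extend)
    aln = aligner.align(reference, read)[0]
    ref_aln, read_aln = str(aln[0]), str(aln[1])
    indels = _extract_indels(ref_aln, read_aln)
    matches = sum(1 for a, b in zip(ref_aln, read_aln) if a == b and a != "-")
    identity = matches / len(ref_aln)
    result = AlignmentResult(
        reference=reference,
        read=read,
        score=float(aln.score),
        identity=identity,
        indels=tuple(indels),
    )
    return result


def _extract_indels(ref_aln: str, read_aln: str) -> list[IndelEvent]:
    events: list[IndelEvent] = []
    ref_pos = 0
    i = 0
    n = len(ref_aln)
    while i < n:
        if ref_aln[i] == "-":  # insertion relative to reference
            j = i
            while j < n and ref_aln[j] == "-":
                j += 1
            events.append(
                IndelEvent("insertion", ref_pos, ref_pos, inserted_seq=read_aln[i:j])
            )
            i = j
        elif read_aln[i] == "-":  # deletion from the read
            j = i
            while j < n and read_aln[j] == "-" and ref_aln[j] != "-":
                j += 1
            length = j - i
            events.append(IndelEvent("deletion", ref_pos, ref_pos + length))
            ref_pos += length
            i = j
        else:
            ref_pos += 1
            i += 1
    return events


def normalize_deletions(result: AlignmentResult, reference: str | None = None) -> AlignmentResult:
    """Shift every indel to its leftmost equivalent placement on the reference.

    A deletion ``[s, e)`` may slide one base left whenever
    ``reference[s-1] == reference[e-1]`` (the deleted substring changes but the
    remaining sequence does not); an insertion slides left by rotating its last
    base to the front whenever that base equals the preceding reference base.
    Events never slide past the previous event.  Idempotent, and the read
    sequence implied by the alignment is unchanged.
    """
    if reference is None:
        reference = result.reference
    normalized: list[IndelEvent] = []
    floor = 0  # leftmost reference coordinate an event may reach
    for ev in sorted(result.indels, key=lambda e: (e.ref_start, e.kind)):
        if ev.kind == "deletion":
            s, e = ev.ref_start, ev.ref_end
            while s > floor and reference[s - 1] == reference[e - 1]:
                s -= 1
                e -= 1
            normalized.append(IndelEvent("deletion", s, e))
            floor = e
        else:
            p = ev.ref_start
            seq = ev.inserted_seq
            while p > floor and reference[p - 1] == seq[-1]:
                seq = seq[-1] + seq[:-1]
                p -= 1
            normalized.append(IndelEvent("insertion", p, p, inserted_seq=seq))
            floor = max(floor, p)
    return replace(result, indels=tuple(normalized))


def similarity_filter(result: AlignmentResult, config: ClassifierConfig) -> bool:
    """``True`` (keep) iff identity to the wild-type amplicon meets the floor.

    The threshold is inclusive: identity exactly at ``min_read_similarity``
    keeps the read.
    """
    return result.identity >= config.min_read_similarity


def _project(reference: str, read: str, indels: tuple[IndelEvent, ...]) -> tuple[str, str]:
    ref_parts: list[str] = []
    read_parts: list[str] = []
    r = q = 0
    for ev in sorted(indels, key=lambda e: e.ref_start):
        take = ev.ref_start - r
        ref_parts.append(reference[r : r + take])
        read_parts.append(read[q : q + take])
        r += take
        q += take
        if ev.kind == "insertion":
            ref_parts.append("-" * len(ev.inserted_seq))
            read_parts.append(read[q : q + len(ev.inserted_seq)])
            q += len(ev.inserted_seq)
        else:
            ref_parts.append(reference[ev.ref_start : ev.ref_end])
            read_parts.append("-" * ev.length)
            r = ev.ref_end
    ref_parts.append(reference[r:])
    read_parts.append(read[q:])
    return "".join(ref_parts), "".join(read_parts)


def read_base_at(result: AlignmentResult, ref_position: int) -> str | None:
    """Read base aligned opposite ``ref_position``, or ``None`` if deleted."""
    offset = 0  # read minus reference coordinate shift accumulated so far
    for ev in sorted(result.indels, key=lambda e: e.ref_start):
        if ev.ref_start > ref_position:
            break
        if ev.kind == "deletion":
            if ev.ref_start <= ref_position < ev.ref_end:
                return None
            offset -= ev.length
        else:
            offset += ev.length
    q = ref_position + offset
    if not 0 <= q < len(result.read):
        return None
    return result.read[q]
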