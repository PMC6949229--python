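"""Tandem-repeat context, repeat-based exclusion and breakpoint microhomology.

Indels called in tandem repeats are error-prone, so the pipeline excludes
indels changing the copy number of a mononucleotide run of >7 units, a
dinucleotide run of >4 units, or a tri-or-longer-nucleotide run of >2 units.
Deletions of >=3 nt in non-repeat context are scanned for 2-4 nt identity
between the deleted sequence and the flank at the breakpoint junction, the
hallmark of microhomology-mediated end joining.

All functions assume VCF-style records (1-based position, shared anchor base,
left-aligned) against an in-memory reference sequence string.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RepeatAnnotation",
    "MicrohomologyAnnotation",
    "RepeatExclusionParams",
    "left_align",
    "indel_change",
    "annotate_repeat",
    "apply_repeat_exclusion",
    "detect_microhomology",
    "mono_run_class",
    "table2_breakdown",
]

MONO_RUN_CLASSES = ("non-repeat", "2", "3", "4-7")


@dataclass(frozen=True)
class RepeatAnnotation:
    unit: str
    unit_length: int
    unit_count: int  # tandem copies of `unit` in the reference at the locus
    is_repeat_indel: bool


@dataclass(frozen=True)
class MicrohomologyAnnotation:
    has_mh: bool
    mh_length: int
    side: str  # "none" | "upstream" | "downstream" | "both"


@dataclass(frozen=True)
class RepeatExclusionParams:
    """Maximum reference copy number tolerated before an indel is excluded."""

    max_mono_units: int = 7
    max_di_units: int = 4
    max_tri_plus_units: int = 2

    def __post_init__(self) -> None:
        if min(self.max_mono_units, self.max_di_units, self.max_tri_plus_units) < 1:
            raise ValueError("unit limits must be >= 1")


def indel_change(ref: str, alt: str) -> tuple[str, str]:
    """Classify a normalized allele pair; returns (kind, inserted/deleted seq).

    kind is "SNV", "insertion" or "deletion".  Alleles must share the single
    VCF anchor base for indels.
    """
    if not ref or not alt or set(ref + alt) - set("ACGT"):
        raise ValueError(f"bad alleles {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref == alt")
    if len(ref) == len(alt) == 1:
        return "SNV", alt
    if len(ref) > len(alt):
        if len(alt) != 1 or ref[0] != alt:
            raise ValueError(f"indel not normalized: {ref!r}>{alt!r}")
        return "deletion", ref[1:]
    if len(ref) != 1 or alt[0] != ref:
        raise ValueError(f"indel not normalized: {ref!r}>{alt!r}")
    return "insertion", alt[1:]


def left_align(pos: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Shift an indel to its leftmost equivalent VCF representation.

    `pos` is 1-based; `refseq` is the full chromosome sequence.  SNVs are
    returned unchanged.  The returned record keeps the single-anchor-base
    convention.
    """
    if len(ref) == len(alt) == 1:
        return pos, ref, alt
    if refseq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ValueError(f"ref allele mismatch at {pos}")
    # reduce to anchor form first (strip any shared suffix/extra prefix)
    r, a = ref, alt
    while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    kind, seq = indel_change(r, a)
    s = pos  # 0-based start of the deleted segment / insertion point
    seq_l = list(seq)
    # shift left while the base before the site equals the last affected base
    while s >= 2 and refseq[s - 1] == seq_l[-1]:
        seq_l.insert(0, seq_l.pop())
        s -= 1
    seq2 = "".join(seq_l)
    if kind == "deletion" and refseq[s : s + len(seq2)] != seq2:
        raise ValueError("left alignment inconsistent with reference")
    anchor = refseq[s - 1]
    pos2 = s  # 1-based anchor position
    if kind == "deletion":
        return pos2, anchor + seq2, anchor
    return pos2, anchor, anchor + seq2


def _count_tandem(refseq: str, start: int, unit: str) -> int:
    """Copies of `unit` tiling the reference around 0-based offset `start`."""
    u = len(unit)
    n = 0
    i = start
    while refseq[i : i + u] == unit:
        n += 1
        i += u
    i = start - u
    while i >= 0 and refseq[i : i + u] == unit:
        n += 1
        i -= u
    return n


def annotate_repeat(
    pos: int, ref: str, alt: str, refseq: str, max_unit: int = 6, min_flank: int = 50
) -> RepeatAnnotation:
    """Smallest repeat unit whose tandem copy number the indel changes.

    Searches unit lengths 1..max_unit (plus the trivial full-length copy for
    longer indels); `unit_count` is the number of tandem copies of the unit
    present in the reference across the locus.  The indel is a repeat indel
    iff the reference already carries >=2 copies.
    """
    kind, seq = indel_change(ref, alt)
    if kind == "SNV":
        raise ValueError("annotate_repeat expects an indel")
    s = pos  # 0-based: first deleted base / first base after insertion point
    length = len(seq)
    end = s + (length if kind == "deletion" else 0)
    if s < min_flank or end + min_flank > len(refseq):
        raise ValueError("flank sequence too short")
    if kind == "deletion" and refseq[s : s + length] != seq:
        raise ValueError("deleted sequence does not match reference")
    units = [u for u in range(1, min(max_unit, length) + 1) if length % u == 0]
    if length > max_unit:
        units.append(length)  # whole-copy gain/loss of a long unit
    for u in units:
        unit = seq[:u]
        if seq != unit * (length // u):
            continue
        count = _count_tandem(refseq, s, unit)
        if count >= 2:
            return RepeatAnnotation(unit, u, count, True)
    # non-repetitive context: report the indel itself as the unit
    return RepeatAnnotation(seq, length, _count_tandem(refseq, s, seq), False)


def apply_repeat_exclusion(
    ann: RepeatAnnotation, params: RepeatExclusionParams = RepeatExclusionParams()
) -> bool:
    """True if the indel is kept, False if excluded by its repeat context."""
    if ann.unit_length == 1:
        return ann.unit_count <= params.max_mono_units
    if ann.unit_length == 2:
        return ann.unit_count <= params.max_di_units
    return ann.unit_count <= params.max_tri_plus_units


def detect_microhomology(
    pos: int,
    ref: str,
    alt: str,
    refseq: str,
    max_mh: int = 4,
    min_mh: int = 2,
    min_flank: int = 50,
) -> MicrohomologyAnnotation:
    """Breakpoint-junction microhomology of a deletion.

    A deletion qualifies iff it removes >=3 nt and >=2 of the deleted bases
    are identical to the adjacent flank: the start of the deleted sequence
    matching the start of the downstream flank, or its end matching the end
    of the upstream flank.  The match length is capped at
    ``min(max_mh, deletion length - 1)`` — a full-length match would be a
    repeat indel instead.  Both junction ends are tested; for left-aligned
    records only the downstream end can actually match, but the symmetric
    test keeps the classification representation-independent.
    """
    kind, seq = indel_change(ref, alt)
    if kind != "deletion":
        raise ValueError("microhomology is defined for deletions only")
    s = pos  # 0-based start of deleted segment
    length = len(seq)
    if s < min_flank or s + length + min_flank > len(refseq):
        raise ValueError("flank sequence too short")
    if refseq[s : s + length] != seq:
        raise ValueError("deleted sequence does not match reference")
    cap = min(max_mh, length - 1)
    down = refseq[s + length : s + length + cap]
    up = refseq[s - cap : s]
    mh_down = mh_up = 0
    for k in range(cap, min_mh - 1, -1):
        if mh_down == 0 and seq[:k] == down[:k]:
            mh_down = k
        if mh_up == 0 and len(up) >= k and seq[-k:] == up[-k:]:
            mh_up = k
    has = length >= 3 and max(mh_down, mh_up) >= min_mh
    if not has:
        return MicrohomologyAnnotation(False, 0, "none")
    side = (
        "both"
        if (mh_down and mh_up)
        else ("downstream" if mh_down else "upstream")
    )
    return MicrohomologyAnnotation(True, max(mh_down, mh_up), side)


def mono_run_class(unit_count: int) -> str:
    """Table-2 mononucleotide-run class for a retained single-nt indel."""
    if unit_count <= 1:  # 0 possible for insertions with no reference copy
        return "non-repeat"
    if unit_count == 2:
        return "2"
    if unit_count == 3:
        return "3"
    if 4 <= unit_count <= 7:
        return "4-7"
    raise ValueError(f"run of {unit_count} units should have been excluded")


def table2_breakdown(calls) -> "pandas.DataFrame":
    """Single-nt indel counts by mononucleotide-run class x (deletion, insertion).

    `calls` is an iterable of accepted DnmCall objects carrying `repeat`
    annotations; runs of more than 7 units must already have been excluded.
    """
    import pandas as pd

    out = pd.DataFrame(
        0, index=list(MONO_RUN_CLASSES), columns=["deletion", "insertion"]
    )
    for c in calls:
        if c.mclass == "SNV":
            continue
        _, seq = indel_change(c.ref, c.alt)
        if len(seq) != 1:
            continue
        if c.repeat is None:
            raise ValueError("repeat annotation missing")
        out.loc[mono_run_class(c.repeat.unit_count), c.mclass] += 1
    return out
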