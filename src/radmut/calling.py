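"""Trio de novo mutation filtering and parent-of-origin assignment.

A variant is a de novo mutation (DNM) candidate in an offspring when both
parents show a variant allele frequency (VAF) below 0.1, the offspring shows
a VAF of at least 0.25, all three samples meet a depth floor, and the site
lies inside the effective whole-genome coverage mask.  Parental origin is
assigned from strain-informative polymorphisms (one parent homozygous alt,
the other homozygous ref) that share a read-backed haplotype tag with the
DNM within a configurable distance.

The variant table is a pandas DataFrame with columns ``chrom, pos, ref, alt``
(pos 1-based) plus per-sample ``{s}_dp`` (high-MQ depth), ``{s}_ad``
(alt-supporting reads) and ``{s}_ht`` (haplotype tag of the alt allele in
that sample, empty when unphased).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ewc import EwcMask
from .indels import MicrohomologyAnnotation, RepeatAnnotation

__all__ = [
    "FilterParams",
    "DnmCall",
    "classify_allele",
    "call_dnm_candidates",
    "informative_sites",
    "assign_parental_origin",
    "summarize_counts",
]


@dataclass(frozen=True)
class FilterParams:
    max_parent_vaf: float = 0.1   # parents must be strictly below this
    min_child_vaf: float = 0.25   # offspring must be at or above this
    min_parent_depth: int = 10
    min_child_depth: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.max_parent_vaf < self.min_child_vaf <= 1):
            raise ValueError("require 0 <= max_parent_vaf < min_child_vaf <= 1")
        if min(self.min_parent_depth, self.min_child_depth) < 0:
            raise ValueError("depth floors must be >= 0")


@dataclass
class DnmCall:
    """An accepted de novo alteration in one offspring."""

    chrom: str
    pos: int  # 1-based, left-aligned
    ref: str
    alt: str
    child: str
    mclass: str  # "SNV" | "insertion" | "deletion"
    child_dp: int
    child_ad: int
    haplotype_tag: str = ""
    parental_origin: str = "undetermined"  # "paternal" | "maternal" | "undetermined"
    origin_conflict: bool = False
    in_ewc: bool = True
    exclusion_flags: set[str] = field(default_factory=set)
    repeat: RepeatAnnotation | None = None
    microhomology: MicrohomologyAnnotation | None = None

    @property
    def vaf(self) -> float:
        return self.child_ad / self.child_dp if self.child_dp else 0.0

    @property
    def key(self) -> tuple:
        return (self.child, self.chrom, self.pos, self.ref, self.alt)


def classify_allele(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "deletion" if len(ref) > len(alt) else "insertion"


def _vaf(ad: np.ndarray, dp: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(dp > 0, ad / np.maximum(dp, 1), 0.0)
    return v


def call_dnm_candidates(
    variants: pd.DataFrame,
    father: str,
    mother: str,
    child: str,
    params: FilterParams = FilterParams(),
    mask: EwcMask | None = None,
    return_rejections: bool = False,
):
    """Apply the trio VAF/depth/region filters for one offspring.

    Returns the accepted calls as a list of :class:`DnmCall`; with
    ``return_rejections=True`` additionally returns a DataFrame recording
    the first failing filter for every non-accepted row.
    """
    for s in (father, mother, child):
        for suf in ("_dp", "_ad"):
            if s + suf not in variants.columns:
                raise KeyError(f"missing sample column {s + suf}")
    fd = variants[father + "_dp"].to_numpy()
    fa = variants[father + "_ad"].to_numpy()
    md = variants[mother + "_dp"].to_numpy()
    ma = variants[mother + "_ad"].to_numpy()
    cd = variants[child + "_dp"].to_numpy()
    ca = variants[child + "_ad"].to_numpy()

    reasons = np.full(len(variants), "", dtype=object)

    def _flag(bad: np.ndarray, reason: str) -> None:
        reasons[(reasons == "") & bad] = reason

    _flag((fd < params.min_parent_depth) | (md < params.min_parent_depth), "parent_depth")
    _flag(cd < params.min_child_depth, "child_depth")
    _flag(
        (_vaf(fa, fd) >= params.max_parent_vaf) | (_vaf(ma, md) >= params.max_parent_vaf),
        "parent_vaf",
    )
    _flag((cd == 0) | (_vaf(ca, cd) < params.min_child_vaf), "child_vaf")
    if mask is not None:
        in_mask = np.fromiter(
            (
                mask.contains_vcf_pos(c, p)
                for c, p in zip(variants["chrom"], variants["pos"])
            ),
            dtype=bool,
            count=len(variants),
        )
        _flag(~in_mask, "outside_ewc")

    accept = reasons == ""
    ht_col = child + "_ht"
    calls = []
    for i in np.flatnonzero(accept):
        row = variants.iloc[i]
        calls.append(
            DnmCall(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                child=child,
                mclass=classify_allele(row["ref"], row["alt"]),
                child_dp=int(cd[i]),
                child_ad=int(ca[i]),
                haplotype_tag=str(row.get(ht_col, "") or ""),
            )
        )
    if not return_rejections:
        return calls
    rej = variants.loc[~accept, ["chrom", "pos", "ref", "alt"]].copy()
    rej["reason"] = reasons[~accept]
    return calls, rej


def informative_sites(
    variants: pd.DataFrame,
    father: str,
    mother: str,
    hom_alt_vaf: float = 0.9,
    hom_ref_vaf: float = 0.1,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Sites where one parent is homozygous alt and the other homozygous ref.

    These are fixed strain differences between the parental strains; the alt
    allele marks the haplotype inherited from the homozygous-alt parent.
    Adds a column ``alt_parent`` ("paternal"/"maternal").
    """
    fd = variants[father + "_dp"].to_numpy()
    fv = _vaf(variants[father + "_ad"].to_numpy(), fd)
    md = variants[mother + "_dp"].to_numpy()
    mv = _vaf(variants[mother + "_ad"].to_numpy(), md)
    deep = (fd >= min_depth) & (md >= min_depth)
    pat = deep & (fv >= hom_alt_vaf) & (mv <= hom_ref_vaf)
    mat = deep & (mv >= hom_alt_vaf) & (fv <= hom_ref_vaf)
    out = variants.loc[pat | mat].copy()
    out["alt_parent"] = np.where(pat[pat | mat], "paternal", "maternal")
    return out


def assign_parental_origin(
    dnm: DnmCall,
    informative: pd.DataFrame,
    child: str | None = None,
    max_distance: int = 500,
) -> tuple[str, bool]:
    """Parent of origin from linked informative sites.

    A site is evidence when it lies within ``max_distance`` of the DNM and
    the offspring's alt allele there carries the same haplotype tag as the
    DNM.  All evidence must agree; conflicting evidence yields
    ``("undetermined", True)``, absent evidence ``("undetermined", False)``.
    """
    child = child or dnm.child
    if not dnm.haplotype_tag:
        return "undetermined", False
    near = informative[
        (informative["chrom"] == dnm.chrom)
        & ((informative["pos"] - dnm.pos).abs() <= max_distance)
    ]
    verdicts = set()
    ht_col, ad_col = child + "_ht", child + "_ad"
    for _, row in near.iterrows():
        if str(row.get(ht_col, "") or "") != dnm.haplotype_tag:
            continue
        if int(row.get(ad_col, 0)) <= 0:  # offspring must actually carry the allele
            continue
        verdicts.add(row["alt_parent"])
    if len(verdicts) == 1:
        return verdicts.pop(), False
    if len(verdicts) > 1:
        return "undetermined", True
    return "undetermined", False


def summarize_counts(dnms: list[DnmCall], clusters) -> dict[str, int]:
    """Per-group mutation tallies with multisite clusters counted once.

    Every alteration belonging to a cluster leaves the SNV/indel tallies and
    each cluster contributes exactly one multisite mutation; repeat-excluded
    indels are omitted entirely.  Conservation:
    ``SNV + indel + sum(cluster sizes) + excluded == len(dnms)``.
    """
    clusters = list(clusters)
    clustered: dict[tuple, int] = {}
    for ci, cl in enumerate(clusters):
        for m in cl.members:
            if m.key in clustered:
                raise ValueError(f"alteration {m.key} assigned to two clusters")
            if m.exclusion_flags:
                raise ValueError(f"excluded alteration {m.key} inside a cluster")
            clustered[m.key] = ci
    counts = {"SNV": 0, "indel": 0, "multisite": len(clusters), "excluded": 0}
    for d in dnms:
        if d.exclusion_flags:
            counts["excluded"] += 1
        elif d.key in clustered:
            pass
        elif d.mclass == "SNV":
            counts["SNV"] += 1
        else:
            counts["indel"] += 1
    return counts
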