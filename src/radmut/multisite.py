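"""Multisite mutation clustering and substitution-spectrum comparison.

A multisite mutation is more than one alteration (SNV or indel) occurring
within 100 bp on the same haplotype in one offspring; it is counted as a
single mutational event, separate from SNVs and indels.  Clusters are the
connected components of the pairwise "within the window and
haplotype-compatible" relation (single linkage), so a chain of alterations
each within 100 bp of the next forms one cluster even if its end-to-end
span exceeds the window.

Substitution spectra use the seven pyrimidine-strand categories
C>A, C>G, C>T at CpG, C>T at non-CpG, T>A, T>C, T>G; spectra are compared
with a global exact test on the 2x7 table followed by per-category Fisher
exact tests with a Bonferroni factor of 7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import DnmCall

__all__ = [
    "SPECTRUM_CATEGORIES",
    "MultisiteCluster",
    "SpectrumTable",
    "cluster_multisite",
    "classify_substitution",
    "spectrum_from_calls",
    "compare_spectra",
    "SpectrumComparison",
    "flag_known_dinucleotide_signatures",
]

SPECTRUM_CATEGORIES = (
    "C>A",
    "C>G",
    "C>T at CpG",
    "C>T at non-CpG",
    "T>A",
    "T>C",
    "T>G",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# error-prone-polymerase dinucleotide signatures, with their reverse-strand
# appearances on the reference (plus) strand
_DINUC_SIGNATURES = {
    ("GC", "AA"): "GC>AA",
    ("GC", "TT"): "GC>AA",  # reverse complement of GC>AA
    ("GA", "TT"): "GA>TT",
    ("TC", "AA"): "GA>TT",  # reverse complement of GA>TT
}


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class MultisiteCluster:
    members: list[DnmCall]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a multisite cluster has >= 2 members")
        if len({m.child for m in self.members}) != 1:
            raise ValueError("cluster members must come from one offspring")
        if len({m.chrom for m in self.members}) != 1:
            raise ValueError("cluster members must share a chromosome")
        self.members = sorted(self.members, key=lambda m: m.pos)

    @property
    def child(self) -> str:
        return self.members[0].child

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def span(self) -> int:
        return self.members[-1].pos - self.members[0].pos

    @property
    def haplotype_evidence(self) -> str:
        tags = {m.haplotype_tag for m in self.members if m.haplotype_tag}
        if len(tags) == 1:
            return f"tag:{tags.pop()}"
        origins = {m.parental_origin for m in self.members}
        return f"origin:{origins.pop()}" if len(origins) == 1 else "mixed"


def _haplotype_compatible(a: DnmCall, b: DnmCall) -> bool:
    """Shared haplotype tag; parental origin is the fallback when tags are absent."""
    if a.haplotype_tag and b.haplotype_tag:
        return a.haplotype_tag == b.haplotype_tag
    if a.parental_origin != "undetermined" and b.parental_origin != "undetermined":
        return a.parental_origin == b.parental_origin
    return False


def cluster_multisite(dnms: list[DnmCall], window: int = 100) -> list[MultisiteCluster]:
    """Single-linkage clusters of proximal, haplotype-sharing alterations."""
    order = sorted(range(len(dnms)), key=lambda i: (dnms[i].child, dnms[i].chrom, dnms[i].pos))
    parent = list(range(len(dnms)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for a in range(len(order)):
        i = order[a]
        for b in range(a + 1, len(order)):
            j = order[b]
            if (dnms[j].child, dnms[j].chrom) != (dnms[i].child, dnms[i].chrom):
                break
            if dnms[j].pos - dnms[i].pos > window:
                break
            if _haplotype_compatible(dnms[i], dnms[j]):
                union(i, j)
    groups: dict[int, list[DnmCall]] = {}
    for i, d in enumerate(dnms):
        groups.setdefault(find(i), []).append(d)
    return [MultisiteCluster(g) for g in groups.values() if len(g) >= 2]


def classify_substitution(ref: str, alt: str, context: str) -> str:
    """Spectrum category of a single-base substitution with 3-nt context.

    Purine-reference substitutions are collapsed onto the pyrimidine strand;
    C>T is split by whether the base 3' of the substituted C (on the
    pyrimidine strand) is G, i.e. whether the site is a CpG.
    """
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("not a single-base substitution")
    if len(context) != 3 or context[1] != ref:
        raise ValueError("context must be 3 nt centred on the reference base")
    if ref in "AG":
        ref, alt, context = _revcomp(ref), _revcomp(alt), _revcomp(context)
    if ref == "C" and alt == "T":
        return "C>T at CpG" if context[2] == "G" else "C>T at non-CpG"
    return f"{ref}>{alt}"


@dataclass
class SpectrumTable:
    """Counts of classified substitutions over the seven categories."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SPECTRUM_CATEGORIES}
    )

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SPECTRUM_CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {bad}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in SPECTRUM_CATEGORIES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative counts")

    def add(self, category: str, n: int = 1) -> None:
        self.counts[category] += n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in SPECTRUM_CATEGORIES], dtype=np.int64)


def spectrum_from_calls(calls, reference: dict[str, str]) -> SpectrumTable:
    """Spectrum of the SNVs in `calls` using the reference trinucleotide context.

    For multisite clusters pass the members: each SNV member contributes one
    substitution (the representation with the fewest alterations — indel
    members contribute none).
    """
    t = SpectrumTable()
    for c in calls:
        if c.mclass != "SNV":
            continue
        seq = reference[c.chrom]
        ctx = seq[c.pos - 2 : c.pos + 1]
        t.add(classify_substitution(c.ref, c.alt, ctx))
    return t


@dataclass
class SpectrumComparison:
    global_p: float
    per_category: pd.DataFrame  # index: category; columns a, b, odds_ratio, p, p_bonferroni
    reps: int
    seed: int | None


def _log_table_prob(table: np.ndarray, lgam_margins: float) -> np.ndarray:
    """Log hypergeometric probability of r x c tables with fixed margins."""
    from scipy.special import gammaln

    return lgam_margins - gammaln(table + 1).sum(axis=(-2, -1))


def compare_spectra(
    a: SpectrumTable,
    b: SpectrumTable,
    reps: int = 20000,
    seed: int | None = 0,
) -> SpectrumComparison:
    """Global exact test on the 2x7 table, then per-category Fisher tests.

    The global test is the conditional exact test with a Monte-Carlo null:
    tables are drawn with fixed margins and the p-value is the proportion
    with probability no larger than the observed table's.  Per-category
    two-tailed Fisher exact p-values are Bonferroni-corrected by the number
    of categories (7), capped at 1.
    """
    if a.total == 0 or b.total == 0:
        raise ValueError("both spectra must contain substitutions")
    obs = np.stack([a.as_array(), b.as_array()])
    keep = obs.sum(axis=0) > 0  # empty categories carry no information
    tab = obs[:, keep]
    from scipy.special import gammaln

    row, col = tab.sum(axis=1), tab.sum(axis=0)
    lgam = (
        gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(tab.sum() + 1)
    )
    lp_obs = _log_table_prob(tab, lgam)
    rng = np.random.default_rng(seed)
    sampled = stats.random_table(row, col).rvs(reps, random_state=rng)
    lp = _log_table_prob(np.asarray(sampled), lgam)
    global_p = float((np.sum(lp <= lp_obs + 1e-9) + 1) / (reps + 1))

    k = len(SPECTRUM_CATEGORIES)
    rows = []
    for i, cat in enumerate(SPECTRUM_CATEGORIES):
        a_i, b_i = int(obs[0, i]), int(obs[1, i])
        table = [[a_i, a.total - a_i], [b_i, b.total - b_i]]
        orr, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "a": a_i,
                "b": b_i,
                "odds_ratio": orr,
                "p": p,
                "p_bonferroni": min(1.0, k * p),
            }
        )
    per_cat = pd.DataFrame(rows, index=list(SPECTRUM_CATEGORIES))
    return SpectrumComparison(global_p, per_cat, reps, seed)


def flag_known_dinucleotide_signatures(cluster: MultisiteCluster) -> set[str]:
    """Known error-prone-polymerase dinucleotide substitutions in a cluster.

    Flags GC>AA and GA>TT (on either strand) among pairs of adjacent
    substituted positions.
    """
    snvs = sorted((m for m in cluster.members if m.mclass == "SNV"), key=lambda m: m.pos)
    flags: set[str] = set()
    for x, y in zip(snvs, snvs[1:]):
        if y.pos - x.pos != 1:
            continue
        key = (x.ref + y.ref, x.alt + y.alt)
        if key in _DINUC_SIGNATURES:
            flags.add(_DINUC_SIGNATURES[key])
    return flags
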