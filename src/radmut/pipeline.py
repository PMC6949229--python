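"""End-to-end analysis: mask, call, classify, cluster, count, estimate.

Runs the whole study analysis on an in-memory cohort: build the shared
effective-coverage mask from all samples' depth tracks, call DNM candidates
per offspring with the trio VAF filters, left-align and classify indels
(repeat exclusion, microhomology), assign parental origin from linked
informative markers, collapse multisite clusters, and turn the per-group
tallies into rates with exact Poisson confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import (
    DnmCall,
    FilterParams,
    assign_parental_origin,
    call_dnm_candidates,
    informative_sites,
    summarize_counts,
)
from .ewc import EwcMask, EwcParams, intersect_masks, sample_mask
from .indels import (
    RepeatExclusionParams,
    annotate_repeat,
    apply_repeat_exclusion,
    detect_microhomology,
    left_align,
    table2_breakdown,
)
from .multisite import MultisiteCluster, cluster_multisite
from .rates import RateEstimate, mutation_rate

__all__ = ["CohortResult", "compute_shared_mask", "annotate_calls", "analyze_cohort"]


@dataclass
class CohortResult:
    mask: EwcMask
    calls: dict[str, list[DnmCall]]           # per offspring, accepted candidates
    clusters: dict[str, list[MultisiteCluster]]
    counts: dict[str, dict[str, int]]         # per group: SNV/indel/multisite/excluded
    rates: dict[str, dict[str, RateEstimate]]
    table2: dict[str, pd.DataFrame]
    G: float = 0.0                            # diploid analysed genome size

    def all_calls(self) -> list[DnmCall]:
        return [c for calls in self.calls.values() for c in calls]


def compute_shared_mask(depth, params: EwcParams = EwcParams()) -> EwcMask:
    """Intersection of per-sample callable masks over every sample's tracks."""
    masks = []
    for sample, tracks in depth.items():
        hq = {c: t["hq"] for c, t in tracks.items()}
        total = {c: t["total"] for c, t in tracks.items()}
        masks.append(sample_mask(hq, total, params, sample=sample))
    return intersect_masks(masks)


def annotate_calls(
    calls: list[DnmCall],
    reference: dict[str, str],
    repeat_params: RepeatExclusionParams = RepeatExclusionParams(),
) -> list[DnmCall]:
    """Left-align indel calls and attach repeat/microhomology annotations.

    Repeat-excluded indels get an ``exclusion_flags`` entry; microhomology is
    only reported for deletions that survive the repeat filter (the two
    classes are disjoint, repeat context wins).
    """
    for c in calls:
        if c.mclass == "SNV":
            continue
        seq = reference[c.chrom]
        c.pos, c.ref, c.alt = left_align(c.pos, c.ref, c.alt, seq)
        c.repeat = annotate_repeat(c.pos, c.ref, c.alt, seq)
        if not apply_repeat_exclusion(c.repeat, repeat_params):
            c.exclusion_flags.add("repeat")
        elif c.mclass == "deletion" and not c.repeat.is_repeat_indel:
            c.microhomology = detect_microhomology(c.pos, c.ref, c.alt, seq)
    return calls


def analyze_cohort(
    cohort,
    filter_params: FilterParams = FilterParams(),
    ewc_params: EwcParams = EwcParams(),
    repeat_params: RepeatExclusionParams = RepeatExclusionParams(),
    window: int = 100,
    max_phase_distance: int = 500,
) -> CohortResult:
    """Run the full DNM analysis on a (synthetic or loaded) trio cohort."""
    mask = compute_shared_mask(cohort.depth, ewc_params)
    G = 2.0 * mask.total_bp
    info = informative_sites(cohort.variants, cohort.father, cohort.mother)

    calls: dict[str, list[DnmCall]] = {}
    clusters: dict[str, list[MultisiteCluster]] = {}
    for child in cohort.children:
        child_calls = call_dnm_candidates(
            cohort.variants, cohort.father, cohort.mother, child, filter_params, mask
        )
        annotate_calls(child_calls, cohort.reference, repeat_params)
        for c in child_calls:
            c.parental_origin, c.origin_conflict = assign_parental_origin(
                c, info, max_distance=max_phase_distance
            )
        calls[child] = child_calls
        kept = [c for c in child_calls if not c.exclusion_flags]
        clusters[child] = cluster_multisite(kept, window=window)

    counts: dict[str, dict[str, int]] = {}
    rates: dict[str, dict[str, RateEstimate]] = {}
    table2: dict[str, pd.DataFrame] = {}
    for group, children in (
        ("before", cohort.children_before),
        ("after", cohort.children_after),
    ):
        tally = {"SNV": 0, "indel": 0, "multisite": 0, "excluded": 0}
        group_calls: list[DnmCall] = []
        for child in children:
            c = summarize_counts(calls[child], clusters[child])
            for k in tally:
                tally[k] += c[k]
            clustered = {
                m.key for cl in clusters[child] for m in cl.members
            }
            group_calls += [
                x for x in calls[child]
                if not x.exclusion_flags and x.key not in clustered
            ]
        counts[group] = tally
        n = len(children)
        rates[group] = {
            kind: mutation_rate(tally[key], n, G)
            for kind, key in (("SNV", "SNV"), ("indel", "indel"), ("multisite", "multisite"))
        }
        table2[group] = table2_breakdown(group_calls)
    return CohortResult(
        mask=mask, calls=calls, clusters=clusters, counts=counts,
        rates=rates, table2=table2, G=G,
    )
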