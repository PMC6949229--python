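"""Synthetic trio cohorts with planted, labelled de novo mutations.

The generator emulates the structure of a two-cohort parental-irradiation
study: a father/mother pair producing six offspring conceived before and six
after the exposure.  It produces, with full ground truth,

* a reference genome seeded with tandem repeat runs (unit lengths 1-4) so
  repeat-based indel filters are exercised,
* strain-informative marker sites (one parent homozygous alt, the other
  homozygous ref) carrying read-backed haplotype tags for phasing,
* spontaneous SNVs/indels at the per-nucleotide per-generation rates
  4.0e-9 and 3.9e-10 over the diploid genome, scaled linearly with parental
  age beyond the 8-week reference,
* radiation-signature mutations in the post-exposure offspring: non-repeat
  deletions (>=3 nt) carrying 2-4 nt breakpoint microhomology in a
  configurable fraction (default 60%), single-nucleotide deletions in
  mononucleotide runs, and multisite clusters within 100 bp on the exposed
  parent's haplotype,
* negative-binomial depth tracks (high-MQ and total) with low-coverage,
  high-coverage and low-mapping-quality artifact segments to exercise the
  callable-region mask.

Every planted mutation has exactly one truth record; a fixed seed yields
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indels import annotate_repeat, detect_microhomology

__all__ = [
    "SimulationConfig",
    "TrioCohort",
    "generate_reference",
    "generate_trio_cohort",
    "simulate_nonrepeat_deletion_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MARGIN = 64  # keep variants clear of chromosome ends (flank requirements)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic two-cohort trio experiment."""

    genome_length: int = 500_000      # bp per synthetic chromosome
    n_chromosomes: int = 2
    n_offspring_per_group: int = 6
    snv_rate: float = 4.0e-9          # per nt per generation (diploid)
    indel_rate: float = 3.9e-10
    multisite_rate: float = 6.5e-11   # 2 clusters / 12 offspring / (2 x 1.29e9 nt)
    paternal_age_weeks: tuple[float, float] = (8.0, 26.0)  # (before, after) group
    maternal_age_weeks: tuple[float, float] = (8.0, 17.0)
    reference_age_weeks: float = 8.0
    aging_r_paternal: float = 0.045   # fraction of baseline count added per week
    aging_r_maternal: float = 0.023
    exposed_parent: str = "father"
    induced_deletion_count_mean: float = 6.0   # per post-exposure offspring
    induced_multisite_count_mean: float = 1.3
    microhomology_fraction: float = 0.6
    mononucleotide_deletion_fraction: float = 0.45
    strain_polymorphism_rate: float = 0.005    # informative markers per nt
    repeat_run_density: float = 0.02           # genome fraction inside planted runs
    mean_depth: float = 40.0
    depth_dispersion: float = 0.05             # NB: var = mu + disp * mu^2
    mq_baseline: float = 0.95                  # high-MQ read fraction outside artifacts
    artifact_fraction: float = 0.02            # genome fraction in depth/MQ artifacts
    vaf_concentration: float = 50.0            # Beta(conc/2, conc/2) child VAF
    parent_noise_vaf: float = 0.01             # parental stray-read rate at DNM sites
    phase_block_bp: int = 1000                 # read-backed phasing range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes < 1:
            raise ValueError("genome_length and n_chromosomes must be positive")
        for name in (
            "snv_rate", "indel_rate", "multisite_rate", "induced_deletion_count_mean",
            "induced_multisite_count_mean", "strain_polymorphism_rate",
            "repeat_run_density", "mean_depth", "depth_dispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "microhomology_fraction", "mononucleotide_deletion_fraction",
            "mq_baseline", "artifact_fraction", "parent_noise_vaf",
        ):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.exposed_parent not in ("father", "mother"):
            raise ValueError("exposed_parent must be 'father' or 'mother'")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @property
    def total_length(self) -> int:
        return self.genome_length * self.n_chromosomes


@dataclass
class TrioCohort:
    """In-memory synthetic experiment: reference, variants, depth, truth."""

    config: SimulationConfig
    reference: dict[str, str]
    variants: pd.DataFrame
    depth: dict[str, dict[str, dict[str, np.ndarray]]]  # sample -> chrom -> {hq,total}
    truth: pd.DataFrame
    father: str = "father"
    mother: str = "mother"
    children_before: tuple[str, ...] = ()
    children_after: tuple[str, ...] = ()

    @property
    def children(self) -> tuple[str, ...]:
        return self.children_before + self.children_after

    @property
    def samples(self) -> tuple[str, ...]:
        return (self.father, self.mother) + self.children

    def group_of(self, child: str) -> str:
        if child in self.children_before:
            return "before"
        if child in self.children_after:
            return "after"
        raise KeyError(child)

    def write(self, outdir) -> None:
        from . import io

        io.write_cohort(self, outdir)


# ---------------------------------------------------------------------------
# reference construction


def _other_base(rng: np.random.Generator, *avoid: int) -> int:
    choices = np.array([b for b in _BASES if b not in avoid], dtype=np.uint8)
    return int(choices[rng.integers(len(choices))])


def _plant_run(
    arr: np.ndarray, occ: np.ndarray, rng: np.random.Generator,
    unit: np.ndarray, count: int,
) -> int:
    """Write a clean tandem run at a free position; returns planted bp (0 on failure)."""
    span = len(unit) * count
    L = len(arr)
    for _ in range(40):
        s = int(rng.integers(_MARGIN, L - _MARGIN - span))
        if occ[s - 1 : s + span + 1].any():
            continue
        arr[s : s + span] = np.tile(unit, count)
        if arr[s - 1] == unit[-1]:
            arr[s - 1] = _other_base(rng, unit[-1])
        if arr[s + span] == unit[0]:
            arr[s + span] = _other_base(rng, unit[0])
        occ[s - 1 : s + span + 1] = True
        return span
    return 0


def _reference_arrays(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10,000 bp")
    arrays: dict[str, np.ndarray] = {}
    occupied: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        arr = _BASES[rng.integers(0, 4, config.genome_length)]
        occ = np.zeros(config.genome_length, dtype=bool)
        if config.repeat_run_density > 0:
            # one exact 8-unit mononucleotide run (exercises the >7 exclusion)
            base = _BASES[rng.integers(4)]
            _plant_run(arr, occ, rng, np.array([base], dtype=np.uint8), 8)
            target = int(config.repeat_run_density * config.genome_length)
            planted = 0
            while planted < target:
                u = int(rng.integers(1, 5))
                count = int(rng.integers(2, 11))
                if u == 1:
                    unit = _BASES[rng.integers(4, size=1)]
                else:
                    unit = _BASES[rng.integers(0, 4, u)]
                planted += _plant_run(arr, occ, rng, unit, count) or len(unit) * count
        arrays[chrom] = arr
        occupied[chrom] = occ
    return arrays, occupied


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Per-chromosome reference sequences (deterministic in config.seed)."""
    rng = np.random.default_rng([config.seed, 0])
    arrays, _ = _reference_arrays(config, rng)
    return {c: a.tobytes().decode("ascii") for c, a in arrays.items()}


# ---------------------------------------------------------------------------
# low-level context planting


def _free_pos(
    rng: np.random.Generator, occ: np.ndarray, span: int, margin: int = _MARGIN
) -> int | None:
    L = len(occ)
    for _ in range(200):
        s = int(rng.integers(margin, L - margin - span))
        if not occ[s - 2 : s + span + 2].any():
            return s
    return None


def _window_record(arr: np.ndarray, s: int, length: int, flank: int = 52):
    """Local sequence window and VCF-style deletion record around arr[s:s+length]."""
    ws = s - flank
    seq = arr[ws : s + length + flank].tobytes().decode("ascii")
    pos_local = flank  # 1-based anchor position inside the window
    ref = seq[flank - 1 : flank + length]
    alt = seq[flank - 1]
    return seq, pos_local, ref, alt


def _write_nonrepeat_deletion(
    arr: np.ndarray,
    s: int,
    length: int,
    with_mh: bool,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> int | None:
    """Shape arr so deleting arr[s:s+length] is a left-aligned non-repeat deletion.

    With ``with_mh`` the downstream flank is made to share the first 2-4
    deleted bases (breakpoint microhomology); otherwise any junction
    identity is removed.  Returns the planted microhomology length (0 for
    none) or None when no valid context was found.
    """
    for _ in range(max_tries):
        lo, hi = s - 1, s + length + 6
        arr[lo:hi] = _BASES[rng.integers(0, 4, hi - lo)]
        k = 0
        if with_mh:
            k = int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1]))
            arr[s + length : s + length + k] = arr[s : s + k]
        elif arr[s + length] == arr[s]:
            arr[s + length] = _other_base(rng, arr[s])
        if arr[s - 1] == arr[s + length - 1]:  # keep the record left-aligned
            arr[s - 1] = _other_base(rng, arr[s + length - 1])
        seq, pos_local, ref, alt = _window_record(arr, s, length)
        ann = annotate_repeat(pos_local, ref, alt, seq, min_flank=50)
        mh = detect_microhomology(pos_local, ref, alt, seq, min_flank=50)
        if not ann.is_repeat_indel and mh.has_mh == with_mh:
            return k
    return None


def _write_mono_run_deletion(
    arr: np.ndarray, s: int, n_units: int, rng: np.random.Generator
) -> None:
    """Write an n-unit mononucleotide run at arr[s:]; the deletion removes one unit."""
    base = _BASES[rng.integers(4)]
    arr[s : s + n_units] = base
    if arr[s - 1] == base:
        arr[s - 1] = _other_base(rng, base)
    if arr[s + n_units] == base:
        arr[s + n_units] = _other_base(rng, base)


def _deletion_length(rng: np.random.Generator) -> int:
    # non-repeat deletion sizes 3-35 nt, mostly small (observed range)
    return 3 + min(int(rng.geometric(0.18)) - 1, 32)


# ---------------------------------------------------------------------------
# cohort generation

_MONO_UNIT_CHOICES = np.array([2, 3, 4, 5, 6, 7])
_MONO_UNIT_WEIGHTS = np.array([0.50, 0.20, 0.12, 0.08, 0.06, 0.04])


class _TagBook:
    """Opaque haplotype tags per (offspring, chromosome, phase block)."""

    def __init__(self, rng: np.random.Generator, block_bp: int) -> None:
        self._rng = rng
        self._block = block_bp
        self._map: dict[tuple, dict[str, str]] = {}
        self._n = 0

    def block(self, pos0: int) -> int:
        return pos0 // self._block

    def tag(self, child: str, chrom: str, pos0: int, origin: str) -> str:
        key = (child, chrom, self.block(pos0))
        if key not in self._map:
            a, b = f"h{self._n:07d}", f"h{self._n + 1:07d}"
            self._n += 2
            if self._rng.random() < 0.5:
                a, b = b, a
            self._map[key] = {"paternal": a, "maternal": b}
        return self._map[key][origin]


def _depth_tracks(
    config: SimulationConfig, rng: np.random.Generator, samples: tuple[str, ...]
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Negative-binomial depth smoothed over 100 bp windows.

    Coverage variation is split into a locus factor shared by all samples
    (GC/mappability-like, including the low/high-depth and low-MQ artifact
    segments every sample sees at the same loci) and a smaller per-sample
    factor, so the all-sample mask intersection behaves like real data
    rather than eroding multiplicatively.
    """
    win = 100
    disp, mu = config.depth_dispersion, config.mean_depth
    L = config.genome_length
    nwin = math.ceil(L / win)

    def _gamma_field(cv2: float) -> np.ndarray:
        if cv2 <= 0:
            return np.ones(nwin)
        k = 1.0 / cv2
        return rng.gamma(k, 1.0 / k, nwin)

    # shared locus-level structure
    locus: dict[str, np.ndarray] = {}
    mq_shared: dict[str, np.ndarray] = {}
    for chrom in config.chromosomes:
        lf = np.repeat(_gamma_field(disp), win)[:L]
        mq = np.full(L, config.mq_baseline)
        n_seg = max(3, int(L * config.artifact_fraction / 1500))
        kinds = ("low", "high", "lowmq")
        for i in range(n_seg):
            seg = int(rng.integers(500, 2500))
            a = int(rng.integers(0, L - seg))
            kind = kinds[i % 3]
            if kind == "low":
                lf[a : a + seg] *= 0.15
            elif kind == "high":
                lf[a : a + seg] *= 4.0
            else:
                mq[a : a + seg] = 0.5
        locus[chrom] = lf
        mq_shared[chrom] = mq

    out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sample in samples:
        out[sample] = {}
        for chrom in config.chromosomes:
            sf = np.repeat(_gamma_field(disp / 4.0), win)[:L]
            total = rng.poisson(mu * locus[chrom] * sf).astype(np.int32)
            hq = rng.binomial(total, mq_shared[chrom]).astype(np.int32)
            out[sample][chrom] = {"hq": hq, "total": total}
    return out


def generate_trio_cohort(config: SimulationConfig) -> TrioCohort:
    """Generate the full synthetic experiment for one seed.

    Returns a :class:`TrioCohort` whose variant table carries per-sample
    high-MQ depth, alt-read counts and haplotype tags, and whose truth table
    labels every planted mutation with its class (spontaneous / aging /
    induced), signature and parental origin.
    """
    rng = np.random.default_rng([config.seed, 1])
    arrays, occupied = _reference_arrays(config, np.random.default_rng([config.seed, 0]))
    chroms = config.chromosomes
    n = config.n_offspring_per_group
    children_before = tuple(f"F1_before_{i + 1}" for i in range(n))
    children_after = tuple(f"F1_after_{i + 1}" for i in range(n))
    samples = ("father", "mother") + children_before + children_after
    tags = _TagBook(rng, config.phase_block_bp)

    # --- strain-informative marker sites ------------------------------------
    markers: list[dict] = []
    for chrom in chroms:
        occ = occupied[chrom]
        candidates = np.flatnonzero(~occ[_MARGIN : config.genome_length - _MARGIN]) + _MARGIN
        pick = candidates[rng.random(candidates.size) < config.strain_polymorphism_rate]
        for pos0 in pick.tolist():
            if occ[pos0 - 1 : pos0 + 2].any():
                continue
            occ[pos0 - 1 : pos0 + 2] = True
            ref = int(arrays[chrom][pos0])
            markers.append(
                {
                    "chrom": chrom,
                    "pos0": pos0,
                    "ref": chr(ref),
                    "alt": chr(_other_base(rng, ref)),
                    "alt_parent": "paternal" if rng.random() < 0.5 else "maternal",
                }
            )

    # --- planted DNMs -------------------------------------------------------
    truth_rows: list[dict] = []
    ms_counter = 0
    L_tot = config.total_length
    hap_mean_snv = config.snv_rate * L_tot      # per haploid genome
    hap_mean_indel = config.indel_rate * L_tot

    def choose_chrom() -> str:
        return chroms[int(rng.integers(len(chroms)))]

    def plant_snv(child: str, cls: str, origin: str) -> None:
        chrom = choose_chrom()
        s = _free_pos(rng, occupied[chrom], 1)
        if s is None:
            return
        occupied[chrom][s - 2 : s + 3] = True
        ref = int(arrays[chrom][s])
        truth_rows.append(
            {
                "chrom": chrom, "pos": s + 1, "ref": chr(ref),
                "alt": chr(_other_base(rng, ref)), "child": child,
                "planted_class": cls, "planted_signature": "none",
                "parental_origin": origin, "cluster_id": "",
            }
        )

    def plant_spont_indel(child: str, cls: str, origin: str) -> None:
        chrom = choose_chrom()
        arr, occ = arrays[chrom], occupied[chrom]
        length = min(int(rng.geometric(0.5)), 10)
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        for _ in range(50):
            s = _free_pos(rng, occ, length + 2)
            if s is None:
                return
            if kind == "deletion":
                if arr[s - 1] == arr[s + length - 1]:  # must stay left-aligned
                    continue
                ref = arr[s - 1 : s + length].tobytes().decode("ascii")
                alt = ref[0]
            else:
                ins = _BASES[rng.integers(0, 4, length)]
                if ins[-1] == arr[s - 1]:
                    ins[-1] = _other_base(rng, arr[s - 1])
                alt = chr(arr[s - 1]) + ins.tobytes().decode("ascii")
                ref = alt[0]
            occ[s - 2 : s + length + 3] = True
            truth_rows.append(
                {
                    "chrom": chrom, "pos": s, "ref": ref, "alt": alt, "child": child,
                    "planted_class": cls, "planted_signature": "none",
                    "parental_origin": origin, "cluster_id": "",
                }
            )
            return

    def plant_induced_deletion(child: str, origin: str) -> None:
        chrom = choose_chrom()
        arr, occ = arrays[chrom], occupied[chrom]
        if rng.random() < config.mononucleotide_deletion_fraction:
            n_units = int(rng.choice(_MONO_UNIT_CHOICES, p=_MONO_UNIT_WEIGHTS))
            s = _free_pos(rng, occ, n_units + 2)
            if s is None:
                return
            _write_mono_run_deletion(arr, s, n_units, rng)
            occ[s - 2 : s + n_units + 3] = True
            truth_rows.append(
                {
                    "chrom": chrom, "pos": s,
                    "ref": chr(arr[s - 1]) + chr(arr[s]), "alt": chr(arr[s - 1]),
                    "child": child, "planted_class": "induced",
                    "planted_signature": "mono_run_deletion",
                    "parental_origin": origin, "cluster_id": "",
                }
            )
            return
        length = _deletion_length(rng)
        with_mh = bool(rng.random() < config.microhomology_fraction)
        s = _free_pos(rng, occ, length + 8)
        if s is None:
            return
        planted = _write_nonrepeat_deletion(arr, s, length, with_mh, rng)
        if planted is None:
            return
        occ[s - 2 : s + length + 8] = True
        truth_rows.append(
            {
                "chrom": chrom, "pos": s,
                "ref": arr[s - 1 : s + length].tobytes().decode("ascii"),
                "alt": chr(arr[s - 1]), "child": child, "planted_class": "induced",
                "planted_signature": (
                    "microhomology_deletion" if with_mh else "nonrepeat_deletion"
                ),
                "parental_origin": origin, "cluster_id": "",
            }
        )

    def plant_multisite(child: str, cls: str, origin: str) -> None:
        nonlocal ms_counter
        chrom = choose_chrom()
        arr, occ = arrays[chrom], occupied[chrom]
        size = 2 if rng.random() < 0.75 else 3
        gaps = [
            int(rng.integers(1, 16)) if rng.random() < 0.9 else int(rng.integers(16, 101))
            for _ in range(size - 1)
        ]
        span = sum(gaps)
        block = config.phase_block_bp
        for _ in range(100):
            s = _free_pos(rng, occ, span + 2)
            if s is None:
                return
            if (s // block) == ((s + span) // block):
                break
        else:
            return
        occ[s - 2 : s + span + 3] = True
        cid = f"ms{ms_counter:05d}"
        ms_counter += 1
        pos0 = s
        positions = [pos0]
        for g in gaps:
            pos0 += g
            positions.append(pos0)
        for p in positions:
            ref = int(arrays[chrom][p])
            if rng.random() < 0.9 or arr[p - 1] == arr[p]:
                rec = {
                    "ref": chr(ref), "alt": chr(_other_base(rng, ref)), "pos": p + 1,
                }
            else:  # occasional single-nt deletion member (kept left-aligned)
                rec = {
                    "ref": chr(arr[p - 1]) + chr(arr[p]), "alt": chr(arr[p - 1]),
                    "pos": p,
                }
            truth_rows.append(
                {
                    "chrom": chrom, **rec, "child": child, "planted_class": cls,
                    "planted_signature": "multisite" if cls == "induced" else "none",
                    "parental_origin": origin, "cluster_id": cid,
                }
            )

    groups = (
        ("before", children_before, 0),
        ("after", children_after, 1),
    )
    for group, children, gi in groups:
        dw_p = max(0.0, config.paternal_age_weeks[gi] - config.reference_age_weeks)
        dw_m = max(0.0, config.maternal_age_weeks[gi] - config.reference_age_weeks)
        for child in children:
            for origin, dw, r in (
                ("paternal", dw_p, config.aging_r_paternal),
                ("maternal", dw_m, config.aging_r_maternal),
            ):
                for _ in range(rng.poisson(hap_mean_snv)):
                    plant_snv(child, "spontaneous", origin)
                for _ in range(rng.poisson(2 * hap_mean_snv * r * dw)):
                    plant_snv(child, "aging", origin)
                for _ in range(rng.poisson(hap_mean_indel)):
                    plant_spont_indel(child, "spontaneous", origin)
                for _ in range(rng.poisson(2 * hap_mean_indel * r * dw)):
                    plant_spont_indel(child, "aging", origin)
            for _ in range(rng.poisson(config.multisite_rate * 2 * L_tot)):
                origin = "paternal" if rng.random() < 0.5 else "maternal"
                plant_multisite(child, "spontaneous", origin)
            if group == "after":
                exposed = "paternal" if config.exposed_parent == "father" else "maternal"
                for _ in range(rng.poisson(config.induced_deletion_count_mean)):
                    plant_induced_deletion(child, exposed)
                for _ in range(rng.poisson(config.induced_multisite_count_mean)):
                    plant_multisite(child, "induced", exposed)

    # --- depth tracks -------------------------------------------------------
    depth = _depth_tracks(config, rng, samples)

    # --- assemble the joint variant table -----------------------------------
    conc = config.vaf_concentration
    rows: list[dict] = []
    for mk in markers:
        chrom, pos0 = mk["chrom"], mk["pos0"]
        row = {"chrom": chrom, "pos": pos0 + 1, "ref": mk["ref"], "alt": mk["alt"]}
        alt_parent = "father" if mk["alt_parent"] == "paternal" else "mother"
        for s in ("father", "mother"):
            dp = int(depth[s][chrom]["hq"][pos0])
            p = 0.99 if s == alt_parent else 0.005
            row[f"{s}_dp"] = dp
            row[f"{s}_ad"] = int(rng.binomial(dp, p))
            row[f"{s}_ht"] = ""
        for c in children_before + children_after:
            dp = int(depth[c][chrom]["hq"][pos0])
            row[f"{c}_dp"] = dp
            row[f"{c}_ad"] = int(rng.binomial(dp, 0.5))
            row[f"{c}_ht"] = tags.tag(c, chrom, pos0, mk["alt_parent"])
        rows.append(row)

    for t in truth_rows:
        chrom, pos0 = t["chrom"], t["pos"] - 1
        row = {"chrom": chrom, "pos": t["pos"], "ref": t["ref"], "alt": t["alt"]}
        for s in samples:
            dp = int(depth[s][chrom]["hq"][pos0])
            row[f"{s}_dp"] = dp
            if s == t["child"]:
                vaf = rng.beta(conc / 2, conc / 2)
                row[f"{s}_ad"] = int(rng.binomial(dp, vaf))
                row[f"{s}_ht"] = tags.tag(s, chrom, pos0, t["parental_origin"])
            elif s in ("father", "mother"):
                row[f"{s}_ad"] = int(rng.binomial(dp, config.parent_noise_vaf))
                row[f"{s}_ht"] = ""
            else:
                row[f"{s}_ad"] = 0
                row[f"{s}_ht"] = ""
        rows.append(row)

    columns = ["chrom", "pos", "ref", "alt"]
    for s in samples:
        columns += [f"{s}_dp", f"{s}_ad", f"{s}_ht"]
    variants = pd.DataFrame(rows, columns=columns)
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "child", "planted_class",
            "planted_signature", "parental_origin", "cluster_id",
        ],
    )
    truth = truth.sort_values(["child", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )

    return TrioCohort(
        config=config,
        reference={c: a.tobytes().decode("ascii") for c, a in arrays.items()},
        variants=variants,
        depth=depth,
        truth=truth,
        children_before=children_before,
        children_after=children_after,
    )


# ---------------------------------------------------------------------------
# standalone signature-deletion sets


def simulate_nonrepeat_deletion_set(
    n: int,
    mh_fraction: float | None = None,
    seed: int | np.random.Generator = 0,
    min_length: int = 3,
    max_length: int = 35,
    flank: int = 52,
) -> pd.DataFrame:
    """Independent non-repeat deletions (>=3 nt) with planted microhomology labels.

    Each row carries its own local reference window, a left-aligned VCF-style
    record, and the planted truth label; `mh_fraction` defaults to the
    signature default in :class:`SimulationConfig`.  Deletion lengths span
    ``min_length``..``max_length``.
    """
    if mh_fraction is None:
        mh_fraction = SimulationConfig().microhomology_fraction
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    while len(rows) < n:
        length = min(max(_deletion_length(rng), min_length), max_length)
        with_mh = bool(rng.random() < mh_fraction)
        arr = _BASES[rng.integers(0, 4, 2 * flank + length + 8)]
        planted = _write_nonrepeat_deletion(arr, flank, length, with_mh, rng)
        if planted is None:
            continue
        seq, pos, ref, alt = _window_record(arr, flank, length, flank)
        rows.append(
            {
                "sequence": seq, "pos": pos, "ref": ref, "alt": alt,
                "length": length, "planted_mh": with_mh, "planted_mh_length": planted,
            }
        )
    return pd.DataFrame(rows)
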