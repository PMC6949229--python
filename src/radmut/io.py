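"""Readers and writers for the standard file formats used by the pipeline.

Variant tables travel as multi-sample VCF (GT/DP/AD plus an HT haplotype-tag
FORMAT field), depth tracks as bedGraph, masks as BED3, reference sequences
as FASTA, truth tables as TSV.  VCF positions are 1-based, BED/bedGraph
coordinates 0-based half-open.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .ewc import EwcMask

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bedgraph",
    "read_bedgraph",
    "write_mask_bed",
    "read_mask_bed",
    "write_trio_vcf",
    "read_trio_vcf",
    "write_cohort",
]


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(os.fspath(path)) as fh:
        for entry in fh:
            out[entry.name] = entry.sequence.upper()
    return out


def write_bedgraph(track: dict[str, np.ndarray], path) -> None:
    """Run-length-encoded per-base values."""
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            arr = np.asarray(arr)
            if not arr.size:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{int(arr[s])}\n")


def read_bedgraph(path, lengths: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )
    if lengths is None:
        lengths = df.groupby("chrom", sort=False)["end"].max().to_dict()
    out = {c: np.zeros(int(n), dtype=np.int64) for c, n in lengths.items()}
    for row in df.itertuples(index=False):
        out[row.chrom][row.start : row.end] = row.value
    return out


def write_mask_bed(mask: EwcMask, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for s, e in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_mask_bed(path, sample_set=()) -> EwcMask:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end"], comment="#")
    intervals = {
        c: g[["start", "end"]].to_numpy(dtype=np.int64)
        for c, g in df.groupby("chrom", sort=True)
    }
    return EwcMask(intervals=intervals, sample_set=frozenset(sample_set))


def _genotype(ad: int, dp: int) -> tuple:
    if dp <= 0:
        return (None, None)
    vaf = ad / dp
    if vaf < 0.1:
        return (0, 0)
    if vaf > 0.9:
        return (1, 1)
    return (0, 1)


def write_trio_vcf(
    variants: pd.DataFrame,
    samples: tuple[str, ...],
    contig_lengths: dict[str, int],
    path,
) -> None:
    """Write the joint variant table as a multi-sample VCF.

    DP carries the high-mapping-quality depth used for VAF computation, AD
    the (ref, alt) read counts, HT the read-backed haplotype tag of the alt
    allele (missing when unphased).
    """
    header = pysam.VariantHeader()
    for chrom, length in contig_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "High-mapping-quality read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("HT", 1, "String", "Haplotype tag of the alt allele")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for row in variants.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom, start=row.pos - 1, alleles=(row.ref, row.alt)
            )
            for s in samples:
                dp = int(getattr(row, f"{s}_dp"))
                ad = int(getattr(row, f"{s}_ad"))
                ht = getattr(row, f"{s}_ht", "") or None
                fmt = rec.samples[s]
                fmt["GT"] = _genotype(ad, dp)
                fmt["DP"] = dp
                fmt["AD"] = (dp - ad, ad)
                if ht:
                    fmt["HT"] = ht
            vf.write(rec)


def read_trio_vcf(path) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Read a multi-sample VCF back into the joint variant table."""
    rows = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = tuple(vf.header.samples)
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise ValueError("multi-allelic records must be split first")
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
            for s in samples:
                fmt = rec.samples[s]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                alt_reads = int(ad[1]) if ad is not None and ad[1] is not None else 0
                row[f"{s}_dp"] = int(dp) if dp is not None else 0
                row[f"{s}_ad"] = alt_reads
                ht = fmt.get("HT") or ""
                # pysam marks a missing String value with 0x07 bytes
                if "\x07" in ht or ht == ".":
                    ht = ""
                row[f"{s}_ht"] = ht
            rows.append(row)
    return pd.DataFrame(rows), samples


def write_cohort(cohort, outdir) -> None:
    """Write a synthetic cohort to disk (FASTA, VCF, bedGraph, truth TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {c: len(s) for c, s in cohort.reference.items()}
    write_fasta(cohort.reference, outdir / "reference.fa")
    write_trio_vcf(cohort.variants, cohort.samples, lengths, outdir / "cohort.vcf")
    depth_dir = outdir / "depth"
    depth_dir.mkdir(exist_ok=True)
    for sample, tracks in cohort.depth.items():
        write_bedgraph(
            {c: t["hq"] for c, t in tracks.items()}, depth_dir / f"{sample}.hq.bedgraph"
        )
        write_bedgraph(
            {c: t["total"] for c, t in tracks.items()},
            depth_dir / f"{sample}.total.bedgraph",
        )
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    meta = {
        "samples": list(cohort.samples),
        "father": cohort.father,
        "mother": cohort.mother,
        "children_before": list(cohort.children_before),
        "children_after": list(cohort.children_after),
        "contig_lengths": lengths,
        "seed": cohort.config.seed,
    }
    with open(outdir / "cohort.json", "w") as fh:
        json.dump(meta, fh, indent=2)
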