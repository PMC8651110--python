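"""VCF / TSV input-output for candidate calls, annotations and reports.

The VCF dialect is deliberately minimal (CHROM POS ID REF ALT QUAL FILTER
INFO + one sample with DP, AD and per-strand counts); annotations travel in
a sidecar TSV keyed by (chrom, pos, ref, alt) so the VCF stays lean.  After
filtering, FILTER carries the failed-filter names (PASS when none) and INFO
records which filters were evaluated, so a written call set re-reads with
identical verdicts.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
import pysam

from .calls import VariantCall
from .filters import FILTER_ORDER

_FILTER_DESCRIPTIONS = {
    "upstream": "Upstream caller FILTER was not PASS",
    "depth": "Sequencing depth at or below the minimum",
    "germline_self": "Allelic fraction in the germline band of this sample",
    "germline_cohort": "Locus germline in another cohort sample",
    "segdup": "Locus inside a known segmental duplication",
    "cluster": "Too many clustered variants in this sample",
    "mapq_parity": "Variant-read mapping quality below reference parity",
    "strand_bias": "Variant reads significantly skewed to one strand",
    "pop_af": "Population allele frequency above the exclusion threshold",
    "binomial_noise": "Not above the context-specific background noise",
}

_ANNOT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "cadd",
    "polyphen", "pop_af", "cosmic", "expressed_in_cd8", "context",
]


def _build_header(sample_id: str, contigs: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in contigs:
        header.contigs.add(chrom)
    for name in FILTER_ORDER:
        header.filters.add(name, None, None, _FILTER_DESCRIPTIONS[name])
    header.info.add("UPSTREAM", 1, "String", "FILTER string of the upstream caller")
    header.info.add("TESTED", 1, "String", "Pipe-joined names of evaluated filters")
    header.info.add("NP", 1, "Float", "Binomial background-noise test p-value")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("SAC", 4, "Integer", "Strand counts: ref fwd, ref rev, alt fwd, alt rev")
    header.formats.add("MQR", 1, "Float", "Mean mapping quality of reference reads")
    header.formats.add("MQA", 1, "Float", "Mean mapping quality of variant reads")
    header.add_sample(sample_id)
    return header


def write_variant_calls(calls: list[VariantCall], vcf_path: str | Path) -> None:
    """Write one sample's calls as a minimal VCF v4.2 (text).

    Verdicts, when present, are encoded in FILTER (semicolon-joined failed
    filter names, PASS if all passed) plus an INFO list of evaluated
    filters; calls without verdicts are written unfiltered ('.').
    """
    if not calls:
        raise ValueError("no calls to write")
    samples = {c.subject_id for c in calls}
    if len(samples) != 1:
        raise ValueError(f"one VCF per sample; got subjects {sorted(samples)}")
    sample_id = calls[0].subject_id
    contigs = sorted({c.chrom for c in calls})
    header = _build_header(sample_id, contigs)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, alleles=(c.ref, c.alt), qual=None
            )
            rec.info["UPSTREAM"] = c.upstream_filter or "PASS"
            if c.verdicts:
                rec.info["TESTED"] = "|".join(c.verdicts)
                for name in c.failed_filters:
                    rec.filter.add(name)
                if c.passed:
                    rec.filter.add("PASS")
            if c.noise_p is not None:
                rec.info["NP"] = c.noise_p
            smp = rec.samples[sample_id]
            smp["DP"] = c.depth
            smp["AD"] = (c.depth - c.alt_count, c.alt_count)
            smp["SAC"] = (c.ref_fwd, c.ref_rev, c.alt_fwd, c.alt_rev)
            smp["MQR"] = c.mean_mapq_ref
            smp["MQA"] = c.mean_mapq_alt
            out.write(rec)


def write_annotations(calls: list[VariantCall], path: str | Path) -> None:
    """Sidecar annotation TSV, one row per distinct (chrom, pos, ref, alt)."""
    seen: dict[tuple, dict] = {}
    for c in calls:
        row = {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gene": c.gene if c.gene is not None else ".",
            "consequence": c.consequence if c.consequence is not None else ".",
            "cadd": c.cadd if c.cadd is not None else ".",
            "polyphen": c.polyphen if c.polyphen is not None else ".",
            "pop_af": c.pop_af if c.pop_af is not None else ".",
            "cosmic": int(c.cosmic),
            "expressed_in_cd8": int(c.expressed_in_cd8),
            "context": c.context if c.context is not None else ".",
        }
        key = c.locus
        if key in seen and seen[key] != row:
            raise ValueError(f"conflicting annotations for {c.locus_id}")
        seen[key] = row
    pd.DataFrame(list(seen.values()), columns=_ANNOT_COLUMNS).sort_values(
        ["chrom", "pos", "ref", "alt"]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[tuple, dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[tuple, dict] = {}
    for r in df.itertuples(index=False):
        key = (r.chrom, int(r.pos), r.ref, r.alt)
        if key in out:
            raise ValueError(f"annotation key collision at {key}")
        out[key] = {
            "gene": None if r.gene == "." else r.gene,
            "consequence": None if r.consequence == "." else r.consequence,
            "cadd": None if r.cadd == "." else float(r.cadd),
            "polyphen": None if r.polyphen == "." else r.polyphen,
            "pop_af": None if r.pop_af == "." else float(r.pop_af),
            "cosmic": bool(int(r.cosmic)),
            "expressed_in_cd8": bool(int(r.expressed_in_cd8)),
            "context": None if r.context == "." else r.context,
        }
    return out


def read_variant_calls(
    vcf_path: str | Path, annotations_path: str | Path | None = None
) -> list[VariantCall]:
    """Read a single-sample VCF (plus optional sidecar) into VariantCalls.

    The sidecar's ref allele is checked against the VCF's: a mismatch means
    the two files disagree on the coordinate system and is an error.
    Records with no sidecar row are flagged ``annotated=False``; their
    annotation fields stay ``None`` rather than being silently defaulted.
    """
    annotations = read_annotations(annotations_path) if annotations_path else {}
    ann_by_pos: dict[tuple, str] = {}
    for (chrom, pos, ref, _alt) in annotations:
        ann_by_pos[(chrom, pos)] = ref
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_ids = list(vcf.header.samples)
        if len(sample_ids) != 1:
            raise ValueError("expected a single-sample VCF")
        sample_id = sample_ids[0]
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"expected exactly one ALT at {rec.chrom}:{rec.pos}")
            alt = rec.alts[0]
            smp = rec.samples[sample_id]
            depth = int(smp["DP"])
            ad = smp["AD"]
            alt_count = int(ad[1])
            if alt_count > depth:
                raise ValueError(f"{rec.chrom}:{rec.pos}: alt count {alt_count} > depth {depth}")
            sac = smp["SAC"]
            filters = list(rec.filter.keys())
            tested = rec.info.get("TESTED")
            upstream = rec.info.get("UPSTREAM")
            if upstream is None:
                upstream = ";".join(filters) if filters else "PASS"
            known_ref = ann_by_pos.get((rec.chrom, rec.pos))
            if known_ref is not None and known_ref != rec.ref:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: VCF ref {rec.ref} != annotation ref {known_ref};"
                    " coordinate-system mismatch?"
                )
            ann = annotations.get((rec.chrom, rec.pos, rec.ref, alt))
            c = VariantCall(
                subject_id=sample_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                depth=depth,
                alt_count=alt_count,
                ref_fwd=int(sac[0]),
                ref_rev=int(sac[1]),
                alt_fwd=int(sac[2]),
                alt_rev=int(sac[3]),
                mean_mapq_ref=round(float(smp["MQR"]), 3),
                mean_mapq_alt=round(float(smp["MQA"]), 3),
                upstream_filter=str(upstream),
                annotated=ann is not None,
                **(ann or {}),
            )
            np_val = rec.info.get("NP")
            if np_val is not None and not math.isnan(float(np_val)):
                c.noise_p = float(np_val)
            if tested:
                failed = set(filters) - {"PASS"}
                c.verdicts = {name: name not in failed for name in str(tested).split("|")}
            calls.append(c)
    return calls


def write_site_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_site_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as <name>.tsv under ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=True, float_format="%.6g")
        paths.append(p)
    return paths
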