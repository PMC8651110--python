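"""Closed-form clone-detectability arithmetic.

How many somatic mutations should a deep targeted sequencing experiment on
sorted CD8+ cells detect per subject?  The model chains five steps: DNA
input mass -> cell count (6 pg per diploid cell); purification -> CD8+
cells; sequencing depth x purity -> effective haploid CD8+ cell equivalents
actually sampled; the non-naive half of those, divided by the mean clone
size (surrogate: mean variant read count), -> number of detectable memory
clones; and an age-linear genome-wide burden scaled to the target region ->
mutations per clone.  The product is the expected number of detectable
mutations per subject.  Each step is rounded the way the derivation is
conventionally quoted (3 sf, 2 sf, floor, 2 dp, nearest integer); exact
values are available from :func:`derivation`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _round_half_down(x: float) -> int:
    """Nearest integer with exact halves rounding down (38.5 -> 38)."""
    return int(math.ceil(x - 0.5))


@dataclass
class CloneModelParams:
    """Constants of the detectability arithmetic, with study-typical defaults."""

    dna_ng: float = 1000.0
    pg_per_cell: float = 6.0
    cd8_purity: float = 0.90
    median_depth: float = 2349.0
    naive_fraction: float = 0.5
    mean_variant_reads: float = 19.3
    genome_burden: float = 880.0  # mutations per diploid genome at the cohort mean age
    genome_size_mb: float = 6200.0
    target_size_mb: float = 5.0

    def __post_init__(self) -> None:
        for name in ("dna_ng", "pg_per_cell", "median_depth", "mean_variant_reads",
                     "genome_burden", "genome_size_mb", "target_size_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.cd8_purity <= 1 or not 0 < self.naive_fraction < 1:
            raise ValueError("cd8_purity must be in (0,1], naive_fraction in (0,1)")


def cells_from_dna(dna_ng: float, pg_per_cell: float = 6.0) -> float:
    """Diploid cell count from DNA input mass, to 3 significant figures."""
    if dna_ng <= 0 or pg_per_cell <= 0:
        raise ValueError("dna_ng and pg_per_cell must be positive")
    return _round_sig(1000.0 * dna_ng / pg_per_cell, 3)


def purified_cd8_cells(total_cells: float, cd8_purity: float) -> float:
    """CD8+ cells after immunomagnetic purification, to 2 significant figures."""
    return _round_sig(total_cells * cd8_purity, 2)


def effective_haploid_cells(median_depth: float, cd8_purity: float) -> float:
    """Haploid CD8+ cell equivalents actually sampled by sequencing, to 2 sf.

    With cells in large excess of the depth, each read is essentially an
    independent haploid draw, so depth x purity cells are sampled.
    """
    if median_depth <= 0 or not 0 < cd8_purity <= 1:
        raise ValueError("median_depth must be > 0 and cd8_purity in (0, 1]")
    return _round_sig(median_depth * cd8_purity, 2)


def detectable_clones(
    effective_cells: float, naive_fraction: float, mean_variant_reads: float
) -> int:
    """Maximum number of detectable memory clones (floor of memory cells / clone size)."""
    if mean_variant_reads <= 0:
        raise ValueError("mean_variant_reads must be positive")
    return int(math.floor(effective_cells * (1.0 - naive_fraction) / mean_variant_reads))


def expected_target_burden(
    genome_burden: float, target_mb: float, genome_mb: float
) -> float:
    """Expected mutations per cell in the haploid target region, to 2 decimals."""
    if min(genome_burden, target_mb, genome_mb) <= 0:
        raise ValueError("all arguments must be positive")
    return round(genome_burden * target_mb / genome_mb, 2)


def expected_detectable_mutations(target_burden: float, n_clones: int) -> int:
    """Expected detectable mutations per subject (independent-phylogeny clones)."""
    if target_burden <= 0 or n_clones <= 0:
        raise ValueError("both arguments must be positive")
    return _round_half_down(target_burden * n_clones)


def genome_burden_at_age(age: float, per_year: float = 880.0 / 35.0, intercept: float = 0.0) -> float:
    """Age-linear diploid-genome mutation burden (default slope anchors 880 at 35 yrs)."""
    if age <= 0 or per_year <= 0:
        raise ValueError("age and per_year must be positive")
    return intercept + per_year * age


def derivation(params: CloneModelParams | None = None) -> dict[str, dict[str, float]]:
    """Full chained derivation; each step with its rounded and exact value."""
    p = params or CloneModelParams()
    total_exact = 1000.0 * p.dna_ng / p.pg_per_cell
    total = cells_from_dna(p.dna_ng, p.pg_per_cell)
    cd8_exact = total * p.cd8_purity
    cd8 = purified_cd8_cells(total, p.cd8_purity)
    eff_exact = p.median_depth * p.cd8_purity
    eff = effective_haploid_cells(p.median_depth, p.cd8_purity)
    clones_exact = eff * (1.0 - p.naive_fraction) / p.mean_variant_reads
    clones = detectable_clones(eff, p.naive_fraction, p.mean_variant_reads)
    burden_exact = p.genome_burden * p.target_size_mb / p.genome_size_mb
    burden = expected_target_burden(p.genome_burden, p.target_size_mb, p.genome_size_mb)
    mut_exact = burden * clones
    mut = expected_detectable_mutations(burden, clones)
    return {
        "total_cells": {"value": total, "exact": total_exact},
        "cd8_cells": {"value": cd8, "exact": cd8_exact},
        "effective_haploid_cells": {"value": eff, "exact": eff_exact},
        "detectable_clones": {"value": float(clones), "exact": clones_exact},
        "target_burden": {"value": burden, "exact": burden_exact},
        "detectable_mutations": {"value": float(mut), "exact": mut_exact},
    }


def derivation_text(params: CloneModelParams | None = None) -> str:
    p = params or CloneModelParams()
    d = derivation(p)
    lines = [
        f"DNA input {p.dna_ng:g} ng at {p.pg_per_cell:g} pg/cell"
        f" -> {d['total_cells']['value']:,.0f} cells",
        f"CD8+ purity {p.cd8_purity:.0%}"
        f" -> {d['cd8_cells']['value']:,.0f} CD8+ cells",
        f"median depth {p.median_depth:g}x * purity"
        f" -> {d['effective_haploid_cells']['value']:,.0f} haploid cell equivalents sampled",
        f"non-naive half / mean clone size {p.mean_variant_reads:g} reads"
        f" -> {d['detectable_clones']['value']:.0f} detectable memory clones",
        f"genome burden {p.genome_burden:g} * {p.target_size_mb:g}/{p.genome_size_mb:g} Mb"
        f" -> {d['target_burden']['value']:.2f} mutations per clone in target",
        f"expected detectable mutations per subject:"
        f" {d['detectable_mutations']['value']:.0f}",
    ]
    return "\n".join(lines)
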