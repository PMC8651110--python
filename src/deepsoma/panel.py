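"""Targeted gene panel: BED ingestion, interval bookkeeping and subjects.

The panel is the universe of the whole analysis: every simulated site, every
candidate call and every enrichment expectation is defined relative to the
summed exonic target intervals of its genes.  Coordinates follow the standard
dialects — BED is 0-based half-open, VCF (and :class:`VariantCall`) is
1-based — and conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Region = tuple[str, int, int]  # chrom, start, end; 0-based half-open


@dataclass
class PanelGene:
    """One gene's summed exonic capture target."""

    gene_id: str
    regions: list[Region]
    target_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: (r[0], r[1]))
        for chrom, start, end in self.regions:
            if start >= end:
                raise ValueError(
                    f"gene {self.gene_id}: malformed interval {chrom}:{start}-{end}"
                )
        self.target_length = sum(end - start for _, start, end in self.regions)
        if self.target_length <= 0:
            raise ValueError(f"gene {self.gene_id}: empty target")


@dataclass
class Panel:
    """A collection of :class:`PanelGene` with the summed target size."""

    genes: list[PanelGene]
    total_target: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty panel")
        self.total_target = sum(g.target_length for g in self.genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValueError("duplicate gene_id in panel")

    def gene(self, gene_id: str) -> PanelGene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} absent from panel") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def site_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten the panel into parallel per-site arrays.

        Returns ``(chroms, positions, gene_idx)`` where ``positions`` are
        0-based coordinates of every targeted base and ``gene_idx`` indexes
        into ``self.genes``.
        """
        chroms, poss, gidx = [], [], []
        for i, g in enumerate(self.genes):
            for chrom, start, end in g.regions:
                n = end - start
                chroms.append(np.full(n, chrom, dtype=object))
                poss.append(np.arange(start, end, dtype=np.int64))
                gidx.append(np.full(n, i, dtype=np.int32))
        return (
            np.concatenate(chroms),
            np.concatenate(poss),
            np.concatenate(gidx),
        )


@dataclass
class Subject:
    subject_id: str
    group: str  # "case" | "control"
    age: float  # years
    sex: str  # "F" | "M"
    median_depth: float  # reads

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be case/control, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F/M, got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.median_depth <= 0:
            raise ValueError("median_depth must be positive")


def _merge_overlaps(regions: list[Region], gene_id: str) -> list[Region]:
    out: list[Region] = []
    for chrom, start, end in sorted(regions, key=lambda r: (r[0], r[1])):
        if out and out[-1][0] == chrom and start < out[-1][2]:
            log.warning("gene %s: overlapping intervals merged at %s:%d", gene_id, chrom, start)
            out[-1] = (chrom, out[-1][1], max(end, out[-1][2]))
        else:
            out.append((chrom, start, end))
    return out


def read_panel(bed_path: str | Path, gene_column: int = 3) -> Panel:
    """Read a BED4+ file into a :class:`Panel`, aggregating rows by gene id.

    Malformed intervals (start >= end) are rejected with their line number;
    overlapping intervals within a gene are merged with a logged warning.
    """
    by_gene: dict[str, list[Region]] = {}
    order: list[str] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) <= gene_column:
                raise ValueError(f"{bed_path}:{lineno}: expected >= {gene_column + 1} columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{bed_path}:{lineno}: malformed interval {start}>={end}")
            gene = parts[gene_column]
            if gene not in by_gene:
                by_gene[gene] = []
                order.append(gene)
            by_gene[gene].append((chrom, start, end))
    if not by_gene:
        raise ValueError("empty panel")
    genes = [PanelGene(g, _merge_overlaps(by_gene[g], g)) for g in order]
    return Panel(genes)


def write_panel_bed(panel: Panel, bed_path: str | Path) -> None:
    rows = []
    for g in panel.genes:
        for chrom, start, end in g.regions:
            rows.append((chrom, start, end, g.gene_id))
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)


def write_subjects(subjects: list[Subject], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "median_depth": s.median_depth,
            }
            for s in subjects
        ]
    ).to_csv(path, sep="\t", index=False)


def read_subjects(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, sep="\t")
    return [
        Subject(str(r.subject_id), str(r.group), float(r.age), str(r.sex), float(r.median_depth))
        for r in df.itertuples()
    ]
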