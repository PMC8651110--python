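"""The candidate somatic variant call record shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

CONSEQUENCES = (
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "stopgain",
    "frameshift_indel",
    "nonframeshift_indel",
    "splice",
    "other",
)

INDEL_CONSEQUENCES = ("frameshift_indel", "nonframeshift_indel")

POLYPHEN = ("D", "P", "B")


@dataclass
class VariantCall:
    """One candidate somatic variant with its read evidence and annotations.

    ``verdicts`` maps filter name -> bool (True = passed) and is populated by
    :func:`deepsoma.filters.apply_filters`.  Annotation fields may be ``None``
    when the sidecar carries no record for the locus; such calls are flagged
    ``annotated=False`` rather than silently defaulted.
    """

    subject_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    alt_fwd: int = 0
    alt_rev: int = 0
    ref_fwd: int = 0
    ref_rev: int = 0
    mean_mapq_alt: float = 60.0
    mean_mapq_ref: float = 60.0
    upstream_filter: str = "PASS"
    gene: str | None = None
    consequence: str | None = None
    cadd: float | None = None
    polyphen: str | None = None  # D / P / B / None (missing)
    pop_af: float | None = None
    cosmic: bool = False
    expressed_in_cd8: bool = True
    context: str | None = None  # 3-mer; None for indels
    annotated: bool = True
    noise_p: float | None = None  # binomial artifact-test p, set by the cascade
    verdicts: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"{self.locus_id}: depth must be positive")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"{self.locus_id}: alt_count {self.alt_count} exceeds depth {self.depth}"
            )
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth

    @property
    def locus(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def passed(self) -> bool:
        """True when every evaluated filter passed (meaningless before filtering)."""
        return bool(self.verdicts) and all(self.verdicts.values())

    @property
    def failed_filters(self) -> list[str]:
        return [name for name, ok in self.verdicts.items() if not ok]


def passing(calls: list[VariantCall]) -> list[VariantCall]:
    """Calls whose every evaluated filter verdict is a pass."""
    return [c for c in calls if c.passed]


def select_expressed(calls: list[VariantCall]) -> list[VariantCall]:
    return [c for c in calls if c.expressed_in_cd8]


def select_consequence(calls: list[VariantCall], *classes: str) -> list[VariantCall]:
    return [c for c in calls if c.consequence in classes]


def nonsynonymous(calls: list[VariantCall]) -> list[VariantCall]:
    """Everything except synonymous SNVs and unannotated/other records."""
    keep = ("nonsynonymous_SNV", "stopgain", "frameshift_indel", "nonframeshift_indel", "splice")
    return select_consequence(calls, *keep)
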