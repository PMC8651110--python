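"""Synthetic deep-panel cohorts with a known truth set.

The generator emulates the statistical structure of deep targeted sequencing
of sorted CD8+ cell DNA: ~2000-3500x depth over a multi-gene exonic panel,
germline heterozygous/homozygous variants at population polymorphic sites,
somatic clones at allelic fractions of 0.2-9% (log-uniform, concentrated
below 1%), and context-dependent substitution noise in which C>T (G>A) at
CpG sites runs roughly an order of magnitude above other substitutions.
Every downstream stage — noise tabulation, the filter cascade, enrichment
and cohort statistics — is exercised against the returned truth set.

Counts are simulated at the pileup-summary level (per-site allele and strand
tallies), not at the read level; see the methods note for what this does and
does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import VariantCall
from .panel import Panel, PanelGene, Subject
from .seq import BASES, decode_context

# consequence mix used for planted somatic variants and caller-emulated noise
# candidates; loosely shaped on the discovered-mutation composition of deep
# CD8+ panels (mostly nonsynonymous SNVs, a few percent truncating/indel).
CONSEQUENCE_PROBS = {
    "nonsynonymous_SNV": 0.60,
    "synonymous_SNV": 0.22,
    "stopgain": 0.06,
    "frameshift_indel": 0.05,
    "nonframeshift_indel": 0.03,
    "splice": 0.02,
    "other": 0.02,
}


@dataclass
class NoiseProfile:
    """Context-dependent per-base mismatch rates.

    ``base_rate`` applies to every (context, substitution) cell unless a
    multiplier is registered for it in ``context_multipliers`` (keyed by the
    3-mer context and the alternate base).  All resulting rates must stay in
    [0, 0.01] — background noise, not genuine mixed alleles.

    ``hotspot_fraction`` adds overdispersion to the multiplier-boosted cells:
    that fraction of their sites carries ``hotspot_multiplier`` times the
    cell rate (site-specific damage propensity, as real deamination noise
    shows).  With hotspots the tabulated cell-mean rate understates the hot
    sites, which is exactly what lets relaxed binomial cutoffs flood the
    call set with C>T artifacts; the default is 0 (pure binomial noise).
    """

    base_rate: float = 1e-4
    context_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    hotspot_fraction: float = 0.0
    hotspot_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 0.01:
            raise ValueError(f"base_rate {self.base_rate} outside [0, 0.01]")
        if not 0.0 <= self.hotspot_fraction < 1.0 or self.hotspot_multiplier < 1.0:
            raise ValueError("hotspot_fraction in [0, 1), hotspot_multiplier >= 1")
        for (ctx, alt), mult in self.context_multipliers.items():
            rate = self.base_rate * mult * max(1.0, self.hotspot_multiplier)
            if not 0.0 <= rate <= 0.01:
                raise ValueError(f"rate {rate} for ({ctx},{alt}) outside [0, 0.01]")

    @classmethod
    def flat(cls, base_rate: float = 1e-4) -> "NoiseProfile":
        return cls(base_rate=base_rate)

    @classmethod
    def with_cpg_ct(
        cls,
        base_rate: float = 1e-4,
        multiplier: float = 10.0,
        hotspot_fraction: float = 0.0,
        hotspot_multiplier: float = 3.0,
    ) -> "NoiseProfile":
        """Default profile: C>T at CpG (and its G>A mirror) boosted ``multiplier``-fold."""
        mult: dict[tuple[str, str], float] = {}
        for flank in BASES:
            mult[(f"{flank}CG", "T")] = multiplier  # NCG, C>T
            mult[(f"CG{flank}", "A")] = multiplier  # CGN, G>A (other-strand reading)
        return cls(
            base_rate=base_rate,
            context_multipliers=mult,
            hotspot_fraction=hotspot_fraction,
            hotspot_multiplier=hotspot_multiplier,
        )

    def rate_matrix(self) -> np.ndarray:
        """(64, 4) array of rates per (context code, alt base); ref cells are 0."""
        rates = np.full((64, 4), self.base_rate)
        for code in range(64):
            ctx = decode_context(code)
            for alt_i, alt in enumerate(BASES):
                mult = self.context_multipliers.get((ctx, alt))
                if mult is not None:
                    rates[code, alt_i] = self.base_rate * mult
        mid = np.array([(c >> 2) & 3 for c in range(64)])
        rates[np.arange(64), mid] = 0.0
        return rates


@dataclass
class CohortCloneSpec:
    """Somatic clone planting parameters.

    ``burden_slope`` is the expected number of detectable mutated clones per
    year of age (clone count per subject ~ Poisson(slope * age)); the default
    0.443/yr puts the mean at ~15.5 clones for a 35-year-old, matching the
    per-subject mutation burden such deep CD8+ panels report.  Clone VAFs are
    log-uniform on [vaf_min, vaf_max], concentrating most clones below 1%.
    """

    burden_slope: float = 0.443
    vaf_min: float = 0.002
    vaf_max: float = 0.09

    def __post_init__(self) -> None:
        if self.burden_slope <= 0:
            raise ValueError("burden_slope must be > 0")
        if not 0 < self.vaf_min <= self.vaf_max:
            raise ValueError("need 0 < vaf_min <= vaf_max")
        if self.vaf_max >= 0.35:
            raise ValueError(
                f"clone VAF {self.vaf_max} >= 0.35 would collide with the germline band"
            )


@dataclass
class TruthSet:
    """Planted variants and the generating parameters of one simulated cohort."""

    germline: pd.DataFrame  # subject_id chrom pos ref alt genotype pop_af
    somatic: pd.DataFrame  # subject_id chrom pos ref alt true_vaf gene consequence context sampled_alt
    noise: NoiseProfile
    seed: int

    def germline_loci(self) -> set[tuple[str, int]]:
        return set(zip(self.germline["chrom"], self.germline["pos"].astype(int)))

    def somatic_keys(self, subject_id: str | None = None) -> set[tuple[str, str, int]]:
        df = self.somatic
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
        return set(zip(df["subject_id"], df["chrom"], df["pos"].astype(int)))


@dataclass
class Cohort:
    """Everything one simulated cohort produces."""

    panel: Panel
    reference: dict[str, np.ndarray]  # chrom -> base-code array
    subjects: list[Subject]
    site_counts: dict[str, pd.DataFrame]
    candidates: dict[str, list[VariantCall]]
    truth: TruthSet
    expressed_genes: set[str]

    def all_candidates(self) -> list[VariantCall]:
        out: list[VariantCall] = []
        for s in self.subjects:
            out.extend(self.candidates[s.subject_id])
        return out


def make_panel(
    n_genes: int,
    mean_gene_length: int = 2000,
    chrom: str = "chr1",
    gap: int = 300,
    seed: int = 0,
) -> Panel:
    """A synthetic single-chromosome panel of ``n_genes`` disjoint targets."""
    rng = np.random.default_rng(seed)
    genes = []
    cursor = 1  # keep 1 bp of flank so every target base has a full 3-mer context
    for i in range(n_genes):
        length = int(rng.integers(int(0.5 * mean_gene_length), int(1.5 * mean_gene_length) + 1))
        genes.append(PanelGene(f"GENE{i + 1:04d}", [(chrom, cursor, cursor + length)]))
        cursor += length + gap
    return Panel(genes)


def simulate_reference(
    panel: Panel, cpg_fraction: float = 0.04, seed: int = 0
) -> dict[str, np.ndarray]:
    """Random reference with controllable CpG density, one array per chromosome.

    ``cpg_fraction`` is the approximate fraction of positions that start a CpG
    dinucleotide; vertebrate-genome-like values sit a few percent.
    """
    rng = np.random.default_rng(seed)
    ref: dict[str, np.ndarray] = {}
    for chrom in sorted({r[0] for g in panel.genes for r in g.regions}):
        length = max(r[2] for g in panel.genes for r in g.regions if r[0] == chrom) + 2
        seq = rng.integers(0, 4, size=length).astype(np.int8)
        # deplete the iid CpG baseline (real genomes are CpG-poor), then plant
        # CpGs to the requested density so the knob controls what it names
        cpg = np.nonzero((seq[:-1] == 1) & (seq[1:] == 2))[0]
        seq[cpg + 1] = rng.choice([0, 1, 3], size=len(cpg)).astype(np.int8)
        n_cpg = int(cpg_fraction * length)
        starts = rng.choice(length - 1, size=n_cpg, replace=False)
        seq[starts] = 1  # C
        seq[starts + 1] = 2  # G
        ref[chrom] = seq
    return ref


def simulate_age_burden(
    subject: Subject, slope: float, rng: np.random.Generator | None = None, seed: int | None = None
) -> int:
    """Number of somatic clones to plant: Poisson with an age-linear mean.

    Mirrors the age-linear accumulation of blood mutational burden; doubling
    the age doubles the expected planted clone count.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    return int(rng.poisson(slope * subject.age))


def _sample_consequences(
    rng: np.random.Generator, n: int, snv_only: bool = False
) -> np.ndarray:
    """Draw consequence labels; noise candidates are substitution-shaped only
    (substitution noise cannot masquerade as an indel call)."""
    probs = dict(CONSEQUENCE_PROBS)
    if snv_only:
        probs.pop("frameshift_indel")
        probs.pop("nonframeshift_indel")
    names = list(probs)
    weights = np.array(list(probs.values()))
    return rng.choice(names, size=n, p=weights / weights.sum())


def _indelify(ref: str, alt: str, consequence: str, rng: np.random.Generator) -> tuple[str, str]:
    """Give indel-consequence calls an indel-shaped allele pair (insertion)."""
    if consequence == "frameshift_indel":
        return ref, ref + "".join(rng.choice(list(BASES), 1))
    if consequence == "nonframeshift_indel":
        return ref, ref + "".join(rng.choice(list(BASES), 3))
    return ref, alt


def simulate_cohort(
    panel: Panel,
    n_cases: int,
    n_controls: int,
    depth_range: tuple[float, float] = (1460.0, 3534.0),
    clone_spec: CohortCloneSpec | None = None,
    noise: NoiseProfile | None = None,
    seed: int = 0,
    *,
    cpg_fraction: float = 0.04,
    pop_site_density: float = 1 / 750.0,
    maf_range: tuple[float, float] = (0.2, 0.5),
    candidate_min_alt: int = 3,
    expressed_fraction: float = 0.8,
    include_germline_in_candidates: bool = False,
    age_range: tuple[int, int] = (23, 57),
    female_fraction: float = 0.76,
    cosmic_rate_somatic: float = 0.2,
    cosmic_rate_noise: float = 0.02,
    strand_bias_fraction: float = 0.0,
    mapq_artifact_fraction: float = 0.0,
) -> Cohort:
    """Simulate per-site read counts and candidate calls for a full cohort.

    Per subject the per-site depth is Poisson around a subject median drawn
    uniformly from ``depth_range``; germline genotypes are drawn at shared
    population polymorphic sites (Hardy-Weinberg, MAF uniform in
    ``maf_range``; the resulting heterozygote density is ~1 per 1.5 kb);
    somatic clones are planted per :class:`CohortCloneSpec` with
    Binomial(depth, VAF) read sampling; and context-specific noise mismatches
    are added per site and substitution.  Candidate calls emulate an upstream
    caller: every non-germline site with an alternate allele count of at
    least ``candidate_min_alt`` is emitted (the subject's own germline sites
    are included instead when ``include_germline_in_candidates`` is set).
    Deterministic for a given seed and argument set.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    if depth_range[0] <= 0 or depth_range[1] < depth_range[0]:
        raise ValueError("depth_range must be positive and ordered")
    clone_spec = clone_spec or CohortCloneSpec()
    noise = noise if noise is not None else NoiseProfile.with_cpg_ct()
    rng = np.random.default_rng(seed)

    reference = simulate_reference(panel, cpg_fraction=cpg_fraction, seed=seed)
    chroms, pos0, gene_idx = panel.site_arrays()
    n_sites = len(pos0)
    gene_ids = np.array(panel.gene_ids, dtype=object)

    # reference base and trinucleotide context per site
    ref_codes = np.empty(n_sites, dtype=np.int64)
    ctx_codes = np.empty(n_sites, dtype=np.int64)
    for chrom in np.unique(chroms):
        m = chroms == chrom
        seq = reference[chrom]
        p = pos0[m]
        ref_codes[m] = seq[p]
        ctx_codes[m] = 16 * seq[p - 1].astype(np.int64) + 4 * seq[p] + seq[p + 1]
    base_chars = np.array(list(BASES))
    ctx_strings = np.array([decode_context(c) for c in range(64)], dtype=object)
    rate_matrix = noise.rate_matrix()
    site_rates = rate_matrix[ctx_codes]  # (n_sites, 4)
    if noise.hotspot_fraction > 0:
        # cohort-shared hotspots among multiplier-boosted cells (sequence-
        # determined damage propensity)
        boosted = site_rates > noise.base_rate
        hot_site = rng.random(n_sites) < noise.hotspot_fraction
        site_rates = site_rates.copy()
        site_rates[boosted & hot_site[:, None]] *= noise.hotspot_multiplier

    # shared population polymorphic sites
    n_pop = int(round(n_sites * pop_site_density))
    pop_idx = np.sort(rng.choice(n_sites, size=n_pop, replace=False))
    pop_maf = rng.uniform(*maf_range, size=n_pop)
    pop_alt = (ref_codes[pop_idx] + rng.integers(1, 4, size=n_pop)) % 4
    pop_lookup = {int(i): j for j, i in enumerate(pop_idx)}

    # subjects
    subjects: list[Subject] = []
    for i in range(n_cases + n_controls):
        group = "case" if i < n_cases else "control"
        label = "MS" if group == "case" else "CTRL"
        subjects.append(
            Subject(
                subject_id=f"{label}-{(i % n_cases) + 1 if group == 'case' else i - n_cases + 1}",
                group=group,
                age=float(rng.integers(age_range[0], age_range[1] + 1)),
                sex="F" if rng.random() < female_fraction else "M",
                median_depth=float(rng.uniform(*depth_range)),
            )
        )

    expressed_genes = {
        g for g in panel.gene_ids if rng.random() < expressed_fraction
    }

    site_counts: dict[str, pd.DataFrame] = {}
    candidates: dict[str, list[VariantCall]] = {}
    germline_rows: list[dict] = []
    somatic_rows: list[dict] = []

    for subj in subjects:
        depth = rng.poisson(subj.median_depth, size=n_sites).astype(np.int64)
        np.maximum(depth, 1, out=depth)

        # context-specific noise mismatches
        counts = rng.binomial(depth[:, None], site_rates).astype(np.int64)

        # germline genotypes at population sites (overwrite noise at that cell)
        u = rng.random(n_pop)
        hom = u < pop_maf**2
        het = (~hom) & (u < pop_maf**2 + 2 * pop_maf * (1 - pop_maf))
        own_germline_idx: set[int] = set()
        for j in np.nonzero(hom | het)[0]:
            si = int(pop_idx[j])
            ai = int(pop_alt[j])
            gt = "hom" if hom[j] else "het"
            p_allele = 1.0 if gt == "hom" else 0.5
            counts[si, ai] = rng.binomial(depth[si], p_allele)
            own_germline_idx.add(si)
            germline_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "chrom": chroms[si],
                    "pos": int(pos0[si]) + 1,
                    "ref": base_chars[ref_codes[si]],
                    "alt": base_chars[ai],
                    "genotype": gt,
                    "pop_af": float(pop_maf[j]),
                }
            )

        # somatic clones
        n_clones = simulate_age_burden(subj, clone_spec.burden_slope, rng=rng)
        free = np.setdiff1d(np.arange(n_sites), np.fromiter(own_germline_idx, dtype=np.int64, count=len(own_germline_idx)))
        clone_sites = rng.choice(free, size=min(n_clones, len(free)), replace=False)
        clone_vafs = np.exp(
            rng.uniform(np.log(clone_spec.vaf_min), np.log(clone_spec.vaf_max), size=len(clone_sites))
        )
        clone_consequences = _sample_consequences(rng, len(clone_sites))
        somatic_lookup: dict[tuple[int, int], dict] = {}
        for si, vaf, csq in zip(clone_sites, clone_vafs, clone_consequences):
            si = int(si)
            ai = int((ref_codes[si] + rng.integers(1, 4)) % 4)
            extra = int(rng.binomial(depth[si], vaf))
            counts[si, ai] += extra
            ref_b = str(base_chars[ref_codes[si]])
            alt_b = str(base_chars[ai])
            ref_allele, alt_allele = _indelify(ref_b, alt_b, csq, rng)
            rec = {
                "subject_id": subj.subject_id,
                "chrom": chroms[si],
                "pos": int(pos0[si]) + 1,
                "ref": ref_allele,
                "alt": alt_allele,
                "true_vaf": float(vaf),
                "gene": str(gene_ids[gene_idx[si]]),
                "consequence": str(csq),
                "context": str(ctx_strings[ctx_codes[si]]),
                "sampled_alt": extra,
                "cosmic": bool(rng.random() < cosmic_rate_somatic),
            }
            somatic_rows.append(rec)
            somatic_lookup[(si, ai)] = rec

        # allele conservation: ref reads absorb the remainder
        nonref_total = counts.sum(axis=1) - counts[np.arange(n_sites), ref_codes]
        counts[np.arange(n_sites), ref_codes] = 0
        overflow = nonref_total > depth
        if overflow.any():
            for si in np.nonzero(overflow)[0]:
                excess = int(nonref_total[si] - depth[si])
                top = int(np.argmax(counts[si]))
                counts[si, top] -= excess
                nonref_total[si] = depth[si]
        ref_counts = depth - nonref_total
        counts[np.arange(n_sites), ref_codes] = ref_counts

        # strand split (binomial 50/50; optional one-strand artifact injection)
        fwd = rng.binomial(counts, 0.5).astype(np.int64)
        if strand_bias_fraction > 0:
            nonref_mask = np.ones_like(counts, dtype=bool)
            nonref_mask[np.arange(n_sites), ref_codes] = False
            inject = nonref_mask & (counts > 0) & (rng.random(counts.shape) < strand_bias_fraction)
            fwd[inject] = counts[inject]

        mapq_ref = np.full(n_sites, 60.0)
        mapq_alt = np.full(n_sites, 60.0)
        if mapq_artifact_fraction > 0:
            bad = rng.random(n_sites) < mapq_artifact_fraction
            mapq_alt[bad] = 45.0

        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos0 + 1,
                "ref": base_chars[ref_codes],
                "context": ctx_strings[ctx_codes],
                "ctx_code": ctx_codes,
                "depth": depth,
                **{f"n_{b}": counts[:, i] for i, b in enumerate(BASES)},
                **{f"f_{b}": fwd[:, i] for i, b in enumerate(BASES)},
                "mapq_ref": mapq_ref,
                "mapq_alt": mapq_alt,
            }
        )
        site_counts[subj.subject_id] = df

        # caller emulation
        calls: list[VariantCall] = []
        cand_site, cand_alt = np.nonzero(counts >= candidate_min_alt)
        for si, ai in zip(cand_site, cand_alt):
            si, ai = int(si), int(ai)
            if ai == ref_codes[si]:
                continue
            if si in own_germline_idx and not include_germline_in_candidates:
                continue
            ref_b = str(base_chars[ref_codes[si]])
            alt_b = str(base_chars[ai])
            truth_rec = somatic_lookup.get((si, ai))
            if truth_rec is not None:
                csq = truth_rec["consequence"]
                ref_allele, alt_allele = truth_rec["ref"], truth_rec["alt"]
                cosmic = truth_rec["cosmic"]
            else:
                csq = str(_sample_consequences(rng, 1, snv_only=True)[0])
                ref_allele, alt_allele = ref_b, alt_b
                cosmic = bool(rng.random() < cosmic_rate_noise)
            is_snv = len(ref_allele) == 1 and len(alt_allele) == 1
            pop_j = pop_lookup.get(si)
            pop_af = float(pop_maf[pop_j]) if pop_j is not None and int(pop_alt[pop_j]) == ai else 0.0
            cadd = None
            polyphen = None
            if csq in ("nonsynonymous_SNV", "synonymous_SNV", "stopgain"):
                if rng.random() >= 0.02:  # a sliver of unclassifiable SNVs
                    cadd = float(np.round(np.clip(rng.normal(24.0, 8.0), 1.0, 50.0), 1))
                    polyphen = str(rng.choice(["D", "P", "B"], p=[0.35, 0.2, 0.45]))
            calls.append(
                VariantCall(
                    subject_id=subj.subject_id,
                    chrom=str(chroms[si]),
                    pos=int(pos0[si]) + 1,
                    ref=ref_allele,
                    alt=alt_allele,
                    depth=int(depth[si]),
                    alt_count=int(counts[si, ai]),
                    alt_fwd=int(fwd[si, ai]),
                    alt_rev=int(counts[si, ai] - fwd[si, ai]),
                    ref_fwd=int(fwd[si, ref_codes[si]]),
                    ref_rev=int(counts[si, ref_codes[si]] - fwd[si, ref_codes[si]]),
                    mean_mapq_alt=float(mapq_alt[si]),
                    mean_mapq_ref=float(mapq_ref[si]),
                    gene=str(gene_ids[gene_idx[si]]),
                    consequence=csq,
                    cadd=cadd,
                    polyphen=polyphen,
                    pop_af=pop_af,
                    cosmic=cosmic,
                    expressed_in_cd8=str(gene_ids[gene_idx[si]]) in expressed_genes,
                    context=str(ctx_strings[ctx_codes[si]]) if is_snv else None,
                )
            )
        candidates[subj.subject_id] = calls

    germline_df = pd.DataFrame(
        germline_rows,
        columns=["subject_id", "chrom", "pos", "ref", "alt", "genotype", "pop_af"],
    )
    somatic_df = pd.DataFrame(
        somatic_rows,
        columns=[
            "subject_id", "chrom", "pos", "ref", "alt", "true_vaf",
            "gene", "consequence", "context", "sampled_alt", "cosmic",
        ],
    )
    truth = TruthSet(germline=germline_df, somatic=somatic_df, noise=noise, seed=seed)
    return Cohort(
        panel=panel,
        reference=reference,
        subjects=subjects,
        site_counts=site_counts,
        candidates=candidates,
        truth=truth,
        expressed_genes=expressed_genes,
    )
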