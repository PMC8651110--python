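"""Empirical trinucleotide-context background-noise model and binomial test.

Deep targeted sequencing (>2000x) turns every systematic library-preparation
error into a potential false somatic call.  The model tabulates, per sample,
the frequency of reference-genome mismatches for each of the 192 possible
(trinucleotide context, base substitution) cells over all sequenced
coordinates outside germline variant sites.  A candidate variant is then
required to carry significantly more reads than the locus's context-specific
noise level would produce: the artifact test is the exact upper binomial tail
P(X >= alt_count) for X ~ Binomial(depth, noise_frequency).  Noisy contexts
(classically C>T/G>A at CpG, from cytosine deamination) thereby demand more
evidence without any a-priori list of error processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .seq import (
    BASES,
    N_CELLS,
    context_middle,
    decode_context,
    encode_context,
)


@dataclass
class GermlineMask:
    """Loci flagged germline in any cohort sample, keyed by (chrom, 1-based pos)."""

    loci: set[tuple[str, int]] = field(default_factory=set)

    def __contains__(self, locus: tuple[str, int]) -> bool:
        return locus in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    @classmethod
    def union(cls, masks: list["GermlineMask"]) -> "GermlineMask":
        out: set[tuple[str, int]] = set()
        for m in masks:
            out |= m.loci
        return cls(out)


class ContextNoiseModel:
    """Per-sample mismatch frequencies over the 192 (context, substitution) cells.

    Internally two (64, 4) arrays: ``mismatches[ctx, alt]`` and
    ``opportunities[ctx, alt]`` (cells where alt equals the context's middle
    base are structural zeros and not part of the 192).
    """

    def __init__(
        self,
        mismatches: np.ndarray,
        opportunities: np.ndarray,
        sample_id: str | None = None,
        n_skipped_sites: int = 0,
    ) -> None:
        if mismatches.shape != (64, 4) or opportunities.shape != (64, 4):
            raise ValueError("expected (64, 4) cell arrays")
        self.mismatches = mismatches.astype(np.int64)
        self.opportunities = opportunities.astype(np.int64)
        self.sample_id = sample_id
        self.n_skipped_sites = n_skipped_sites
        if (self.mismatches < 0).any() or (self.opportunities < 0).any():
            raise ValueError("negative cell counts")
        if (self.mismatches > self.opportunities).any():
            raise ValueError("mismatches exceed opportunities")

    # -- cell accounting ---------------------------------------------------
    def cells(self) -> pd.DataFrame:
        """All 192 cells as a tidy frame (context, substitution, counts, frequency)."""
        rows = []
        for code in range(64):
            ctx = decode_context(code)
            mid = context_middle(code)
            for alt_i, alt in enumerate(BASES):
                if alt_i == mid:
                    continue
                opp = int(self.opportunities[code, alt_i])
                mis = int(self.mismatches[code, alt_i])
                rows.append(
                    {
                        "context": ctx,
                        "substitution": f"{ctx[1]}>{alt}",
                        "mismatches": mis,
                        "opportunities": opp,
                        "frequency": mis / opp if opp > 0 else np.nan,
                    }
                )
        df = pd.DataFrame(rows)
        assert len(df) == N_CELLS
        return df

    def pooled_rate(self, ref: str, alt: str) -> float:
        """Substitution-class rate pooled over all 16 flank combinations."""
        ref_i, alt_i = BASES.index(ref), BASES.index(alt)
        codes = [c for c in range(64) if context_middle(c) == ref_i]
        mis = int(self.mismatches[codes, alt_i].sum())
        opp = int(self.opportunities[codes, alt_i].sum())
        if opp == 0:
            raise ValueError(f"no opportunities anywhere for {ref}>{alt}")
        return mis / opp if mis > 0 else 1.0 / (opp + 1)

    def rate(self, context: str, alt: str) -> float:
        """Noise frequency for one cell, with floor and pooled fallbacks.

        Zero-mismatch cells return the rule-of-one floor 1/(opportunities+1)
        so the binomial test never degenerates to an automatic pass; cells
        with zero opportunities fall back to the pooled substitution-class
        rate.  Unknown cells raise rather than silently returning zero.
        """
        code = encode_context(context)
        ref = context[1]
        if alt not in BASES or alt == ref:
            raise ValueError(f"invalid substitution {ref}>{alt} for context {context}")
        alt_i = BASES.index(alt)
        opp = int(self.opportunities[code, alt_i])
        if opp == 0:
            return self.pooled_rate(ref, alt)
        mis = int(self.mismatches[code, alt_i])
        if mis == 0:
            return 1.0 / (opp + 1)
        return mis / opp

    # -- serialisation -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.cells().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None) -> "ContextNoiseModel":
        df = pd.read_csv(path, sep="\t")
        mis = np.zeros((64, 4), dtype=np.int64)
        opp = np.zeros((64, 4), dtype=np.int64)
        for r in df.itertuples():
            code = encode_context(r.context)
            alt_i = BASES.index(r.substitution[-1])
            mis[code, alt_i] = r.mismatches
            opp[code, alt_i] = r.opportunities
        return cls(mis, opp, sample_id=sample_id)

    @classmethod
    def pool(cls, models: list["ContextNoiseModel"]) -> "ContextNoiseModel":
        """Cohort-pooled model (sums of per-sample cells); for small fixtures."""
        mis = sum(m.mismatches for m in models)
        opp = sum(m.opportunities for m in models)
        return cls(mis, opp, sample_id="pooled")


def tabulate_noise(
    site_counts: pd.DataFrame,
    mask: GermlineMask | None = None,
    sample_id: str | None = None,
) -> ContextNoiseModel:
    """Tally the 192-cell noise table from one sample's per-site read counts.

    ``site_counts`` is the table produced by the simulator (or an equivalent
    pileup summary): one row per sequenced coordinate with columns ``chrom``,
    ``pos`` (1-based), ``ref``, ``ctx_code``, ``depth`` and per-base allele
    counts ``n_A..n_T``.  For every unmasked site each non-reference allele
    count is added to the (context, ref->alt) mismatch tally and the site's
    depth to the same cell's opportunity tally.  Sites whose context contains
    a non-ACGT base carry ``ctx_code < 0`` and are skipped (counted).
    """
    if len(site_counts) == 0:
        raise ValueError("site_counts is empty")
    df = site_counts
    skip = df["ctx_code"].to_numpy() < 0
    n_skipped = int(skip.sum())
    keep = ~skip
    if mask is not None and len(mask) > 0:
        masked = np.fromiter(
            ((c, int(p)) in mask for c, p in zip(df["chrom"], df["pos"])),
            dtype=bool,
            count=len(df),
        )
        keep &= ~masked
    sub = df.loc[keep]

    ctx = sub["ctx_code"].to_numpy(np.int64)
    depth = sub["depth"].to_numpy(np.int64)
    mis = np.zeros((64, 4), dtype=np.int64)
    opp = np.zeros((64, 4), dtype=np.int64)
    mid = np.array([context_middle(c) for c in range(64)])
    site_mid = mid[ctx]
    for alt_i, base in enumerate(BASES):
        counts = sub[f"n_{base}"].to_numpy(np.int64)
        nonref = site_mid != alt_i
        np.add.at(mis[:, alt_i], ctx[nonref], counts[nonref])
        np.add.at(opp[:, alt_i], ctx[nonref], depth[nonref])
    return ContextNoiseModel(mis, opp, sample_id=sample_id, n_skipped_sites=n_skipped)


def binomial_noise_test(alt_count: int, depth: int, noise_freq: float) -> float:
    """Exact upper-tail P(X >= alt_count), X ~ Binomial(depth, noise_freq)."""
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt_count {alt_count} outside [0, {depth}]")
    if not 0.0 <= noise_freq <= 1.0:
        raise ValueError(f"noise_freq {noise_freq} outside [0, 1]")
    if alt_count == 0:
        return 1.0
    return float(stats.binom.sf(alt_count - 1, depth, noise_freq))


def noise_rate(model: ContextNoiseModel, context: str, substitution: tuple[str, str] | str) -> float:
    """Convenience lookup: frequency of a (context, ref->alt) cell.

    ``substitution`` is either an ``(ref, alt)`` pair or a ``"C>T"`` string;
    the ref must match the context's middle base.
    """
    if isinstance(substitution, str):
        ref, alt = substitution.split(">")
    else:
        ref, alt = substitution
    if context[1] != ref:
        raise ValueError(f"substitution ref {ref} does not match context {context}")
    return model.rate(context, alt)
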