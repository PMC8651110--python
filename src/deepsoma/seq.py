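"""Base and trinucleotide-context encodings shared across modules.

Contexts are strand-resolved: the 64 possible reference trinucleotides times
the 3 possible alternate alleles of the middle base give the 192
(context, substitution) cells of the noise table.  For spectrum summaries a
separate strand-collapsed 6-class encoding (C>A, C>G, C>T, T>A, T>C, T>G) is
used, folding purine-reference substitutions onto their reverse complement.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

N_CONTEXTS = 64  # trinucleotides
N_CELLS = 192  # (context, substitution) pairs

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def encode_context(ctx: str) -> int:
    """3-mer string -> integer code in [0, 64)."""
    if len(ctx) != 3:
        raise ValueError(f"context must be a 3-mer, got {ctx!r}")
    try:
        return 16 * BASE_INDEX[ctx[0]] + 4 * BASE_INDEX[ctx[1]] + BASE_INDEX[ctx[2]]
    except KeyError:
        raise ValueError(f"context {ctx!r} contains a non-ACGT base") from None


def decode_context(code: int) -> str:
    return BASES[code >> 4] + BASES[(code >> 2) & 3] + BASES[code & 3]


def context_middle(code: int) -> int:
    """Index of the reference (middle) base of an encoded context."""
    return (code >> 2) & 3


def contexts_of_base(seq_codes: np.ndarray) -> np.ndarray:
    """Vectorised context codes for interior positions of a base-code array."""
    return 16 * seq_codes[:-2] + 4 * seq_codes[1:-1] + seq_codes[2:]


def six_class(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class of a SNV."""
    if ref not in BASE_INDEX or alt not in BASE_INDEX or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "GA":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def is_cpg_context(ctx: str, alt: str) -> bool:
    """True for C>T at CpG or its reverse-complement reading (G>A after C)."""
    return (ctx[1] == "C" and ctx[2] == "G" and alt == "T") or (
        ctx[1] == "G" and ctx[0] == "C" and alt == "A"
    )
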