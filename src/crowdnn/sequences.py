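"""RNA duplex canonicalization.

A duplex is specified by two strands written 5'→3'.  Position ``i`` of the
top strand pairs with position ``n_bp - 1 - i`` of the bottom strand.  Every
pair must be Watson–Crick (A·U or G·C) unless it is explicitly declared as a
G·U wobble, in which case :func:`wobble_normalize` substitutes an effective
A·U pair before any parameter lookup (both pairs share two hydrogen bonds,
so the wobble is approximated as energetically equivalent to A·U).

Dinucleotide steps are reduced to the 10 canonical Watson–Crick
nearest-neighbor labels; a step read from the opposite strand (e.g. UG/AC)
maps to the same canonical label (CA/GU) as its forward reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: The 10 canonical propagating Watson–Crick NN stacks.  "XY/WZ" means
#: 5'-XY-3' on one strand stacked on 3'-WZ-5' of the complement.
CANONICAL_STEPS: tuple[str, ...] = (
    "AA/UU", "AU/UA", "UA/AU", "CA/GU", "GU/CA",
    "CU/GA", "GA/CU", "CG/GC", "GC/CG", "GG/CC",
)
_CANONICAL_SET = frozenset(CANONICAL_STEPS)

WOBBLE_PAIRS = {("G", "U"), ("U", "G")}
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class SequenceError(ValueError):
    """Invalid RNA sequence or duplex specification."""


def clean_rna(seq: str, *, name: str = "sequence") -> str:
    """Uppercase and validate an RNA string over {A, C, G, U}.

    DNA thymine and ambiguity codes are rejected with the offending
    position rather than silently converted.
    """
    if not seq:
        raise SequenceError(f"{name} is empty")
    out = seq.upper().replace(" ", "")
    for i, base in enumerate(out):
        if base not in COMPLEMENT:
            hint = " (this tool is RNA-only; use U, not T)" if base == "T" else ""
            raise SequenceError(
                f"{name}: invalid character {base!r} at position {i + 1}{hint}"
            )
    return out


def reverse_complement(seq: str) -> str:
    """Watson–Crick complement of an RNA string, returned 5'→3'."""
    s = clean_rna(seq)
    return "".join(COMPLEMENT[b] for b in reversed(s))


def canonical_step(top: str, bottom: str) -> str:
    """Canonical label for a stack of top 5'-XY-3' over bottom 3'-WZ-5'.

    The same physical stack can be read from either strand; the reading
    that appears in :data:`CANONICAL_STEPS` is returned.
    """
    label = f"{top}/{bottom}"
    if label in _CANONICAL_SET:
        return label
    dual = f"{bottom[::-1]}/{top[::-1]}"
    if dual in _CANONICAL_SET:
        return dual
    raise SequenceError(f"not a Watson-Crick stack: {label}")


@dataclass(frozen=True)
class DuplexSpec:
    """A fully base-paired RNA duplex (blunt ends, no gaps).

    Parameters
    ----------
    top_strand, bottom_strand:
        Both 5'→3'.  ``bottom_strand`` defaults to the reverse complement
        of ``top_strand``.
    wobble_positions:
        0-based pair indices (along the top strand) held by G·U wobbles.
    """

    top_strand: str
    bottom_strand: str = ""
    wobble_positions: tuple[int, ...] = ()
    record_id: str | None = None
    #: pair indices that were G·U before wobble normalization (set on the
    #: effective duplex returned by :func:`wobble_normalize`, for reporting)
    normalized_wobbles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        top = clean_rna(self.top_strand, name="top strand")
        object.__setattr__(self, "top_strand", top)
        bottom = (
            clean_rna(self.bottom_strand, name="bottom strand")
            if self.bottom_strand
            else reverse_complement(top)
        )
        object.__setattr__(self, "bottom_strand", bottom)
        if len(bottom) != len(top):
            raise SequenceError(
                f"strand lengths differ: {len(top)} vs {len(bottom)} "
                "(only fully complementary, blunt-ended duplexes are supported)"
            )
        wob = tuple(sorted(set(self.wobble_positions)))
        object.__setattr__(self, "wobble_positions", wob)
        n = len(top)
        for i in range(n):
            pair = (top[i], bottom[n - 1 - i])
            if i in wob:
                if pair not in WOBBLE_PAIRS:
                    raise SequenceError(
                        f"pair {i + 1} declared as G-U wobble but is "
                        f"{pair[0]}-{pair[1]}"
                    )
            elif pair not in WC_PAIRS:
                if pair in WOBBLE_PAIRS:
                    raise SequenceError(
                        f"pair {i + 1} is G-U; declare it in wobble_positions "
                        "(mismatches, bulges and dangling ends are unsupported)"
                    )
                raise SequenceError(
                    f"pair {i + 1} is {pair[0]}-{pair[1]}, not Watson-Crick "
                    "(mismatches, bulges and dangling ends are unsupported)"
                )

    @property
    def n_bp(self) -> int:
        return len(self.top_strand)

    @property
    def self_complementary(self) -> bool:
        return self.top_strand == reverse_complement(self.top_strand)

    def pair(self, i: int) -> tuple[str, str]:
        """Bases of pair ``i`` as (top base, bottom base)."""
        return self.top_strand[i], self.bottom_strand[self.n_bp - 1 - i]


def from_strands(
    top: str,
    bottom: str | None = None,
    *,
    wobble: str | tuple[int, ...] = (),
    record_id: str | None = None,
) -> DuplexSpec:
    """Build a :class:`DuplexSpec`; ``wobble="auto"`` detects G·U pairs."""
    b = bottom if bottom is not None else ""
    if wobble == "auto":
        probe = clean_rna(top)
        pb = clean_rna(b) if b else reverse_complement(probe)
        n = len(probe)
        if len(pb) != n:
            raise SequenceError("strand lengths differ")
        wob = tuple(
            i for i in range(n) if (probe[i], pb[n - 1 - i]) in WOBBLE_PAIRS
        )
    else:
        wob = tuple(wobble)  # type: ignore[arg-type]
    return DuplexSpec(top, b, wob, record_id)


def wobble_normalize(duplex: DuplexSpec) -> DuplexSpec:
    """Effective duplex with each G·U pair replaced by A·U.

    The G of the wobble becomes A on whichever strand carries it; the U is
    untouched.  The original wobble positions are preserved on the output
    (``normalized_wobbles``) so reports can still flag them.  Identity for
    duplexes without wobbles.
    """
    if not duplex.wobble_positions:
        return duplex
    top = list(duplex.top_strand)
    bottom = list(duplex.bottom_strand)
    n = duplex.n_bp
    for i in duplex.wobble_positions:
        if top[i] == "G":
            top[i] = "A"
        else:
            bottom[n - 1 - i] = "A"
    return DuplexSpec(
        "".join(top),
        "".join(bottom),
        (),
        duplex.record_id,
        normalized_wobbles=duplex.wobble_positions,
    )


def nn_steps(duplex: DuplexSpec) -> list[str]:
    """Canonical NN labels of the ``n_bp − 1`` stacks, 5'→3' along the top.

    G·U wobbles are normalized to A·U before canonicalization.
    """
    if duplex.n_bp < 2:
        raise SequenceError("need at least 2 base pairs for an NN step")
    d = wobble_normalize(duplex)
    n = d.n_bp
    # bottom bases under top[i], top[i+1] read 3'->5' left to right
    return [
        canonical_step(
            d.top_strand[i : i + 2], d.bottom_strand[n - 2 - i : n - i][::-1]
        )
        for i in range(n - 1)
    ]


def count_terminal_au(duplex: DuplexSpec) -> int:
    """Number of duplex ends (0–2) closed by an A·U pair.

    A terminal G·U counts after wobble normalization (it carries the same
    two hydrogen bonds as A·U).
    """
    d = wobble_normalize(duplex)
    au = {("A", "U"), ("U", "A")}
    return int(d.pair(0) in au) + int(d.pair(d.n_bp - 1) in au)


def read_fasta(path: str | Path) -> Iterator[DuplexSpec]:
    """Yield one duplex per FASTA record (bottom strand = reverse complement)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield from_strands(str(rec.seq), record_id=rec.id)
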