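"""Reference Y RNA model, coordinate conventions, and variant-library enumeration.

Coordinates are 1-based and inclusive throughout; a cleavage site is named by the
"cut-after" position i, meaning scission between nucleotides i and i+1.

The packaged default reference is a SYNTHETIC 81-nt Y RNA-like sequence (the true
human RNY5 sequence can be supplied via FASTA).  It is constructed so that:

* a cut after position 49 yields a 32-nt 3' fragment (the modal 3' ysRNA size),
* positions 22-26 read UGGGU (the 5' cleavage motif, inside loop L2b),
* position 8 pairs with position 68 as C:G next to an unpaired cytidine bulge at
  position 9 (the RO60 binding site),
* a GC-rich 6-bp stem S3 starts at position 52, directly downstream of the 9-nt
  internal loop L2a (positions 43-51),
* six randomized 5-nt windows L1..L6 cover the stem S3 strand, the 3' tail, the
  RO60 pairing partner, and the 5' motif region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "RNA_ALPHABET",
    "ReferenceRNA",
    "RandomizedWindow",
    "VariantLibrary",
    "normalize_rna",
    "load_reference",
    "default_reference",
    "default_windows",
    "enumerate_variants",
    "variant_ordinal",
    "ordinal_to_motif",
    "apply_motif",
    "window_slice",
    "write_library_fasta",
    "WT_SEQUENCE",
    "WT_DOTBRACKET",
    "WT_LANDMARKS",
]

RNA_ALPHABET = "ACGU"
_BASE_ORD = {b: i for i, b in enumerate(RNA_ALPHABET)}

# maximum randomized-window width: 4**8 = 65,536 variants
MAX_WINDOW_K = 8

# --- packaged synthetic reference (see module docstring) --------------------

WT_SEQUENCE = (
    "GGCUACGCCG"  # 1-10
    "UGACGUGGUU"  # 11-20
    "GUGGGUUAUA"  # 21-30
    "CAACCACGUC"  # 31-40
    "ACAAUCACUC"  # 41-50
    "CGGCGCCAAU"  # 51-60
    "GGCGCCAGCG"  # 61-70
    "UAGCCUUUUUU"  # 71-81
)

# curated reference secondary structure (hand-built; not necessarily the
# base-pair-maximizing fold) with stem S3 = 52-57 : 61-66
WT_DOTBRACKET = (
    "((((((((" "." "(((((((((((("
    "........."
    "))))))))))))" "........."
    "((((((" "..." "))))))" "."
    "))))))))" "......"
)

WT_LANDMARKS: dict[str, object] = {
    "ro60_pair": (8, 68),
    "ro60_bulge_pos": 9,
    "cut3_region": (49, 51),
    "cut5_region": (32, 33),
    "motif5_window": (22, 26),
    "loop_L2a_span": (43, 51),
    "loop_L2b_span": (23, 26),
    "stem_S3_span": (52, 57),
}

_DEFAULT_WINDOWS: dict[str, tuple[int, int]] = {
    # name -> (1-based start, width)
    "L1": (52, 5),  # stem S3 5' strand (3' pool; structure-sensitive)
    "L2": (76, 5),  # 3' single-stranded tail (3' pool; structure-neutral)
    "L3": (64, 5),  # spans the RO60 pairing partner at position 68
    "L4": (22, 5),  # the UGGGU motif window
    "L5": (27, 5),  # downstream of the motif (wild type starts UAU)
    "L6": (17, 5),  # upstream of the motif
}


class ReferenceError(ValueError):
    """Malformed reference sequence or landmark configuration."""


def normalize_rna(seq: str) -> str:
    """Uppercase, convert T to U, and reject any non-ACGU character."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ReferenceError(f"non-ACGTU character(s) in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class ReferenceRNA:
    """A reference Y RNA with named 1-based landmark coordinates."""

    id: str
    sequence: str
    landmarks: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError("empty reference sequence")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        n = len(self.sequence)
        for name, value in self.landmarks.items():
            coords = value if isinstance(value, (tuple, list)) else (value,)
            for c in coords:
                if not (1 <= int(c) <= n):
                    raise ReferenceError(
                        f"landmark {name}={value} outside sequence of length {n}"
                    )
            if len(coords) == 2 and coords[0] > coords[1]:
                raise ReferenceError(f"landmark span {name}={value} has start > end")

    def __len__(self) -> int:
        return len(self.sequence)

    def landmark(self, name: str):
        try:
            return self.landmarks[name]
        except KeyError:
            raise ReferenceError(f"landmark {name!r} not defined") from None


@dataclass(frozen=True)
class RandomizedWindow:
    """A k-nt window substituted by all 4^k motifs (1-based, inclusive)."""

    name: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ReferenceError("window length must be >= 1")
        if self.length > MAX_WINDOW_K:
            raise ReferenceError(
                f"window length {self.length} exceeds enumeration bound {MAX_WINDOW_K}"
            )
        if self.start < 1:
            raise ReferenceError("window start must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def check_fits(self, reference: ReferenceRNA) -> None:
        if self.end > len(reference):
            raise ReferenceError(
                f"window {self.name} ({self.start}..{self.end}) outside reference "
                f"of length {len(reference)}"
            )


def variant_ordinal(motif: str) -> int:
    """Base-4 value of a motif with A=0, C=1, G=2, U=3.

    Lexicographic order of motifs (A<C<G<U) equals numeric order of ordinals.
    """
    value = 0
    for b in motif:
        try:
            value = value * 4 + _BASE_ORD[b]
        except KeyError:
            raise ReferenceError(f"invalid motif character {b!r}") from None
    return value


def ordinal_to_motif(ordinal: int, k: int) -> str:
    """Inverse of :func:`variant_ordinal` for a k-mer."""
    if not (0 <= ordinal < 4**k):
        raise ReferenceError(f"ordinal {ordinal} out of range for k={k}")
    bases = []
    for _ in range(k):
        ordinal, r = divmod(ordinal, 4)
        bases.append(RNA_ALPHABET[r])
    return "".join(reversed(bases))


def window_slice(sequence: str, window: RandomizedWindow) -> str:
    """Content of the randomized window within a full-length sequence."""
    return sequence[window.start - 1 : window.end]


def apply_motif(reference: ReferenceRNA, window: RandomizedWindow, motif: str) -> str:
    """Full-length variant sequence with `motif` substituted into the window."""
    if len(motif) != window.length:
        raise ReferenceError("motif length does not match window")
    s = reference.sequence
    return s[: window.start - 1] + normalize_rna(motif) + s[window.end :]


@dataclass(frozen=True)
class VariantLibrary:
    """All 4^k variants of a reference for one randomized window.

    Variants are ordered lexicographically (A<C<G<U), so the list index of a
    variant equals its :func:`variant_ordinal`.
    """

    reference: ReferenceRNA
    window: RandomizedWindow
    variants: tuple[tuple[str, str], ...]  # (motif, full_sequence)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def k(self) -> int:
        return self.window.length

    def motif(self, ordinal: int) -> str:
        return self.variants[ordinal][0]

    def sequence(self, ordinal: int) -> str:
        return self.variants[ordinal][1]

    @property
    def wildtype_ordinal(self) -> int:
        return variant_ordinal(window_slice(self.reference.sequence, self.window))

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.variants)


def enumerate_variants(
    reference: ReferenceRNA, window: RandomizedWindow
) -> VariantLibrary:
    """Enumerate all 4^k window substitutions of the reference, in
    lexicographic motif order (a 5-nt window yields 1,024 variants)."""
    window.check_fits(reference)
    k = window.length
    variants = tuple(
        (m, apply_motif(reference, window, m))
        for m in (ordinal_to_motif(i, k) for i in range(4**k))
    )
    return VariantLibrary(reference=reference, window=window, variants=variants)


# --- I/O ---------------------------------------------------------------------


def load_reference(
    source: str | None = None,
    *,
    sequence: str | None = None,
    id: str = "reference",
    landmarks: Mapping[str, object] | None = None,
) -> ReferenceRNA:
    """Build a ReferenceRNA from a FASTA file path or an inline sequence.

    T is converted to U and lowercase is folded; landmark coordinates are
    validated against the sequence length.
    """
    if (source is None) == (sequence is None):
        raise ReferenceError("provide exactly one of a FASTA path or an inline sequence")
    if source is not None:
        from Bio import SeqIO

        records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise ReferenceError(f"no FASTA records in {source}")
        rec = records[0]
        return ReferenceRNA(id=rec.id, sequence=str(rec.seq), landmarks=dict(landmarks or {}))
    return ReferenceRNA(id=id, sequence=sequence, landmarks=dict(landmarks or {}))


def default_reference() -> ReferenceRNA:
    """The packaged synthetic 81-nt Y RNA-like reference with its landmarks."""
    return ReferenceRNA(id="synthetic_yrna_81", sequence=WT_SEQUENCE, landmarks=dict(WT_LANDMARKS))


def default_windows() -> dict[str, RandomizedWindow]:
    """The six packaged 5-nt randomized windows (L1..L6)."""
    return {
        name: RandomizedWindow(name=name, start=start, length=k)
        for name, (start, k) in _DEFAULT_WINDOWS.items()
    }


def write_library_fasta(library: VariantLibrary, path: str) -> None:
    """Export a variant library as FASTA (headers: pool name + motif)."""
    with open(path, "w") as fh:
        for motif, seq in library:
            fh.write(f">{library.window.name}_{motif}\n{seq}\n")
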