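"""RNA secondary structure: folding, dot-bracket parsing, and cleavage geometry.

Folding is a weighted Nussinov base-pair maximization (GC=3, AU=2, GU=1, minimum
hairpin loop 3) — a deliberately simple, exhaustively testable stand-in for a
thermodynamic folder.  All downstream feature extraction is folder-agnostic:
curated or externally predicted structures can be supplied as dot-bracket text
(Vienna-style plain records) and flow through the same element parser.

Conventions
-----------
* positions are 1-based; pair tables map position -> partner (0 = unpaired);
* a stem is a maximal helix with zero interior unpaired nucleotides (a 1-bp
  helix counts as a stem);
* "above the stem" means 5' (upstream) of the stem's 5' strand, so a cut
  between the 2nd and 3rd nt above a stem starting at s has cut-after s-3 and
  offset 2 = number of unpaired nt strictly between the cut and the stem;
* pseudoknots and non-() bracket alphabets are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_model import normalize_rna

__all__ = [
    "SecondaryStructure",
    "StemElement",
    "LoopElement",
    "StructureError",
    "StructureRuleError",
    "DEFAULT_PAIR_WEIGHTS",
    "fold",
    "fold_score",
    "parse_elements",
    "locate_stem_S3",
    "cut_offset",
    "upstream_loop_size",
    "ro60_site_intact",
    "structure_distance",
    "read_dotbracket_file",
    "write_dotbracket_file",
]

CANONICAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}
DEFAULT_PAIR_WEIGHTS: Mapping[str, int] = {"GC": 3, "AU": 2, "GU": 1}


class StructureError(ValueError):
    """Malformed dot-bracket or sequence/structure mismatch."""


class StructureRuleError(ValueError):
    """Structure incompatible with a structural cleavage rule (e.g. no stem)."""


def _pair_weight(a: str, b: str, weights: Mapping[str, int]) -> int:
    """Weight of pairing bases a:b, 0 if not pairable."""
    p = a + b
    if p in ("GC", "CG"):
        return weights["GC"]
    if p in ("AU", "UA"):
        return weights["AU"]
    if p in ("GU", "UG"):
        return weights["GU"]
    return 0


def _parse_pair_table(dotbracket: str) -> tuple[int, ...]:
    """1-based pair table from a dot-bracket string (index 0 unused)."""
    table = [0] * (len(dotbracket) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            table[i] = pos
            table[pos] = i
        elif ch != ".":
            raise StructureError(f"unsupported character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(table)


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with a nested (pseudoknot-free) dot-bracket structure.

    ``check_pairs=False`` admits imposed/hypothetical structures whose pairs
    need not be canonical on this particular sequence (e.g. one pool-wide
    reference structure applied to every variant of a mutant pool).
    """

    sequence: str
    dotbracket: str
    check_pairs: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) != len(self.dotbracket):
            raise StructureError(
                f"sequence length {len(self.sequence)} != structure length "
                f"{len(self.dotbracket)}"
            )
        table = _parse_pair_table(self.dotbracket)
        object.__setattr__(self, "_pair_table", table)
        if self.check_pairs:
            for i, j in self.pairs():
                p = self.sequence[i - 1] + self.sequence[j - 1]
                if p not in CANONICAL_PAIRS:
                    raise StructureError(f"non-canonical pair {p} at {i}:{j}")

    @property
    def pair_table(self) -> tuple[int, ...]:
        """1-based partner table; entry 0 is unused, 0 means unpaired."""
        return self._pair_table  # type: ignore[attr-defined]

    def partner(self, i: int) -> int:
        return self.pair_table[i]

    def is_paired(self, i: int) -> bool:
        return self.pair_table[i] != 0

    def pairs(self) -> set[tuple[int, int]]:
        """Set of base pairs as (i, j) with i < j."""
        return {
            (i, j)
            for i, j in enumerate(self.pair_table[1:], start=1)
            if j > i
        }

    def __len__(self) -> int:
        return len(self.sequence)


# --- folding -----------------------------------------------------------------


def fold(
    sequence: str,
    min_hairpin: int = 3,
    pair_weights: Mapping[str, int] = DEFAULT_PAIR_WEIGHTS,
) -> SecondaryStructure:
    """Weighted Nussinov fold: maximize total pair weight over nested structures.

    Hairpin loops must contain at least ``min_hairpin`` unpaired nucleotides
    (j - i - 1 >= min_hairpin for any pair i:j).  The traceback is
    deterministic: at each decomposition step "leave i unpaired" is preferred
    when it ties the optimum, and among tying partners the smallest j wins.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    # W[i][j] = best weight on seq[i..j] (1-based, inclusive); 0 for empty
    W = [[0] * (n + 2) for _ in range(n + 2)]
    wt = [[0] * (n + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(i + min_hairpin + 1, n + 1):
            wt[i][j] = _pair_weight(seq[i - 1], seq[j - 1], pair_weights)

    for span in range(min_hairpin + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = W[i + 1][j]  # i unpaired
            row_wt = wt[i]
            row_next = W[i + 1]
            for k in range(i + min_hairpin + 1, j + 1):
                w = row_wt[k]
                if w:
                    cand = w + row_next[k - 1] + W[k + 1][j]
                    if cand > best:
                        best = cand
            W[i][j] = best

    db = ["."] * (n + 1)
    stack = [(1, n)]
    while stack:
        i, j = stack.pop()
        while i < j:
            if W[i][j] == W[i + 1][j]:
                i += 1  # prefer i unpaired on ties
                continue
            for k in range(i + min_hairpin + 1, j + 1):
                w = wt[i][k]
                if w and w + W[i + 1][k - 1] + W[k + 1][j] == W[i][j]:
                    db[i], db[k] = "(", ")"
                    stack.append((k + 1, j))
                    i, j = i + 1, k - 1
                    break
            else:  # pragma: no cover - DP/traceback consistency guard
                raise AssertionError("traceback failed")
    structure = SecondaryStructure(seq, "".join(db[1:]))
    return structure


def fold_score(
    structure: SecondaryStructure,
    pair_weights: Mapping[str, int] = DEFAULT_PAIR_WEIGHTS,
) -> int:
    """Total pair weight of a structure under the folding weights."""
    return sum(
        _pair_weight(structure.sequence[i - 1], structure.sequence[j - 1], pair_weights)
        for i, j in structure.pairs()
    )


# --- element decomposition ---------------------------------------------------


@dataclass(frozen=True)
class StemElement:
    """A maximal helix: consecutive stacked pairs with no interior bulges."""

    five_prime_span: tuple[int, int]
    three_prime_span: tuple[int, int]
    length: int
    gc_fraction: float

    @property
    def start(self) -> int:
        """First (5'-most) paired position of the 5' strand."""
        return self.five_prime_span[0]


@dataclass(frozen=True)
class LoopElement:
    """An unpaired region: hairpin, bulge, internal, multibranch or exterior."""

    kind: str  # hairpin | bulge | internal | multi | exterior
    spans: tuple[tuple[int, int], ...]
    size: int


def _stems(structure: SecondaryStructure) -> list[StemElement]:
    pt = structure.pair_table
    seq = structure.sequence
    n = len(structure)
    stems = []
    for i in range(1, n + 1):
        j = pt[i]
        if j <= i:
            continue
        # start of a stem iff (i-1, j+1) is not the stacked outer pair
        if i > 1 and j < n and pt[i - 1] == j + 1:
            continue
        length = 1
        while pt[i + length] == j - length and (i + length) < (j - length):
            length += 1
        gc = sum(
            1
            for t in range(length)
            if seq[i + t - 1] + seq[j - t - 1] in ("GC", "CG")
        )
        stems.append(
            StemElement(
                five_prime_span=(i, i + length - 1),
                three_prime_span=(j - length + 1, j),
                length=length,
                gc_fraction=gc / length,
            )
        )
    return stems


def _unpaired_runs(pt: Sequence[int], lo: int, hi: int) -> list[tuple[int, int]]:
    """Maximal unpaired runs within [lo, hi]."""
    runs = []
    i = lo
    while i <= hi:
        if pt[i] == 0:
            a = i
            while i <= hi and pt[i] == 0:
                i += 1
            runs.append((a, i - 1))
        else:
            i += 1
    return runs


def parse_elements(structure: SecondaryStructure) -> list[StemElement | LoopElement]:
    """Decompose a structure into stems and loops.

    Every position belongs to exactly one stem strand or one loop span; fully
    unpaired regions outside any pair are reported as ``exterior`` loops, and
    unpaired runs inside a multibranch junction as a single ``multi`` loop.
    """
    pt = structure.pair_table
    n = len(structure)
    elements: list[StemElement | LoopElement] = list(_stems(structure))

    # loops are anchored at the innermost pair of each stem (the helix end)
    for stem in list(elements):
        if not isinstance(stem, StemElement):  # pragma: no cover
            continue
        i = stem.five_prime_span[1]
        j = stem.three_prime_span[0]
        if j - i < 2:
            continue
        # direct branches and top-level unpaired runs inside (i, j)
        branches = []
        runs = []
        k = i + 1
        run_start = None
        while k < j:
            if pt[k] > k:
                if run_start is not None:
                    runs.append((run_start, k - 1))
                    run_start = None
                branches.append((k, pt[k]))
                k = pt[k] + 1
            else:
                if run_start is None:
                    run_start = k
                k += 1
        if run_start is not None:
            runs.append((run_start, j - 1))
        size = sum(b - a + 1 for a, b in runs)
        if not branches:
            elements.append(LoopElement("hairpin", tuple(runs), size))
        elif len(branches) == 1 and size > 0:
            kind = "internal" if len(runs) == 2 else "bulge"
            elements.append(LoopElement(kind, tuple(runs), size))
        elif size > 0:
            elements.append(LoopElement("multi", tuple(runs), size))

    # exterior: unpaired positions not enclosed by any pair
    depth = 0
    ext_runs = []
    a = None
    for pos in range(1, n + 1):
        enclosed = depth > 0
        if pt[pos] != 0:
            if pt[pos] > pos:
                depth += 1
            else:
                depth -= 1
        if pt[pos] == 0 and not enclosed:
            if a is None:
                a = pos
        else:
            if a is not None:
                ext_runs.append((a, pos - 1))
                a = None
    if a is not None:
        ext_runs.append((a, n))
    if ext_runs:
        ext_size = sum(b - a + 1 for a, b in ext_runs)
        elements.append(LoopElement("exterior", tuple(ext_runs), ext_size))
    return elements


# --- cleavage geometry -------------------------------------------------------


def locate_stem_S3(
    elements: Iterable[StemElement | LoopElement] | SecondaryStructure,
    cut3_region: tuple[int, int],
) -> StemElement:
    """The stem whose 5' strand starts closest downstream of the 3' cut region.

    Raises :class:`StructureRuleError` when no stem lies strictly downstream
    (the structure is then incompatible with the structural 3' rule).
    """
    if isinstance(elements, SecondaryStructure):
        elements = parse_elements(elements)
    candidates = [
        e
        for e in elements
        if isinstance(e, StemElement) and e.start > cut3_region[0]
    ]
    if not candidates:
        raise StructureRuleError(
            f"no stem downstream of cut region {cut3_region}: structure "
            "incompatible with the 3' cleavage rule"
        )
    return min(candidates, key=lambda e: e.start)


def cut_offset(cut_after: int, stem: StemElement) -> int:
    """Unpaired nucleotides strictly between a cut and the stem's first pair.

    A cut "between the 2nd and 3rd nt above the stem" has offset 2.
    """
    if cut_after >= stem.start:
        raise StructureRuleError(
            f"cut after {cut_after} is not upstream of stem start {stem.start}"
        )
    return stem.start - 1 - cut_after


def upstream_loop_size(structure: SecondaryStructure, stem: StemElement) -> int:
    """Length of the contiguous unpaired run ending immediately 5' of the stem."""
    pt = structure.pair_table
    size = 0
    i = stem.start - 1
    while i >= 1 and pt[i] == 0:
        size += 1
        i -= 1
    return size


def ro60_site_intact(
    structure: SecondaryStructure, landmarks: Mapping[str, object]
) -> bool:
    """True iff the RO60 anchor pair is a G:C/C:G pair and the cytidine bulge
    is present: landmark positions paired with each other, and the base at
    ``ro60_bulge_pos`` a C that is unpaired."""
    a, b = landmarks["ro60_pair"]  # type: ignore[misc]
    bulge = int(landmarks["ro60_bulge_pos"])  # type: ignore[arg-type]
    n = len(structure)
    if not (1 <= a <= n and 1 <= b <= n and 1 <= bulge <= n):
        raise StructureError("RO60 landmark positions beyond sequence length")
    pt = structure.pair_table
    seq = structure.sequence
    pair = seq[a - 1] + seq[b - 1]
    return (
        pt[a] == b
        and pair in ("GC", "CG")
        and seq[bulge - 1] == "C"
        and pt[bulge] == 0
    )


def structure_distance(s1: SecondaryStructure, s2: SecondaryStructure) -> int:
    """Base-pair distance: size of the symmetric difference of the pair sets."""
    if len(s1) != len(s2):
        raise StructureError("structures have different lengths")
    return len(s1.pairs() ^ s2.pairs())


# --- Vienna-style dot-bracket text I/O ---------------------------------------


def read_dotbracket_file(
    path: str, check_pairs: bool = True
) -> list[tuple[str, SecondaryStructure]]:
    """Read plain-text records of the form ``>name / sequence / dotbracket``."""
    records = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header at line {i + 1}")
        if i + 2 >= len(lines):
            raise StructureError(f"truncated record at line {i + 1}")
        name = lines[i][1:].strip()
        records.append(
            (name, SecondaryStructure(lines[i + 1], lines[i + 2], check_pairs=check_pairs))
        )
        i += 3
    return records


def write_dotbracket_file(
    records: Iterable[tuple[str, SecondaryStructure]], path: str
) -> None:
    with open(path, "w") as fh:
        for name, s in records:
            fh.write(f">{name}\n{s.sequence}\n{s.dotbracket}\n")
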