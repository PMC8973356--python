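"""Simulated mutant-pool sequencing: configurable cleavage rules over a variant
library, HD-adapter read layout, and FASTQ/FASTA/provenance output.

The simulator emulates the transfected-pool experiments the pipeline is built
to analyse: each read is drawn from a variant of the library (under a uniform
or Dirichlet abundance model, optionally with explicit dropout), and is either
the full-length transcript, a 3' fragment produced by the structural rule
(cut at a sampled offset above stem S3, gated on stem length, upstream loop
size and an intact RO60 site), or a 5' fragment produced by the sequence rule
(gated on the UGGGU motif at its landmark position).  3' fragments always
extend to the transcript 3' end and 5' fragments always start at position 1;
cuts are inferred downstream purely from read boundaries.

Raw reads follow the HD small-RNA library layout: 4 random nt + insert +
4 random nt + 3' adapter (TGGAATTC...), written in DNA alphabet with constant
quality.  Per-base substitution errors and a configurable fraction of decoy
reads (random inserts in the same layout, matching no variant) emulate
sequencing noise and genome-derived background.  Provenance (true variant,
fragment type, true cut) is retained in a sidecar for testing only and is
never consumed by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_model import ReferenceRNA, VariantLibrary, normalize_rna
from .structure import (
    CANONICAL_PAIRS,
    SecondaryStructure,
    StructureRuleError,
    fold,
    locate_stem_S3,
    ro60_site_intact,
    upstream_loop_size,
)

__all__ = [
    "Rule3",
    "Rule5",
    "CleavageRuleSet",
    "AbundanceModel",
    "SimulatedRead",
    "SimulatedReadSet",
    "DEFAULT_ADAPTER",
    "rule3_passes",
    "rule5_passes",
    "simulate_variant_fragments",
    "simulate_pool",
    "uniform_structures",
    "folded_structures",
    "repaired_structures",
    "shifted_stem_dotbracket",
    "loop_deletion_mutant",
    "write_fastq",
    "write_fasta",
    "write_provenance",
]

# Illumina small-RNA 3' adapter; the first 8 nt (TGGAATTC) are the trimming key
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_DNA = str.maketrans("U", "T")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Rule3:
    """Structural 3'-cleavage rule: cut a sampled number of nt above stem S3.

    A variant passes when its structure has a stem starting downstream of the
    3' cut region with at least ``stem_min_len`` pairs, the unpaired loop
    immediately upstream of that stem has at least ``require_loop_min`` nt,
    and (when required) the RO60 site is intact.

    ``gate="sequence"`` replaces the structural gate by a motif gate (a
    control condition for the structure-vs-sequence contrast): the variant
    passes iff ``seq_motif`` occurs at ``seq_motif_start``, and the cut is
    placed relative to the reference's stem_S3_span landmark.
    """

    enabled: bool = True
    offsets: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.4}
    )
    require_loop_min: int = 1
    require_ro60: bool = True
    stem_min_len: int = 5
    gate: str = "structure"
    seq_motif: str | None = None
    seq_motif_start: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.offsets.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"offset probabilities sum to {total}, not 1")
        if any(o < 0 for o in self.offsets):
            raise SimulationError("offsets must be non-negative")
        if self.gate not in ("structure", "sequence"):
            raise SimulationError(f"unknown rule3 gate {self.gate!r}")
        if self.gate == "sequence" and (
            self.seq_motif is None or self.seq_motif_start is None
        ):
            raise SimulationError("sequence gate requires seq_motif and seq_motif_start")


@dataclass(frozen=True)
class Rule5:
    """Sequence 5'-cleavage rule: requires a motif at a fixed 1-based start."""

    enabled: bool = True
    motif: str = "UGGGU"
    motif_start: int = 22
    exact_match_required: bool = True

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise SimulationError("motif must be non-empty")


@dataclass(frozen=True)
class CleavageRuleSet:
    """Simulator rule configuration; ``efficiency`` scales per-read cleavage
    probability in [0, 1] (0 emulates a cleavage-incompetent condition such as
    an Ro60 knockout)."""

    rule3: Rule3 = field(default_factory=Rule3)
    rule5: Rule5 = field(default_factory=Rule5)
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficiency <= 1.0):
            raise SimulationError("efficiency must be in [0, 1]")


@dataclass(frozen=True)
class AbundanceModel:
    """Per-variant abundance: uniform or symmetric-Dirichlet, with optional
    explicit dropout (variants at exactly zero abundance)."""

    kind: str = "uniform"
    concentration: float = 5.0
    dropout_set: frozenset[int] | None = None

    def probabilities(self, n_variants: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            p = np.full(n_variants, 1.0 / n_variants)
        elif self.kind == "dirichlet":
            if self.concentration <= 0:
                raise SimulationError("dirichlet concentration must be positive")
            p = rng.dirichlet(np.full(n_variants, self.concentration))
        else:
            raise SimulationError(f"unknown abundance kind {self.kind!r}")
        if self.dropout_set:
            drop = np.fromiter(self.dropout_set, dtype=int)
            if drop.min() < 0 or drop.max() >= n_variants:
                raise SimulationError("dropout ordinal outside library")
            p[drop] = 0.0
            total = p.sum()
            if total <= 0:
                raise SimulationError("all variants dropped out")
            p = p / total
        return p


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    raw: str  # DNA alphabet, HD 4-mer + insert + HD 4-mer + adapter
    variant_ordinal: int  # -1 for decoy reads
    fragment_type: str  # full_length | frag3 | frag5 | decoy
    cut_after: int  # 0 when not a fragment


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead]
    reference: ReferenceRNA
    adapter: str = DEFAULT_ADAPTER

    def __len__(self) -> int:
        return len(self.reads)


# --- rule evaluation ---------------------------------------------------------


def rule3_passes(
    structure: SecondaryStructure,
    rule: Rule3,
    landmarks: Mapping[str, object],
    variant_sequence: str | None = None,
) -> tuple[bool, int]:
    """Evaluate the 3' rule; returns (passes, stem_start for cut placement)."""
    if not rule.enabled:
        return False, 0
    if rule.gate == "sequence":
        stem_start = int(landmarks["stem_S3_span"][0])  # type: ignore[index]
        seq = variant_sequence if variant_sequence is not None else structure.sequence
        start = rule.seq_motif_start
        ok = seq[start - 1 : start - 1 + len(rule.seq_motif)] == rule.seq_motif
        return ok, stem_start
    try:
        stem = locate_stem_S3(structure, landmarks["cut3_region"])  # type: ignore[arg-type]
    except StructureRuleError:
        return False, 0
    if stem.length < rule.stem_min_len:
        return False, stem.start
    if upstream_loop_size(structure, stem) < rule.require_loop_min:
        return False, stem.start
    if rule.require_ro60 and not ro60_site_intact(structure, landmarks):
        return False, stem.start
    return True, stem.start


def rule5_passes(variant_sequence: str, rule: Rule5) -> bool:
    """Evaluate the 5' sequence rule on a variant sequence."""
    if not rule.enabled:
        return False
    start = rule.motif_start
    window = variant_sequence[start - 1 : start - 1 + len(rule.motif)]
    if rule.exact_match_required:
        return window == rule.motif
    # relaxed mode: allow one mismatch
    return sum(a != b for a, b in zip(window, rule.motif)) <= 1 and len(window) == len(
        rule.motif
    )


def _sample_offset(rule: Rule3, rng: np.random.Generator) -> int:
    offsets = sorted(rule.offsets)
    probs = np.array([rule.offsets[o] for o in offsets])
    return int(rng.choice(offsets, p=probs))


def simulate_variant_fragments(
    variant_sequence: str,
    structure: SecondaryStructure,
    rules: CleavageRuleSet,
    landmarks: Mapping[str, object],
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """One cleavage trial for a variant: the fragments its rules allow.

    Returns a list of (fragment_type, cut_after); an empty-rule variant yields
    only ``[("full_length", 0)]``.
    """
    out: list[tuple[str, int]] = []
    ok3, stem_start = rule3_passes(structure, rules.rule3, landmarks, variant_sequence)
    if ok3:
        cut = stem_start - 1 - _sample_offset(rules.rule3, rng)
        if cut >= 1:
            out.append(("frag3", cut))
    if rule5_passes(variant_sequence, rules.rule5):
        cut5 = landmarks["cut5_region"][0]  # type: ignore[index]
        out.append(("frag5", int(cut5)))
    if not out:
        out.append(("full_length", 0))
    return out


# --- pool simulation ---------------------------------------------------------


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_err, replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def simulate_pool(
    library: VariantLibrary,
    structures: Sequence[SecondaryStructure],
    rules: CleavageRuleSet,
    abundance: AbundanceModel,
    depth: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    error_rate: float = 0.001,
    decoy_fraction: float = 0.05,
    frag3_prob: float = 0.4,
    frag5_prob: float = 0.3,
    hd_len: int = 4,
    adapter: str = DEFAULT_ADAPTER,
) -> SimulatedReadSet:
    """Simulate ``depth`` reads from a mutant pool.

    ``structures`` supplies one structure per variant (same order as the
    library).  For a cleavage-competent variant, each read is a 3' fragment
    with probability ``frag3_prob * efficiency``, a 5' fragment with
    ``frag5_prob * efficiency``, otherwise full length.  Reproducible for a
    fixed seed.
    """
    if depth < 0:
        raise SimulationError("depth must be >= 0")
    if len(structures) != library.n_variants:
        raise SimulationError(
            f"{len(structures)} structures for {library.n_variants} variants"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    landmarks = library.reference.landmarks
    eff = rules.efficiency

    p3 = np.zeros(library.n_variants)
    p5 = np.zeros(library.n_variants)
    stem_starts = np.zeros(library.n_variants, dtype=int)
    for v, (motif, seq) in enumerate(library):
        ok3, stem_start = rule3_passes(structures[v], rules.rule3, landmarks, seq)
        stem_starts[v] = stem_start
        if ok3:
            p3[v] = frag3_prob * eff
        if rule5_passes(seq, rules.rule5):
            p5[v] = frag5_prob * eff

    probs = abundance.probabilities(library.n_variants, rng)
    cut5 = int(landmarks["cut5_region"][0])  # type: ignore[index]

    reads: list[SimulatedRead] = []
    for i in range(depth):
        rid = f"read_{i}"
        if decoy_fraction > 0 and rng.random() < decoy_fraction:
            insert = _random_dna(int(rng.integers(25, 41)), rng)
            raw = _random_dna(hd_len, rng) + insert + _random_dna(hd_len, rng) + adapter
            reads.append(SimulatedRead(rid, _mutate(raw, error_rate, rng), -1, "decoy", 0))
            continue
        v = int(rng.choice(library.n_variants, p=probs))
        seq = library.sequence(v)
        u = rng.random()
        if u < p3[v]:
            cut = stem_starts[v] - 1 - _sample_offset(rules.rule3, rng)
            ftype, cut_after, insert_rna = "frag3", cut, seq[cut:]
        elif u < p3[v] + p5[v]:
            ftype, cut_after, insert_rna = "frag5", cut5, seq[:cut5]
        else:
            ftype, cut_after, insert_rna = "full_length", 0, seq
        raw = (
            _random_dna(hd_len, rng)
            + insert_rna.translate(_DNA)
            + _random_dna(hd_len, rng)
            + adapter
        )
        reads.append(SimulatedRead(rid, _mutate(raw, error_rate, rng), v, ftype, cut_after))
    return SimulatedReadSet(reads=reads, reference=library.reference, adapter=adapter)


# --- structure models for pools ---------------------------------------------


def uniform_structures(
    library: VariantLibrary, dotbracket: str
) -> list[SecondaryStructure]:
    """Impose one dot-bracket on every variant of a pool (pair-legality checks
    off: variant sequences need not be canonical under the shared structure)."""
    return [
        SecondaryStructure(seq, dotbracket, check_pairs=False) for _, seq in library
    ]


def folded_structures(library: VariantLibrary) -> list[SecondaryStructure]:
    """Fold each variant independently (weighted base-pair maximization)."""
    return [fold(seq) for _, seq in library]


def repaired_structures(
    library: VariantLibrary, dotbracket: str
) -> list[SecondaryStructure]:
    """Impose a reference structure per variant, dropping pairs the variant
    sequence can no longer form.

    The local-repair model for pools whose window overlaps a helix: each
    designed pair that is non-canonical under the variant's sequence becomes
    unpaired (splitting the stem), everything else keeps the reference
    geometry.  Wobble-compatible substitutions therefore change the sequence
    but not the structure — the property that lets downstream analysis
    separate structural from sequence determinants.
    """
    template = SecondaryStructure(
        library.reference.sequence, dotbracket, check_pairs=False
    )
    pairs = sorted(template.pairs())
    out = []
    for _, seq in library:
        db = list(template.dotbracket)
        for i, j in pairs:
            if seq[i - 1] + seq[j - 1] not in CANONICAL_PAIRS:
                db[i - 1] = "."
                db[j - 1] = "."
        out.append(SecondaryStructure(seq, "".join(db)))
    return out


def shifted_stem_dotbracket(reference: ReferenceRNA, dotbracket: str, shift: int) -> str:
    """Rebuild a fixture dot-bracket with stem S3 moved ``shift`` nt upstream.

    Emulates pool variants whose mutations shorten loop L2a so that the S3
    stem (and with it the cleavage site) sits further 5'; the stem keeps its
    length and hairpin loop, vacated positions become unpaired.
    """
    span = reference.landmark("stem_S3_span")
    s = SecondaryStructure(reference.sequence, dotbracket, check_pairs=False)
    start, end = int(span[0]), int(span[1])
    length = end - start + 1
    pt = s.pair_table
    db = list(dotbracket)
    # clear the existing stem
    for i in range(start, end + 1):
        j = pt[i]
        if j:
            db[i - 1] = "."
            db[j - 1] = "."
    three_start = pt[end] if pt[end] else None
    if three_start is None:
        raise StructureRuleError("stem_S3_span is not paired in the given structure")
    for t in range(length):
        db[start - shift + t - 1] = "("
        # partner of (start+t) is pt[start+t]; shift it too
        db[pt[start + t] - shift - 1] = ")"
    return "".join(db)


def loop_deletion_mutant(
    reference: ReferenceRNA, dotbracket: str, n_deleted: int
) -> tuple[ReferenceRNA, str]:
    """Delete ``n_deleted`` nt from the 5' end of internal loop L2a.

    Emulates the loop-deletion series (1..9 nt removed): the returned
    reference has the loop span, stem S3, cut regions and downstream
    landmarks re-coordinated; the structure string loses the deleted
    (unpaired) positions.  The 3' cut region is re-anchored to the 3 nt
    directly upstream of the shifted stem.
    """
    loop = reference.landmark("loop_L2a_span")
    lo, hi = int(loop[0]), int(loop[1])
    loop_size = hi - lo + 1
    if not (0 <= n_deleted <= loop_size):
        raise SimulationError(f"cannot delete {n_deleted} nt from a {loop_size}-nt loop")
    if n_deleted == 0:
        return reference, dotbracket
    cut_positions = set(range(lo, lo + n_deleted))
    seq = "".join(
        b for i, b in enumerate(reference.sequence, start=1) if i not in cut_positions
    )
    db = "".join(
        c for i, c in enumerate(dotbracket, start=1) if i not in cut_positions
    )

    def _shift(pos: int) -> int:
        return pos - n_deleted if pos >= lo + n_deleted else pos

    d = n_deleted
    landmarks: dict[str, object] = {}
    for name, value in reference.landmarks.items():
        if name == "loop_L2a_span":
            if loop_size - d >= 1:
                landmarks[name] = (lo, hi - d)
            continue
        if name == "cut3_region":
            stem_start = _shift(int(reference.landmark("stem_S3_span")[0]))
            landmarks[name] = (stem_start - 3, stem_start - 1)
            continue
        if isinstance(value, (tuple, list)):
            landmarks[name] = tuple(_shift(int(c)) for c in value)
        else:
            landmarks[name] = _shift(int(value))
    ref = ReferenceRNA(
        id=f"{reference.id}_L2a_del{d}", sequence=seq, landmarks=landmarks
    )
    return ref, db


# --- output ------------------------------------------------------------------


def write_fastq(read_set: SimulatedReadSet, path: str, quality_char: str = "I") -> None:
    """Standard 4-line FASTQ with constant quality."""
    with open(path, "w") as fh:
        for r in read_set.reads:
            fh.write(f"@{r.read_id}\n{r.raw}\n+\n{quality_char * len(r.raw)}\n")


def write_fasta(read_set: SimulatedReadSet, path: str) -> None:
    with open(path, "w") as fh:
        for r in read_set.reads:
            fh.write(f">{r.read_id}\n{r.raw}\n")


def write_provenance(read_set: SimulatedReadSet, path: str) -> None:
    """Testing-only sidecar: true variant, fragment type and cut per read."""
    with open(path, "w") as fh:
        fh.write("read_id\tvariant_ordinal\tfragment_type\tcut_after\n")
        for r in read_set.reads:
            fh.write(f"{r.read_id}\t{r.variant_ordinal}\t{r.fragment_type}\t{r.cut_after}\n")
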