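"""Demultiplexing trimmed reads to pool variants and cleavage-site inference.

Matching is exact (no mismatches): a read is matched to the reference with the
randomized window treated as free positions, anchored as full-length (read ==
whole transcript), 5' fragment (read starts at position 1) or 3' fragment
(read ends at the transcript 3' end), in that precedence order.  A read whose
span covers the randomized window determines its variant uniquely (the window
bases are read off directly); reads matching the pool but not covering the
window are tallied pool-level rather than fractionally distributed; everything
else is unassigned.

Cut positions are inferred purely from read boundaries in cut-after
coordinates: a 3' fragment of length n on a reference of length L implies a
cut after position L - n; a 5' fragment of length n implies a cut after n.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import VariantLibrary, variant_ordinal
from .read_processing import TrimmedRead

__all__ = [
    "AssignmentTable",
    "NoCleavageError",
    "assign_reads",
    "size_distribution",
    "infer_cut_positions",
    "write_assignment_tsv",
]

FULL = "full_length"
FRAG3 = "frag3"
FRAG5 = "frag5"


class NoCleavageError(ValueError):
    """No fragment reads present where a cleavage signal is required."""


@dataclass
class AssignmentTable:
    """Per-variant read counts stratified by fragment class and cut position."""

    n_variants: int
    reference_length: int
    window_span: tuple[int, int]
    full_length: np.ndarray = field(default=None)  # type: ignore[assignment]
    frag3: dict[int, Counter] = field(default_factory=dict)  # v -> {(len, cut): n}
    frag5: dict[int, Counter] = field(default_factory=dict)
    pool_level: Counter = field(default_factory=Counter)  # (ftype, len, cut) -> n
    unassigned_count: int = 0
    accepted_total: int = 0
    prefix_suffix_flags: int = 0  # reads that matched both ends (degenerate refs)

    def __post_init__(self) -> None:
        if self.full_length is None:
            self.full_length = np.zeros(self.n_variants, dtype=np.int64)

    # -- totals ---------------------------------------------------------------

    def frag3_count(self, v: int) -> int:
        return sum(self.frag3.get(v, Counter()).values())

    def frag5_count(self, v: int) -> int:
        return sum(self.frag5.get(v, Counter()).values())

    def full_length_count(self, v: int) -> int:
        return int(self.full_length[v])

    @property
    def pool_level_total(self) -> int:
        return sum(self.pool_level.values())

    @property
    def assigned_total(self) -> int:
        return (
            int(self.full_length.sum())
            + sum(self.frag3_count(v) for v in self.frag3)
            + sum(self.frag5_count(v) for v in self.frag5)
        )

    def check_conservation(self) -> None:
        """Exact reconciliation: assigned + pool-level + unassigned = accepted."""
        total = self.assigned_total + self.pool_level_total + self.unassigned_count
        if total != self.accepted_total:
            raise AssertionError(
                f"count conservation violated: {total} != {self.accepted_total}"
            )

    def metric(self, name: str) -> np.ndarray:
        """Per-variant counts for a named metric."""
        if name == "full_length_count":
            return self.full_length.copy()
        if name == "frag3_count":
            return np.array([self.frag3_count(v) for v in range(self.n_variants)])
        if name == "frag5_count":
            return np.array([self.frag5_count(v) for v in range(self.n_variants)])
        raise KeyError(f"unknown metric {name!r}")


def _match_window_free(
    read: str, ref: str, offset: int, ws: int, we: int
) -> str | None:
    """Match `read` against `ref` at 0-based ``offset`` with window positions
    (1-based ws..we) free.  Returns the observed window content ('' if the
    window is not fully covered) or None on mismatch."""
    window_bases = []
    for p, base in enumerate(read):
        g = offset + p + 1
        if ws <= g <= we:
            window_bases.append(base)
        elif base != ref[g - 1]:
            return None
    if offset + 1 <= ws and we <= offset + len(read):
        return "".join(window_bases)
    return ""


def assign_reads(
    reads: Iterable[TrimmedRead | str], library: VariantLibrary
) -> AssignmentTable:
    """Assign trimmed inserts to variants of one pool.

    Accepts TrimmedRead objects or plain insert strings.  Reads that match the
    pool at an internal offset (neither boundary) cannot carry a fragment
    class and are tallied pool-level.
    """
    ref = library.reference.sequence
    L = len(ref)
    w = library.window
    ws, we = w.start, w.end
    table = AssignmentTable(
        n_variants=library.n_variants,
        reference_length=L,
        window_span=(ws, we),
    )

    for item in reads:
        insert = item.insert if isinstance(item, TrimmedRead) else item
        table.accepted_total += 1
        n = len(insert)
        if n > L or n == 0:
            table.unassigned_count += 1
            continue

        if n == L:
            motif = _match_window_free(insert, ref, 0, ws, we)
            if motif:  # full-length reads always cover the window
                v = variant_ordinal(motif)
                table.full_length[v] += 1
                continue
            table.unassigned_count += 1
            continue

        as_prefix = _match_window_free(insert, ref, 0, ws, we)
        as_suffix = _match_window_free(insert, ref, L - n, ws, we)
        if as_prefix is not None and as_suffix is not None:
            table.prefix_suffix_flags += 1  # frag5 takes precedence
        if as_prefix is not None:
            cut_after = n
            if as_prefix:
                v = variant_ordinal(as_prefix)
                table.frag5.setdefault(v, Counter())[(n, cut_after)] += 1
            else:
                table.pool_level[(FRAG5, n, cut_after)] += 1
            continue
        if as_suffix is not None:
            cut_after = L - n
            if as_suffix:
                v = variant_ordinal(as_suffix)
                table.frag3.setdefault(v, Counter())[(n, cut_after)] += 1
            else:
                table.pool_level[(FRAG3, n, cut_after)] += 1
            continue

        # internal (boundary-free) matches carry no fragment class
        internal = False
        for offset in range(1, L - n):
            if _match_window_free(insert, ref, offset, ws, we) is not None:
                internal = True
                break
        if internal:
            table.pool_level[("internal", n, 0)] += 1
        else:
            table.unassigned_count += 1

    table.check_conservation()
    return table


def size_distribution(
    table: AssignmentTable,
    length_range: tuple[int, int] = (25, 35),
    which: str = FRAG3,
) -> pd.Series:
    """Percentage of fragment reads at each length within ``length_range``,
    with underflow/overflow bins; sums to 100 when any fragment reads exist.

    ``which`` is ``frag3``, ``frag5`` or ``both`` (percentages are always over
    the selected fragment reads only, never full-length reads)."""
    lo, hi = length_range
    counters: list[dict[int, Counter]] = []
    if which in (FRAG3, "both"):
        counters.append(table.frag3)
    if which in (FRAG5, "both"):
        counters.append(table.frag5)
    if not counters:
        raise KeyError(f"unknown fragment class {which!r}")

    lengths: Counter = Counter()
    for per_variant in counters:
        for cnt in per_variant.values():
            for (length, _cut), n in cnt.items():
                lengths[length] += n
        # pool-level fragments participate: they have a defined length
    for (ftype, length, _cut), n in table.pool_level.items():
        if (which == "both" and ftype in (FRAG3, FRAG5)) or ftype == which:
            lengths[length] += n

    index = [f"<{lo}"] + list(range(lo, hi + 1)) + [f">{hi}"]
    counts = pd.Series(0.0, index=index)
    for length, n in lengths.items():
        if length < lo:
            counts[f"<{lo}"] += n
        elif length > hi:
            counts[f">{hi}"] += n
        else:
            counts[length] += n
    total = counts.sum()
    if total == 0:
        return counts  # all-zero row: flagged by the caller via .sum() == 0
    return 100.0 * counts / total


def infer_cut_positions(
    table: AssignmentTable,
    which: str = FRAG3,
    variant: int | None = None,
    include_pool_level: bool = True,
) -> tuple[Counter, int]:
    """Histogram of inferred cut-after positions and the modal cut.

    Pools over all variants unless ``variant`` is given.  Ties on the mode are
    broken toward the smaller position.  Raises :class:`NoCleavageError` when
    no fragment reads of the requested class exist.
    """
    if which not in (FRAG3, FRAG5):
        raise KeyError(f"unknown fragment class {which!r}")
    per_variant = table.frag3 if which == FRAG3 else table.frag5
    hist: Counter = Counter()
    variants = [variant] if variant is not None else list(per_variant)
    for v in variants:
        for (_length, cut), n in per_variant.get(v, Counter()).items():
            hist[cut] += n
    if include_pool_level and variant is None:
        for (ftype, _length, cut), n in table.pool_level.items():
            if ftype == which:
                hist[cut] += n
    if not hist:
        raise NoCleavageError(f"no {which} reads: no cleavage signal")
    modal = min(sorted(hist), key=lambda c: (-hist[c], c))
    return hist, modal


def write_assignment_tsv(
    table: AssignmentTable, library: VariantLibrary, path: str
) -> None:
    """Long-format TSV: one row per (variant, category, length, cut) counter."""
    rows = []
    for v in range(table.n_variants):
        motif = library.motif(v)
        if table.full_length[v]:
            rows.append((v, motif, FULL, table.reference_length, 0, int(table.full_length[v])))
        for (length, cut), n in sorted(table.frag3.get(v, Counter()).items()):
            rows.append((v, motif, FRAG3, length, cut, n))
        for (length, cut), n in sorted(table.frag5.get(v, Counter()).items()):
            rows.append((v, motif, FRAG5, length, cut, n))
    for (ftype, length, cut), n in sorted(table.pool_level.items()):
        rows.append((-1, "pool", ftype, length, cut, n))
    rows.append((-1, "unassigned", "unassigned", 0, 0, table.unassigned_count))
    df = pd.DataFrame(
        rows, columns=["ordinal", "motif", "category", "length", "cut_after", "count"]
    )
    df.to_csv(path, sep="\t", index=False)
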