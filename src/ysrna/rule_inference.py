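"""Recovery of cleavage rules from assignment tables plus structures.

Four analyses mirror the mutant-pool experiments:

* ``recover_offset`` — where does the 3' cut sit relative to stem S3?  Each 3'
  fragment read implies a cut-after position; its offset is the number of
  unpaired nt between the cut and the stem's first pair.  The pooled histogram
  and its mode recover the structural rule (modal offset 2 = cleavage between
  the 2nd and 3rd nt above the stem).
* ``loop_length_response`` — fragment yield as a function of the size of the
  internal loop upstream of S3, over a deletion series; the smallest loop that
  still yields fragments is the minimal permissive size (1 nt under the
  default rule: a bulge of at least 1 nt suffices).
* ``localize_motif`` — per-position information-content difference between
  cleavage-competent and incompetent variant motifs localizes a sequence
  requirement (the UGGGU motif for 5' cleavage).
* ``structure_vs_sequence_report`` — Spearman rank association of per-variant
  fragment yield with structural similarity to wild type versus with window
  sequence similarity; a structural cleavage rule makes the former dominate.

Yield is measured as fragment reads / (fragment + full-length reads) per
variant, undefined when the denominator is zero.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import FRAG3, FRAG5, AssignmentTable, NoCleavageError
from .core_model import VariantLibrary, window_slice
from .structure import (
    SecondaryStructure,
    StructureRuleError,
    cut_offset,
    locate_stem_S3,
    structure_distance,
)
from .enrichment import pwm_logo

__all__ = [
    "MotifCall",
    "RuleReport",
    "variant_yields",
    "recover_offset",
    "loop_length_response",
    "localize_motif",
    "competent_split",
    "structure_vs_sequence_report",
]


@dataclass(frozen=True)
class MotifCall:
    """A localized sequence requirement: reference start coordinate, consensus
    among competent variants, and per-position IC difference (competent minus
    incompetent, bits)."""

    start: int | None
    consensus: str
    ic_difference: tuple[float, ...]

    @property
    def called(self) -> bool:
        return self.start is not None


@dataclass
class RuleReport:
    """Aggregate rule-recovery report for one pool/series."""

    modal_offset: int | None = None
    offset_histogram: dict[int, int] = field(default_factory=dict)
    loop_response: dict[int, float] = field(default_factory=dict)
    minimal_permissive_loop: int | None = None
    motif_call: MotifCall | None = None
    structure_assoc: float | None = None
    sequence_assoc: float | None = None
    degenerate: bool = False

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "modal_offset": self.modal_offset,
            "offset_histogram": {str(k): v for k, v in sorted(self.offset_histogram.items())},
            "loop_response": {str(k): v for k, v in sorted(self.loop_response.items())},
            "minimal_permissive_loop": self.minimal_permissive_loop,
            "motif_call": None
            if self.motif_call is None
            else {
                "start": self.motif_call.start,
                "consensus": self.motif_call.consensus,
                "ic_difference": list(self.motif_call.ic_difference),
            },
            "structure_assoc": self.structure_assoc,
            "sequence_assoc": self.sequence_assoc,
            "degenerate": self.degenerate,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# --- yields ------------------------------------------------------------------


def variant_yields(table: AssignmentTable, which: str = FRAG3) -> np.ndarray:
    """Per-variant fragment yield: frag / (frag + full_length); NaN where the
    denominator is zero."""
    frag = table.metric(f"{which}_count").astype(float)
    full = table.full_length.astype(float)
    denom = frag + full
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(denom > 0, frag / denom, np.nan)
    return y


def pooled_yield(table: AssignmentTable, which: str = FRAG3) -> float:
    """Pool-level fragment yield: total frag / (total frag + total full)."""
    frag = int(table.metric(f"{which}_count").sum())
    full = int(table.full_length.sum())
    if frag + full == 0:
        return float("nan")
    return frag / (frag + full)


# --- offset recovery ---------------------------------------------------------


def recover_offset(
    table: AssignmentTable,
    structures: Sequence[SecondaryStructure],
    cut3_region: tuple[int, int],
) -> tuple[int, Counter]:
    """Modal cut offset above stem S3, pooled over all variants with 3'
    fragments and a locatable stem.  Ties break toward the smaller offset."""
    hist: Counter = Counter()
    for v, counts in table.frag3.items():
        try:
            stem = locate_stem_S3(structures[v], cut3_region)
        except StructureRuleError:
            continue
        for (_length, cut), n in counts.items():
            if cut < stem.start:
                hist[cut_offset(cut, stem)] += n
    if not hist:
        raise NoCleavageError(
            "no variant has both 3' fragments and a stem downstream of the cut region"
        )
    modal = min(sorted(hist), key=lambda o: (-hist[o], o))
    return modal, hist


# --- loop-length response ----------------------------------------------------


def loop_length_response(
    series: Mapping[int, AssignmentTable | float],
    which: str = FRAG3,
) -> tuple[pd.Series, int | None]:
    """Fragment yield per loop size over a loop-deletion series.

    ``series`` maps loop size (nt) to an assignment table (pooled yield is
    computed) or directly to a yield.  Returns the response and the minimal
    permissive loop size — the smallest size with positive yield — or None
    when all yields are zero/undefined (flagged degenerate outcome).
    """
    if len(series) < 2:
        raise ValueError("loop series needs at least two distinct loop sizes")
    resp = {}
    for size, value in series.items():
        if isinstance(value, AssignmentTable):
            y = pooled_yield(value, which)
            resp[size] = 0.0 if np.isnan(y) else y
        else:
            resp[size] = float(value)
    response = pd.Series(resp).sort_index()
    permissive = [s for s, y in response.items() if y > 0]
    return response, (min(permissive) if permissive else None)


# --- motif localization ------------------------------------------------------


def localize_motif(
    competent_motifs: Sequence[str],
    incompetent_motifs: Sequence[str],
    window_start: int,
    pseudocount: float = 0.5,
) -> MotifCall:
    """Localize a sequence requirement within a randomized window.

    Computes per-position information content for the competent and
    incompetent motif sets and their difference; the call start is the
    reference coordinate of the first position whose IC difference exceeds
    half the maximum difference.  No call is made when the maximum difference
    is not positive.
    """
    if not competent_motifs or not incompetent_motifs:
        raise ValueError("both motif sets must be non-empty")
    pwm_c = pwm_logo(competent_motifs, pseudocount)
    pwm_i = pwm_logo(incompetent_motifs, pseudocount)
    if pwm_c.k != pwm_i.k:
        raise ValueError("motif sets have different lengths")
    diff = pwm_c.information_content - pwm_i.information_content
    consensus = pwm_c.consensus
    max_diff = float(diff.max())
    if max_diff <= 0:
        return MotifCall(start=None, consensus=consensus, ic_difference=tuple(diff))
    first = int(np.argmax(diff > max_diff / 2))
    return MotifCall(
        start=window_start + first,
        consensus=consensus,
        ic_difference=tuple(diff),
    )


def competent_split(
    table: AssignmentTable,
    library: VariantLibrary,
    which: str = FRAG5,
    threshold_frac: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Split variant motifs into cleavage-competent and incompetent sets.

    A variant is competent when its yield exceeds ``threshold_frac`` times the
    wild-type variant's yield (falling back to the pool maximum when the wild
    type itself has no defined or positive yield).  Variants with undefined
    yield count as incompetent.
    """
    y = variant_yields(table, which)
    wt = library.wildtype_ordinal
    ref_yield = y[wt]
    if np.isnan(ref_yield) or ref_yield <= 0:
        defined = y[~np.isnan(y)]
        ref_yield = float(defined.max()) if defined.size else 0.0
    threshold = threshold_frac * ref_yield
    competent, incompetent = [], []
    for v in range(library.n_variants):
        motif = library.motif(v)
        if not np.isnan(y[v]) and y[v] > threshold and y[v] > 0:
            competent.append(motif)
        else:
            incompetent.append(motif)
    return competent, incompetent


# --- structure vs sequence ---------------------------------------------------


def structure_vs_sequence_report(
    table: AssignmentTable,
    structures: Sequence[SecondaryStructure],
    library: VariantLibrary,
    which: str = FRAG3,
    min_defined: int = 10,
) -> RuleReport:
    """Contrast structural and sequence determinants of fragment yield.

    Spearman rank correlation of per-variant yield with (a) negated base-pair
    distance of the variant's structure to the wild-type variant's structure
    and (b) negated Hamming distance of the variant's window motif to the
    wild-type motif.  Under a structural cleavage rule (a) exceeds (b).
    """
    y = variant_yields(table, which)
    defined = ~np.isnan(y)
    if defined.sum() < min_defined:
        raise ValueError(
            f"only {int(defined.sum())} variants with defined yield (< {min_defined})"
        )
    wt = library.wildtype_ordinal
    wt_structure = structures[wt]
    wt_motif = window_slice(library.reference.sequence, library.window)

    struct_sim = np.array(
        [
            -structure_distance(structures[v], wt_structure)
            for v in range(library.n_variants)
        ],
        dtype=float,
    )
    seq_sim = np.array(
        [
            -sum(a != b for a, b in zip(library.motif(v), wt_motif))
            for v in range(library.n_variants)
        ],
        dtype=float,
    )

    report = RuleReport()
    yv = y[defined]
    if np.all(yv == yv[0]):
        report.degenerate = True
        report.structure_assoc = 0.0
        report.sequence_assoc = 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            # constant predictors yield NaN, mapped to 0 + degenerate below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho_s = stats.spearmanr(yv, struct_sim[defined]).statistic
            rho_q = stats.spearmanr(yv, seq_sim[defined]).statistic
        report.structure_assoc = 0.0 if np.isnan(rho_s) else float(rho_s)
        report.sequence_assoc = 0.0 if np.isnan(rho_q) else float(rho_q)
        report.degenerate = bool(np.isnan(rho_s) or np.isnan(rho_q))

    try:
        modal, hist = recover_offset(
            table, structures, library.reference.landmark("cut3_region")
        )
        report.modal_offset = modal
        report.offset_histogram = dict(hist)
    except NoCleavageError:
        pass
    return report
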