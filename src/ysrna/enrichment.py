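"""Variant abundance ranking, missing-variant detection, sequence logos, and
pool-coverage (coupon-collector) statistics.

The coverage statistic answers the library-construction question: how many
uniformly sampled colonies must be harvested so that any given one of the V
equally likely variants is represented at least once with probability p?
The per-variant presence probability after n draws is 1 - (1 - 1/V)^n, so the
minimum is ceil(ln(1-p) / ln(1 - 1/V)); for V = 1024 and p = 0.99 this gives
4,714 colonies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assignment import AssignmentTable
from .core_model import RNA_ALPHABET, VariantLibrary

__all__ = [
    "PositionWeightMatrix",
    "rank_variants",
    "top_k",
    "bottom_k",
    "missing_variants",
    "pwm_logo",
    "presence_probability",
    "min_pool_size",
    "write_pwm_tsv",
    "plot_logo",
]


# --- ranking and missing variants -------------------------------------------


def rank_variants(
    table: AssignmentTable,
    library: VariantLibrary,
    metric: str = "frag3_count",
) -> pd.DataFrame:
    """Variants ordered by a count metric, descending; ties break by ordinal.

    ``metric`` is ``frag3_count``, ``frag5_count`` or ``full_length_count``.
    The result carries a ``degenerate`` attribute flag when the metric is zero
    everywhere (ranking then carries no signal).
    """
    values = table.metric(metric)
    order = np.lexsort((np.arange(len(values)), -values))
    df = pd.DataFrame(
        {
            "ordinal": order,
            "motif": [library.motif(v) for v in order],
            metric: values[order],
        }
    ).reset_index(drop=True)
    df.attrs["degenerate"] = bool(values.sum() == 0)
    return df


def top_k(ranked: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """The k most abundant variants of a ranking (default 50)."""
    return ranked.head(k)


def bottom_k(ranked: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    return ranked.tail(k)


def missing_variants(table: AssignmentTable, min_count: int = 1) -> list[int]:
    """Ordinals whose full-length count falls below ``min_count``."""
    return [
        v for v in range(table.n_variants) if table.full_length_count(v) < min_count
    ]


# --- sequence logos ----------------------------------------------------------


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base frequencies (rows A,C,G,U) per motif column, with per-column
    information content in bits: IC_j = 2 + sum_b f_bj log2 f_bj."""

    frequencies: np.ndarray  # shape (4, k), columns sum to 1
    pseudocount: float
    n_motifs: int

    @property
    def k(self) -> int:
        return self.frequencies.shape[1]

    @property
    def information_content(self) -> np.ndarray:
        f = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + plogp.sum(axis=0)

    def dominant_base(self, column: int) -> tuple[str, float]:
        i = int(self.frequencies[:, column].argmax())
        return RNA_ALPHABET[i], float(self.frequencies[i, column])

    @property
    def consensus(self) -> str:
        return "".join(self.dominant_base(j)[0] for j in range(self.k))


def pwm_logo(motifs: Iterable[str], pseudocount: float = 0.5) -> PositionWeightMatrix:
    """Position weight matrix with Laplace-style pseudocount per base."""
    motifs = list(motifs)
    if not motifs:
        raise ValueError("empty motif set")
    k = len(motifs[0])
    if any(len(m) != k for m in motifs):
        raise ValueError("motifs have unequal lengths")
    counts = np.full((4, k), pseudocount, dtype=float)
    base_index = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for m in motifs:
        for j, b in enumerate(m):
            counts[base_index[b], j] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return PositionWeightMatrix(
        frequencies=freqs, pseudocount=pseudocount, n_motifs=len(motifs)
    )


def write_pwm_tsv(pwm: PositionWeightMatrix, path: str) -> None:
    """4 x k frequency matrix plus an information-content row, tab-separated."""
    df = pd.DataFrame(
        pwm.frequencies, index=list(RNA_ALPHABET), columns=range(1, pwm.k + 1)
    )
    df.loc["IC_bits"] = pwm.information_content
    df.to_csv(path, sep="\t")


def plot_logo(pwm: PositionWeightMatrix, path: str) -> None:  # pragma: no cover
    """Optional logo rendering (letter heights = IC * frequency); isolated so
    the pipeline has no hard matplotlib dependency."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = pwm.information_content
    fig, ax = plt.subplots(figsize=(max(2, pwm.k), 2.5))
    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "U": "#e31a1c"}
    for j in range(pwm.k):
        heights = sorted(
            ((pwm.frequencies[i, j] * ic[j], RNA_ALPHABET[i]) for i in range(4))
        )
        y = 0.0
        for h, base in heights:
            if h <= 0:
                continue
            ax.text(
                j + 1, y + h / 2, base, ha="center", va="center",
                fontsize=8 + 16 * h, color=colors[base], fontweight="bold",
            )
            y += h
    ax.set_xlim(0.5, pwm.k + 0.5)
    ax.set_ylim(0, 2)
    ax.set_xticks(range(1, pwm.k + 1))
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --- pool coverage (coupon collector) ----------------------------------------


def presence_probability(v: int, n: int) -> float:
    """P(a given one of v equally likely variants appears in n draws)."""
    if v < 1:
        raise ValueError("v must be >= 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if v == 1:
        return 0.0 if n == 0 else 1.0
    return 1.0 - (1.0 - 1.0 / v) ** n


def min_pool_size(v: int, p: float) -> int:
    """Smallest n with presence_probability(v, n) >= p.

    Closed form ceil(ln(1-p)/ln(1-1/v)), nudged by +/-1 draw to absorb
    floating-point edge effects against the exact definition.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if v == 1:
        return 1
    n = math.ceil(math.log(1.0 - p) / math.log(1.0 - 1.0 / v))
    while n > 0 and presence_probability(v, n - 1) >= p:
        n -= 1
    while presence_probability(v, n) < p:
        n += 1
    return n
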