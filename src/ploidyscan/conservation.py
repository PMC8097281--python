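"""Per-site conservation from ortholog alignments (pairwise alignment identity).

PAI of an alignment column is the mean pairwise residue identity over all
unordered sequence pairs; pairs involving a gap count as non-identical (a
fully gapped column scores zero identity). Columns are addressed through the
reference sequence: protein position *k* maps to the column holding the
reference's *k*-th non-gap residue.

The conservation contrast asks whether candidate amino-acid substitutions in
one group (e.g. tetraploid-differentiated sites) hit more conserved residues
than another group's (Wilcoxon rank-sum on the two PAI samples).
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProteinAlignment

log = logging.getLogger(__name__)


def pai_column(column: str, count_gaps: bool = True) -> float:
    """Mean pairwise identity of one alignment column.

    With ``count_gaps`` (default), gap-containing pairs are counted in the
    denominator as non-identical; otherwise gapped sequences are dropped
    before pairing.
    """
    symbols = list(column)
    if not count_gaps:
        symbols = [s for s in symbols if s != "-"]
    k = len(symbols)
    if k < 2:
        raise ValueError("PAI needs at least two symbols in the column")
    counts: dict[str, int] = {}
    for s in symbols:
        if s != "-":
            counts[s] = counts.get(s, 0) + 1
    same = sum(comb(c, 2) for c in counts.values())
    return same / comb(k, 2)


def map_reference_position(alignment: ProteinAlignment, ref_pos: int) -> int:
    """1-based alignment column of the reference's ``ref_pos``-th residue."""
    seq = alignment.sequences[alignment.reference_name]
    if ref_pos < 1:
        raise ValueError("reference positions are 1-based")
    count = 0
    for col, ch in enumerate(seq, start=1):
        if ch != "-":
            count += 1
            if count == ref_pos:
                return col
    raise ValueError(
        f"reference position {ref_pos} beyond the {count}-residue reference"
    )


def conservation_table(alignment: ProteinAlignment, gene_id: str,
                       ref_positions: list[int],
                       count_gaps: bool = True) -> pd.DataFrame:
    """PAI at the requested reference protein positions of one gene."""
    rows = []
    for pos in sorted(set(ref_positions)):
        col = map_reference_position(alignment, pos)
        column = alignment.column(col)
        rows.append({
            "gene": gene_id,
            "ref_pos": pos,
            "column": col,
            "pai": pai_column(column, count_gaps),
            "n_sequences": alignment.n_sequences,
            "n_gaps": column.count("-"),
        })
    return pd.DataFrame(rows)


def conservation_compare(pai_a: np.ndarray, pai_b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum of two PAI samples (medians reported)."""
    a = np.asarray(pai_a, dtype=float)
    b = np.asarray(pai_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("conservation comparison needs two non-empty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "W": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


__all__ = [
    "pai_column", "map_reference_position", "conservation_table",
    "conservation_compare",
]
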