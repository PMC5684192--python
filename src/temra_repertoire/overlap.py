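"""Clonotype sharing between T-cell subsets.

Sharing is measured source-relative: the fraction of distinct source
clonotypes (by exact CDR3 amino-acid identity) that also occur in a
reference repertoire, regardless of their abundance there.  The analysis
distinguishes all clonotypes from "highly represented" ones — those
supported by at least ``min_cells`` cells (default 10) in the source —
and additionally reports the fraction of source *cells* carried by the
highly represented clonotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import pandas as pd

from .errors import ValidationError
from .models import Repertoire


@dataclass
class OverlapSummary:
    """Sharing statistics between one source and one reference repertoire."""

    source_donor: str
    source_subset: str
    reference_donor: str
    reference_subset: str
    n_source_clonotypes: int
    fraction_shared: float
    high_threshold: int
    n_high_clonotypes: int
    fraction_shared_high: float
    cell_mass_fraction_high: float

    def to_dict(self) -> dict:
        return asdict(self)


def shared_fraction(source: Repertoire, reference: Repertoire) -> float:
    """Fraction of distinct source clonotypes present in the reference.

    Deliberately asymmetric: membership in the reference is all that
    matters, not abundance there.
    """
    if not source.clones:
        raise ValidationError("source repertoire is empty")
    src = source.clones.keys()
    return len(src & reference.clones.keys()) / len(src)


def highly_represented(rep: Repertoire, min_cells: int = 10) -> set[str]:
    """Clonotypes supported by at least ``min_cells`` cells (inclusive)."""
    if min_cells < 1:
        raise ValidationError(f"min_cells must be >= 1, got {min_cells}")
    return {c for c, n in rep.clones.items() if n >= min_cells}


def cell_mass_fraction(rep: Repertoire, clonotypes: set[str]) -> float:
    """Fraction of the repertoire's cells in the given clonotype set."""
    unknown = clonotypes - rep.clones.keys()
    if unknown:
        raise ValidationError(
            f"clonotypes not in repertoire: {sorted(unknown)[:3]}..."
            if len(unknown) > 3 else
            f"clonotypes not in repertoire: {sorted(unknown)}"
        )
    return sum(rep.clones[c] for c in clonotypes) / rep.total_cells


def percentile_threshold(rep: Repertoire, top_fraction: float = 0.01) -> int:
    """Smallest integer count threshold selecting at most the top
    ``top_fraction`` of clonotypes.

    Returns the smallest integer ``t`` such that the fraction of
    clonotypes with count >= t is <= ``top_fraction``.  If no such
    threshold selects anything (the most abundant clonotype alone already
    exceeds the fraction), the smallest ``t`` selecting exactly the
    maximal-count clonotypes is returned instead.  If every count is tied
    there is no defensible split: the sentinel ``max count + 1`` is
    returned with a warning.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValidationError(
            f"top_fraction must be in (0, 1), got {top_fraction}"
        )
    counts = sorted(rep.clones.values())
    n = len(counts)
    max_count = counts[-1]
    if counts[0] == max_count:
        # all tied: selecting any is selecting all
        warnings.warn(
            "all clonotype counts are tied; returning sentinel "
            "threshold max count + 1 (selects nothing)",
            stacklevel=2,
        )
        return max_count + 1
    for t in range(1, max_count + 2):
        n_at_or_above = n - _bisect_left(counts, t)
        if n_at_or_above / n <= top_fraction:
            if n_at_or_above > 0:
                return t
            # even the top clonotype alone exceeds top_fraction:
            # fall back to selecting exactly the maximal-count clones
            second = max(c for c in counts if c < max_count)
            return second + 1
    raise AssertionError("unreachable")  # pragma: no cover


def _bisect_left(sorted_counts: list[int], t: int) -> int:
    import bisect

    return bisect.bisect_left(sorted_counts, t)


def overlap_report(
    source: Repertoire,
    references: list[Repertoire],
    min_cells: int = 10,
) -> list[OverlapSummary]:
    """All sharing statistics of one source against each reference."""
    high = highly_represented(source, min_cells=min_cells)
    mass_high = cell_mass_fraction(source, high)
    out = []
    for ref in references:
        shared = shared_fraction(source, ref)
        if high:
            shared_high = len(high & ref.clones.keys()) / len(high)
        else:
            shared_high = 0.0
        out.append(
            OverlapSummary(
                source_donor=source.donor_id,
                source_subset=source.subset,
                reference_donor=ref.donor_id,
                reference_subset=ref.subset,
                n_source_clonotypes=source.richness,
                fraction_shared=shared,
                high_threshold=min_cells,
                n_high_clonotypes=len(high),
                fraction_shared_high=shared_high,
                cell_mass_fraction_high=mass_high,
            )
        )
    return out


def overlap_table(summaries: list[OverlapSummary]) -> pd.DataFrame:
    """One row per source x reference pair."""
    return pd.DataFrame([s.to_dict() for s in summaries])
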