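"""Core domain objects: clonotype records and aggregated repertoires.

A *clonotype* is a group of T cells sharing the same CDR3 amino-acid
sequence of the TCR-beta chain; V/J gene calls are annotation only and
never part of the clonotype identity.  A :class:`Repertoire` is the
clonotype -> cell-count mapping for one (donor, subset) sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: The 20 standard amino acids; CDR3s containing anything else
#: (stop codons '*', frameshift '_', X, ...) are treated as
#: non-productive and dropped at parse time.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Canonical T-cell subset labels used throughout.  Free-form labels are
#: also accepted (`subset` is an open vocabulary), but these are the ones
#: the analysis and the synthetic generator know about.
CANONICAL_SUBSETS = (
    "TN",
    "TCM",
    "TEM",
    "TEMRA",
    "TEMRA_GPR56neg",
    "TEMRA_GPR56pos",
)


def is_productive_cdr3(cdr3: str) -> bool:
    """True if ``cdr3`` is a non-empty string over the 20-letter alphabet."""
    return bool(cdr3) and all(ch in AMINO_ACIDS for ch in cdr3)


@dataclass(frozen=True)
class ClonotypeRecord:
    """One row of a clonotype table.

    Parameters
    ----------
    donor_id : str
        Opaque donor label.
    subset : str
        T-cell subset label (TN, TCM, TEM, TEMRA, TEMRA_GPR56neg,
        TEMRA_GPR56pos, or any other label).
    cdr3_aa : str
        CDR3 amino-acid sequence; must be productive
        (uppercase 20-letter alphabet, non-empty).
    count : int
        Template/cell count supporting the clonotype; must be >= 1.
        Counts are integers by construction — the "at least 10 cells"
        rule downstream requires integer abundances.
    v_call, j_call : str or None
        Optional gene-segment annotations.
    """

    donor_id: str
    subset: str
    cdr3_aa: str
    count: int
    v_call: str | None = None
    j_call: str | None = None

    def __post_init__(self) -> None:
        if not is_productive_cdr3(self.cdr3_aa):
            raise ValidationError(
                f"invalid CDR3 amino-acid sequence: {self.cdr3_aa!r}"
            )
        if not isinstance(self.count, (int, np.integer)) or isinstance(
            self.count, bool
        ):
            raise ValidationError(
                f"clonotype count must be an integer, got {self.count!r}"
            )
        if self.count < 1:
            raise ValidationError(
                f"clonotype count must be >= 1, got {self.count}"
            )


@dataclass
class Repertoire:
    """Aggregated clonotype -> count mapping for one (donor, subset).

    Invariants enforced at construction: every count is a positive
    integer and there is at least one clonotype.  ``gene_calls``
    optionally annotates clonotypes with the (v_call, j_call) of the
    most abundant contributing row; it never participates in identity.
    """

    donor_id: str
    subset: str
    clones: dict[str, int]
    gene_calls: dict[str, tuple[str | None, str | None]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValidationError("a repertoire must contain >= 1 clonotype")
        for cdr3, count in self.clones.items():
            if not is_productive_cdr3(cdr3):
                raise ValidationError(f"invalid clonotype key: {cdr3!r}")
            if not isinstance(count, (int, np.integer)) or count < 1:
                raise ValidationError(
                    f"count for {cdr3} must be a positive integer, got {count!r}"
                )

    @property
    def total_cells(self) -> int:
        return int(sum(self.clones.values()))

    @property
    def richness(self) -> int:
        """Number of distinct clonotypes."""
        return len(self.clones)

    @property
    def frequencies(self) -> dict[str, float]:
        total = self.total_cells
        return {c: n / total for c, n in self.clones.items()}

    def counts_array(self) -> np.ndarray:
        return np.fromiter(self.clones.values(), dtype=np.int64, count=len(self.clones))

    def frequency_array(self) -> np.ndarray:
        counts = self.counts_array()
        return counts / counts.sum()
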