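"""Read/write clonotype tables in two TSV dialects.

Two dialects are supported, both UTF-8 tab-separated with a mandatory
header row:

``airr``
    AIRR-Rearrangement-style columns ``sequence_id``, ``junction_aa``,
    ``v_call``, ``j_call``, ``duplicate_count`` (+ optional ``donor_id``,
    ``subset``).
``immunoseq``
    immunoSEQ-export-style columns ``amino_acid``, ``templates``
    (+ optional ``v_gene``, ``j_gene``, ``donor_id``, ``subset``).

Rows whose CDR3 is empty or non-productive (contains characters outside
the 20-letter amino-acid alphabet, e.g. ``*`` or ``_``) are dropped and
counted in the returned skip tally; this productive-only filtering is the
field default for repertoire analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .models import ClonotypeRecord, Repertoire, is_productive_cdr3

log = logging.getLogger(__name__)

_DIALECTS = {
    "airr": {
        "cdr3": "junction_aa",
        "count": "duplicate_count",
        "v": "v_call",
        "j": "j_call",
        "columns": ["sequence_id", "junction_aa", "v_call", "j_call",
                    "duplicate_count"],
    },
    "immunoseq": {
        "cdr3": "amino_acid",
        "count": "templates",
        "v": "v_gene",
        "j": "j_gene",
        "columns": ["amino_acid", "templates", "v_gene", "j_gene"],
    },
}


def _dialect(name: str) -> dict:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise FormatError(
            f"unknown dialect {name!r}; expected one of {sorted(_DIALECTS)}"
        ) from None


@dataclass
class ParseResult:
    """Records parsed from a clonotype table plus the skip tally."""

    records: list[ClonotypeRecord]
    n_skipped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_clonotype_table(
    path: str | Path,
    dialect: str,
    donor_id: str | None = None,
    subset: str | None = None,
) -> ParseResult:
    """Parse a clonotype TSV into validated records.

    ``donor_id``/``subset`` arguments override the same-named columns if
    both are present (immunoSEQ exports often lack sample metadata, so the
    caller supplies it).

    Raises
    ------
    FormatError
        If a mandatory column for the dialect is missing.
    ValidationError
        If a row carries a non-positive or fractional count, or no donor
        or subset label can be resolved for it.
    """
    spec = _dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (spec["cdr3"], spec["count"]):
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {col!r} for "
                f"dialect {dialect!r}"
            )

    records: list[ClonotypeRecord] = []
    n_skipped = 0
    for idx, row in df.iterrows():
        cdr3 = row[spec["cdr3"]].strip()
        if not is_productive_cdr3(cdr3):
            n_skipped += 1
            continue
        raw_count = row[spec["count"]].strip()
        try:
            count_f = float(raw_count)
        except ValueError:
            raise ValidationError(
                f"{path} row {idx}: unparseable count {raw_count!r}"
            ) from None
        if count_f != int(count_f):
            raise ValidationError(
                f"{path} row {idx}: fractional count {raw_count!r}; "
                "template/cell counts must be integers"
            )
        count = int(count_f)
        if count < 1:
            raise ValidationError(
                f"{path} row {idx}: non-positive count {count}"
            )
        d = donor_id or row.get("donor_id", "").strip()
        s = subset or row.get("subset", "").strip()
        if not d or not s:
            raise ValidationError(
                f"{path} row {idx}: donor_id/subset neither in columns "
                "nor supplied as defaults"
            )
        v = row.get(spec["v"], "").strip() or None
        j = row.get(spec["j"], "").strip() or None
        records.append(
            ClonotypeRecord(donor_id=d, subset=s, cdr3_aa=cdr3,
                            count=count, v_call=v, j_call=j)
        )
    if n_skipped:
        log.info("%s: skipped %d non-productive row(s)", path, n_skipped)
    return ParseResult(records=records, n_skipped=n_skipped)


def aggregate_clonotypes(records: list[ClonotypeRecord]) -> list[Repertoire]:
    """Merge records into one :class:`Repertoire` per (donor, subset).

    Records sharing (donor, subset, CDR3) are merged by summing counts —
    the clonotype key is the CDR3 amino-acid string alone, never V/J.
    Gene calls of the most abundant contributing row are kept as
    annotation.  Total cell count is conserved.  An empty input yields an
    empty list.
    """
    merged: dict[tuple[str, str], dict[str, int]] = {}
    # (donor, subset, cdr3) -> (best row count, v, j)
    genes: dict[tuple[str, str, str], tuple[int, str | None, str | None]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.donor_id, rec.subset)
        if key not in merged:
            merged[key] = {}
            order.append(key)
        merged[key][rec.cdr3_aa] = merged[key].get(rec.cdr3_aa, 0) + rec.count
        gkey = (rec.donor_id, rec.subset, rec.cdr3_aa)
        prev = genes.get(gkey)
        if prev is None or rec.count > prev[0]:
            genes[gkey] = (rec.count, rec.v_call, rec.j_call)
    out = []
    for donor, subset in order:
        clones = merged[(donor, subset)]
        gene_calls = {
            cdr3: genes[(donor, subset, cdr3)][1:] for cdr3 in clones
        }
        out.append(
            Repertoire(donor_id=donor, subset=subset, clones=clones,
                       gene_calls=gene_calls)
        )
    return out


def write_clonotype_table(
    reps: list[Repertoire], path: str | Path, dialect: str
) -> None:
    """Write repertoires as a clonotype TSV in the chosen dialect.

    Round-trip guarantee: ``read + aggregate`` of the written file
    reproduces every repertoire's clone -> count mapping exactly.
    """
    spec = _dialect(dialect)
    rows = []
    seq_id = 0
    for rep in reps:
        for cdr3, count in rep.clones.items():
            v, j = rep.gene_calls.get(cdr3, (None, None))
            row = {
                spec["cdr3"]: cdr3,
                spec["count"]: count,
                spec["v"]: v or "",
                spec["j"]: j or "",
                "donor_id": rep.donor_id,
                "subset": rep.subset,
            }
            if dialect == "airr":
                row["sequence_id"] = f"seq{seq_id}"
            rows.append(row)
            seq_id += 1
    columns = spec["columns"] + ["donor_id", "subset"]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False)


def read_repertoires(
    path: str | Path,
    dialect: str,
    donor_id: str | None = None,
    subset: str | None = None,
) -> list[Repertoire]:
    """Convenience: parse a table and aggregate in one step."""
    return aggregate_clonotypes(
        read_clonotype_table(path, dialect, donor_id=donor_id,
                             subset=subset).records
    )
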