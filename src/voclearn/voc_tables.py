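"""Identification tables of urinary VOCs and cohort summary fixtures.

The package ships four TSV fixtures transcribed from the study tables:
cohort characteristics (``table1``), the acid- and alkaline-condition
VOC identification tables (``table2``/``table3``; 110 and 83 compounds),
and the 14-marker univariate statistics table (``table4``).

Dialect: tab-separated, UTF-8, one header row; an em dash (``—``) or an
empty cell means "not available" and parses as absent (``None``), except
for occurrence percentages where an absent cell means the compound was
never detected in that group (0%).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

_ABSENT = {"", "—", "-", "NA", "nan"}

_COLUMNS = [
    "metabolite",
    "chemical_class",
    "mz",
    "match_percent",
    "ri_cal",
    "ri_lit",
    "id_method",
    "occurrence_nw",
    "occurrence_ow",
]


class VOCTableParseError(ValueError):
    """Malformed identification-table row; message carries the line number."""


@dataclass
class VOCRecord:
    """One row of a VOC identification table.

    ``mz`` keeps every printed main fragment ion (slash-separated in the
    source); ``ri_cal``/``ri_lit`` are the experimental and literature
    Kovats indices, absent (None) when the compound was identified by
    mass spectrum only; ``id_method`` is a subset of {RI, MS, S}.
    """

    name: str
    mz: list[int]
    match_percent: float
    ri_cal: float | None
    ri_lit: float | None
    id_method: list[str]
    occurrence_nw: float
    occurrence_ow: float
    chemical_class: str
    condition: str


def _parse_optional(cell: str) -> float | None:
    cell = cell.strip()
    if cell in _ABSENT:
        return None
    return float(cell)


def _parse_occurrence(cell: str) -> float:
    val = _parse_optional(cell)
    val = 0.0 if val is None else val
    if not 0.0 <= val <= 100.0:
        raise ValueError(f"occurrence {val} outside [0, 100]")
    return val


def parse_voc_table(path, condition: str = "alkaline") -> list[VOCRecord]:
    """Parse a VOC identification TSV into records, one per compound."""
    records: list[VOCRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise VOCTableParseError(f"line 1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(_COLUMNS):
                raise VOCTableParseError(
                    f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(cells)}"
                )
            row = dict(zip(_COLUMNS, cells))
            try:
                method = [m for m in row["id_method"].split("/") if m]
                if not method:
                    raise ValueError("empty identification method")
                rec = VOCRecord(
                    name=row["metabolite"].strip(),
                    mz=[int(x) for x in row["mz"].split("/")],
                    match_percent=float(row["match_percent"]),
                    ri_cal=_parse_optional(row["ri_cal"]),
                    ri_lit=_parse_optional(row["ri_lit"]),
                    id_method=method,
                    occurrence_nw=_parse_occurrence(row["occurrence_nw"]),
                    occurrence_ow=_parse_occurrence(row["occurrence_ow"]),
                    chemical_class=row["chemical_class"].strip(),
                    condition=condition,
                )
            except ValueError as exc:
                raise VOCTableParseError(f"line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def _fixture_path(name: str):
    return resources.files("voclearn.data").joinpath(name)


def load_voc_table(condition: str) -> list[VOCRecord]:
    """Packaged identification table for ``"acid"`` (110) or ``"alkaline"`` (83)."""
    if condition not in ("acid", "alkaline"):
        raise ValueError(f"unknown condition {condition!r}")
    name = "table2.tsv" if condition == "acid" else "table3.tsv"
    with resources.as_file(_fixture_path(name)) as p:
        return parse_voc_table(p, condition=condition)


def occurrence_probabilities(condition: str, group: str = "NW") -> pd.Series:
    """Per-compound detection frequency (as a probability) from the fixtures."""
    records = load_voc_table(condition)
    col = {"NW": "occurrence_nw", "OW/Ob": "occurrence_ow"}[group]
    vals = pd.Series(
        [getattr(r, col) / 100.0 for r in records],
        index=[r.name for r in records],
    )
    # duplicate compound names (isomers listed twice) get suffixed ids
    if vals.index.duplicated().any():
        idx = pd.Series(vals.index)
        counts = idx.groupby(idx).cumcount()
        vals.index = [f"{n} ({k+1})" if c > 0 else n
                      for n, c, k in zip(idx, counts, counts)]
    return vals


def load_cohort_characteristics() -> pd.DataFrame:
    """Cohort summary table: per-variable group mean/SD/n and printed p."""
    with resources.as_file(_fixture_path("table1.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_marker_table() -> pd.DataFrame:
    """The 14-marker univariate statistics table (alkaline condition)."""
    with resources.as_file(_fixture_path("table4.tsv")) as p:
        return pd.read_csv(p, sep="\t")
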