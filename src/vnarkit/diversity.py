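"""Repertoire diversity statistics.

Summaries mirror what an NGS characterization of a naive single-domain
library reports: unique protein sequences, per-type composition, the number
of clones whose CDR3 is not shared with any other unique clone, CDR3 length
and CDR3 cysteine-count histograms, and CDR1 variability.

Percentage convention: 100*count/denominator rounded half-up at the printed
precision — one decimal for type composition, integers for CDR3-level
percentages. The convention is centralized in :func:`vnarkit._util.percentage`.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percentage
from .classify import TYPE_LABELS, TypeCall
from .io import CloneRecord
from .regions import RegionMap


def type_percentages(
    counts: Mapping[str, int], ndigits: int = 1
) -> dict[str, float]:
    """Per-type percentages from per-type counts (half-up at ``ndigits``)."""
    total = sum(counts.values())
    return {label: percentage(n, total, ndigits) for label, n in counts.items()}


def dedupe_sequences(
    records: Sequence[CloneRecord],
) -> tuple[list[CloneRecord], dict[str, int]]:
    """Collapse to unique translated protein sequences.

    Uniqueness is exact amino-acid identity over the full translated domain;
    the first occurrence is kept as the representative. Returns the unique
    records (input order) and the multiplicity of each distinct sequence.
    """
    unique: list[CloneRecord] = []
    mult: dict[str, int] = {}
    for rec in records:
        if rec.aa is None:
            raise ValueError(f"clone {rec.clone_id!r} has no translation; dedupe on aa")
        if rec.aa not in mult:
            unique.append(rec)
            mult[rec.aa] = 1
        else:
            mult[rec.aa] += 1
    return unique, mult


def unique_cdr3_partition(maps: Sequence[RegionMap]) -> tuple[int, int]:
    """Split unique clones into CDR3-unique vs variable-elsewhere.

    ``n_unique_cdr3`` counts clones whose CDR3 string occurs in exactly one
    unique clone; the remainder share a CDR3 with another clone and owe their
    uniqueness to FR/CDR1/HV differences. The two counts sum to the input size.
    """
    cdr3_counts = Counter(m.cdr3_seq for m in maps)
    n_unique = sum(1 for m in maps if cdr3_counts[m.cdr3_seq] == 1)
    return n_unique, len(maps) - n_unique


@dataclass
class RepertoireSummary:
    """Everything a library characterization figure reports, in one object."""

    n_total_unique: int
    per_type_counts: dict[str, int]
    per_type_pct: dict[str, float]
    n_unique_cdr3: int
    pct_unique_cdr3: int
    cdr3_length_hist: dict[int, int]
    cdr3_cys_hist: dict[int, int]
    cdr3_cys_pct: dict[int, int]
    cdr1_variability_pct: float
    excluded: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        payload = {
            "n_total_unique": self.n_total_unique,
            "per_type_counts": self.per_type_counts,
            "per_type_pct": self.per_type_pct,
            "n_unique_cdr3": self.n_unique_cdr3,
            "pct_unique_cdr3": self.pct_unique_cdr3,
            "cdr3_length_hist": {str(k): v for k, v in sorted(self.cdr3_length_hist.items())},
            "cdr3_cys_hist": {str(k): v for k, v in sorted(self.cdr3_cys_hist.items())},
            "cdr3_cys_pct": {str(k): v for k, v in sorted(self.cdr3_cys_pct.items())},
            "cdr1_variability_pct": self.cdr1_variability_pct,
        }
        return json.dumps(payload, **kwargs)

    def to_text(self) -> str:
        lines = [f"Unique vNAR protein sequences: {self.n_total_unique:,}"]
        for label in TYPE_LABELS:
            if label in self.per_type_counts:
                lines.append(
                    f"  type {label:<3} {self.per_type_counts[label]:>9,}"
                    f"  ({self.per_type_pct[label]}%)"
                )
        lines.append(
            f"Clones with a unique CDR3: {self.n_unique_cdr3:,} ({self.pct_unique_cdr3}%)"
        )
        if self.cdr3_length_hist:
            lo, hi = min(self.cdr3_length_hist), max(self.cdr3_length_hist)
            lines.append(f"CDR3 length range: {lo}-{hi} aa")
        cys = ", ".join(
            f"{k} Cys: {self.cdr3_cys_pct[k]}%" for k in sorted(self.cdr3_cys_pct)
        )
        lines.append(f"CDR3 cysteines (among unique CDR3s): {cys}")
        lines.append(f"CDR1 variability: {self.cdr1_variability_pct}%")
        return "\n".join(lines)


def summarize_repertoire(
    calls: Sequence[TypeCall], maps: Sequence[RegionMap]
) -> RepertoireSummary:
    """Build the repertoire summary from aligned type calls and region maps.

    Inputs are expected to be deduplicated already (one entry per unique
    clone). The CDR3 cysteine histogram is taken over the clones whose CDR3
    is unique, matching how library characterizations report it.
    """
    maps_by_id = {m.clone_id: m for m in maps if m.ok}
    call_ids = {c.clone_id for c in calls}
    if call_ids != set(maps_by_id):
        missing = call_ids.symmetric_difference(maps_by_id)
        raise ValueError(f"calls and maps disagree on clone IDs (e.g. {sorted(missing)[:5]})")
    n = len(calls)
    if n == 0:
        raise ValueError("empty repertoire")

    per_type_counts = {label: 0 for label in TYPE_LABELS}
    for c in calls:
        per_type_counts[c.label] += 1
    per_type_pct = type_percentages(per_type_counts, ndigits=1)

    ordered_maps = [maps_by_id[c.clone_id] for c in calls]
    n_unique_cdr3, _ = unique_cdr3_partition(ordered_maps)
    pct_unique_cdr3 = percentage(n_unique_cdr3, n, 0)

    cdr3_length_hist = dict(Counter(m.cdr3_length for m in ordered_maps))

    cdr3_counts = Counter(m.cdr3_seq for m in ordered_maps)
    calls_by_id = {c.clone_id: c for c in calls}
    cys_hist = Counter(
        calls_by_id[m.clone_id].cdr3_cys_count
        for m in ordered_maps
        if cdr3_counts[m.cdr3_seq] == 1
    )
    denom = max(1, n_unique_cdr3)
    cys_pct = {k: percentage(v, denom, 0) for k, v in cys_hist.items()}

    cdr1_counter = Counter(m.cdr1_seq for m in ordered_maps)
    modal_cdr1, modal_n = cdr1_counter.most_common(1)[0]
    cdr1_var_pct = percentage(n - modal_n, n, 1)

    return RepertoireSummary(
        n_total_unique=n,
        per_type_counts=per_type_counts,
        per_type_pct=per_type_pct,
        n_unique_cdr3=n_unique_cdr3,
        pct_unique_cdr3=pct_unique_cdr3,
        cdr3_length_hist=cdr3_length_hist,
        cdr3_cys_hist=dict(cys_hist),
        cdr3_cys_pct=cys_pct,
        cdr1_variability_pct=cdr1_var_pct,
    )


def cdr3_length_stats(
    maps: Sequence[RegionMap], band: tuple[int, int] = (15, 16)
) -> tuple[int, int, float]:
    """Min/max CDR3 length and the fraction of clones in a length band."""
    lengths = [m.cdr3_length for m in maps if m.ok and m.cdr3_length is not None]
    if not lengths:
        raise ValueError("no annotated clones with a CDR3 length")
    lo, hi = band
    in_band = sum(1 for length in lengths if lo <= length <= hi)
    return min(lengths), max(lengths), in_band / len(lengths)


def histogram_table(hist: Mapping[int, int], key_name: str) -> pd.DataFrame:
    return pd.DataFrame(
        {key_name: k, "count": v} for k, v in sorted(hist.items())
    )
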