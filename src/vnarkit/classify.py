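"""vNAR type classification from noncanonical cysteine/tryptophan patterns.

Types are defined by where noncanonical cysteines sit relative to the two
antigen-contacting loops (the canonical Cys22/Cys83 pair lies in framework
spans and never enters these counts):

* **III** — Cys at scheme position 29 *and* Trp at 30 inside CDR1;
* **IIa** — at least one Cys in CDR1 and at least one in CDR3 (the typical
  type II with a CDR1-CDR3 interloop disulfide);
* **I**   — no CDR1 Cys, an even CDR3 Cys count >= 2 (paired intra/interloop
  linkages within CDR3);
* **IIb** — a Cys in exactly one of the two loops (odd CDR3 counts with a
  Cys-free CDR1 land here: the unpaired cysteine cannot form a loop-loop
  bond);
* **IV**  — no noncanonical Cys in either loop.

Rules are evaluated in that strict precedence; the textual definitions
overlap (Cys in both loops with an even CDR3 count satisfies both the I and
IIa descriptions) and interloop-capable patterns are assigned IIa first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CloneRecord
from .regions import RegionMap

TYPE_LABELS = ("I", "IIa", "IIb", "III", "IV")


@dataclass
class TypeCall:
    """A type label plus the loop-cysteine evidence that produced it."""

    clone_id: str
    label: str
    cdr1_cys_positions: list[int]
    cdr3_cys_count: int
    cdr1_trp30: bool
    rule_fired: str
    warnings: list[str] = field(default_factory=list)


def _decide(
    cys29: bool, cdr1_has_cys: bool, cdr3_cys_count: int, trp30: bool
) -> tuple[str, str]:
    """Precedence table on the evidence tuple. Returns (label, rule name)."""
    if cys29 and trp30:
        return "III", "cdr1_cys29_trp30"
    cdr3_has = cdr3_cys_count >= 1
    if cdr1_has_cys and cdr3_has:
        return "IIa", "interloop_cdr1_cdr3"
    if not cdr1_has_cys and cdr3_cys_count >= 2 and cdr3_cys_count % 2 == 0:
        return "I", "even_cdr3_pair"
    if cdr1_has_cys != cdr3_has:
        return "IIb", "single_loop_cys"
    return "IV", "no_noncanonical_cys"


def classify_type(
    rmap: RegionMap,
    aa: str,
    cdr1_cys_anywhere: bool = True,
) -> TypeCall:
    """Assign a vNAR type to one annotated clone.

    ``cdr1_cys_anywhere`` counts a CDR1 cysteine at any of the nine CDR1
    positions (the default); when False only scheme position 29 counts for
    the IIa/IIb rules. Position 29/30 are resolved relative to the first
    canonical anchor, so shifted anchors shift the check coherently.
    """
    if not rmap.ok:
        raise ValueError(f"clone {rmap.clone_id!r}: cannot classify status={rmap.annotation_status}")
    c1 = rmap.anchor_cys1
    assert rmap.spans is not None and c1 is not None
    cdr1_s, cdr1_e = rmap.spans["CDR1"]
    cdr3_s, cdr3_e = rmap.spans["CDR3"]
    cdr1 = aa[cdr1_s - 1 : cdr1_e]
    cdr3 = aa[cdr3_s - 1 : cdr3_e]
    cdr1_cys_positions = [cdr1_s + i for i, ch in enumerate(cdr1) if ch == "C"]
    pos29, pos30 = c1 + 7, c1 + 8
    cys29 = pos29 <= len(aa) and aa[pos29 - 1] == "C"
    trp30 = pos30 <= len(aa) and aa[pos30 - 1] == "W"
    cdr3_cys_count = cdr3.count("C")
    cdr1_has = bool(cdr1_cys_positions) if cdr1_cys_anywhere else cys29
    label, rule = _decide(cys29, cdr1_has, cdr3_cys_count, trp30)
    return TypeCall(
        clone_id=rmap.clone_id,
        label=label,
        cdr1_cys_positions=cdr1_cys_positions,
        cdr3_cys_count=cdr3_cys_count,
        cdr1_trp30=trp30,
        rule_fired=rule,
        warnings=list(rmap.warnings),
    )


def classify_repertoire(
    maps: Sequence[RegionMap],
    records: Sequence[CloneRecord] | Mapping[str, str],
    cdr1_cys_anywhere: bool = True,
) -> tuple[list[TypeCall], list[str]]:
    """Classify every cleanly annotated clone, preserving input order.

    Returns the type calls plus the IDs of clones excluded because their
    annotation status was not ``ok``.
    """
    if isinstance(records, Mapping):
        aa_by_id = dict(records)
    else:
        aa_by_id = {r.clone_id: r.aa for r in records if r.aa is not None}
    calls: list[TypeCall] = []
    excluded: list[str] = []
    for rmap in maps:
        if not rmap.ok:
            excluded.append(rmap.clone_id)
            continue
        aa = aa_by_id.get(rmap.clone_id)
        if aa is None:
            raise KeyError(f"no translated sequence for clone {rmap.clone_id!r}")
        calls.append(classify_type(rmap, aa, cdr1_cys_anywhere=cdr1_cys_anywhere))
    if not calls:
        warnings.warn("no cleanly annotated clones to classify", stacklevel=2)
    return calls, excluded


def calls_table(calls: Iterable[TypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": c.clone_id,
            "label": c.label,
            "cdr1_cys_positions": ";".join(map(str, c.cdr1_cys_positions)),
            "cdr3_cys_count": c.cdr3_cys_count,
            "cdr1_trp30": c.cdr1_trp30,
            "rule_fired": c.rule_fired,
        }
        for c in calls
    )
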