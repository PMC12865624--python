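"""Framework / hypervariable region delimitation for translated vNAR domains.

The vNAR fold is pinned by a canonical disulfide between two framework
cysteines near positions 22 (strand C) and 83 (strand G). All region
boundaries here are expressed as fixed offsets from those two anchors, which
generalizes the crystal-structure coordinates (CDR1 25-33, HV2 44-51,
HV4 60-65, CDR3 87-96 for a 10-residue CDR3) to length-variant clones:
CDR3 length variation is absorbed between the second anchor and the
carboxy-terminal FR4 framework motif (default pattern ``[YW]G.G``).

Coordinates are 1-based inclusive throughout, matching the field's usage
(Cys22, Leu31, CDR1 25-33).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CloneRecord

REGION_ORDER = ("FR1", "CDR1", "FR2", "HV2", "FR3a", "HV4", "FR3b", "CDR3", "FR4")


@dataclass(frozen=True)
class RegionScheme:
    """Anchor-offset region scheme.

    With anchors ``c1``/``c2`` (defaults 22/83) the spans are::

        FR1   1        .. c1+2
        CDR1  c1+3     .. c1+2+cdr1_width      (25..33)
        FR2   ..       .. c1+hv2_start_off-1
        HV2   c1+hv2_start_off .. c1+hv2_end_off   (44..51)
        FR3a  ..       .. c1+hv4_start_off-1
        HV4   c1+hv4_start_off .. c1+hv4_end_off   (60..65)
        FR3b  ..       .. c2+3
        CDR3  c2+4     .. FR4_start-1
        FR4   first [YW]G.G match at/after c2+4 .. end
    """

    cys1_pos: int = 22
    cys1_window: int = 3
    cys2_pos: int = 83
    cys2_window: int = 6
    cdr1_width: int = 9
    hv2_start_off: int = 22  # 44 when c1 = 22
    hv2_end_off: int = 29  # 51
    hv4_start_off: int = 38  # 60
    hv4_end_off: int = 43  # 65
    fr4_motif: str = r"[YW]G.G"
    cdr3_min: int = 4
    cdr3_max: int = 34
    leu_pos_off: int = 9  # scheme position 31 when c1 = 22


DEFAULT_SCHEME = RegionScheme()


@dataclass
class RegionMap:
    """Per-clone residue spans plus the anchor evidence that produced them."""

    clone_id: str
    spans: dict[str, tuple[int, int]] | None
    anchor_cys1: int | None
    anchor_cys2: int | None
    cdr3_length: int | None
    leu31_present: bool
    annotation_status: str  # ok | no_anchor | atypical_spacing
    cdr1_seq: str = ""
    cdr3_seq: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.annotation_status == "ok"


def _nearest_cys(aa: str, center: int, window: int) -> int | None:
    """1-based position of the Cys nearest ``center`` within ``center±window``."""
    best = None
    for pos in range(max(1, center - window), min(len(aa), center + window) + 1):
        if aa[pos - 1] == "C":
            if best is None or abs(pos - center) < abs(best - center):
                best = pos
    return best


def find_canonical_anchors(
    aa: str, scheme: RegionScheme = DEFAULT_SCHEME
) -> tuple[int | None, int | None]:
    """Locate the canonical disulfide cysteines (nearest-in-window search)."""
    if not aa:
        raise ValueError("empty protein sequence")
    c1 = _nearest_cys(aa, scheme.cys1_pos, scheme.cys1_window)
    c2 = _nearest_cys(aa, scheme.cys2_pos, scheme.cys2_window)
    return c1, c2


def annotate_regions(
    record: CloneRecord | tuple[str, str],
    scheme: RegionScheme = DEFAULT_SCHEME,
) -> RegionMap:
    """Delimit the nine vNAR regions of one translated clone.

    Status ``no_anchor`` when either canonical cysteine is missing;
    ``atypical_spacing`` when the offsets cannot be laid out on the sequence,
    the FR4 motif is absent, or the implied CDR3 length falls outside the
    configured bounds. For status ``ok`` the spans exactly tile 1..len(aa).
    """
    if isinstance(record, CloneRecord):
        clone_id, aa = record.clone_id, record.aa
    else:
        clone_id, aa = record
    if not aa:
        raise ValueError(f"clone {clone_id!r}: no translated sequence to annotate")

    c1, c2 = find_canonical_anchors(aa, scheme)
    leu_pos = None if c1 is None else c1 + scheme.leu_pos_off
    leu31 = bool(leu_pos and leu_pos <= len(aa) and aa[leu_pos - 1] == "L")
    fail = RegionMap(
        clone_id=clone_id,
        spans=None,
        anchor_cys1=c1,
        anchor_cys2=c2,
        cdr3_length=None,
        leu31_present=leu31,
        annotation_status="no_anchor",
    )
    if c1 is None or c2 is None:
        return fail

    bounds = {
        "FR1": (1, c1 + 2),
        "CDR1": (c1 + 3, c1 + 2 + scheme.cdr1_width),
        "FR2": (c1 + 3 + scheme.cdr1_width, c1 + scheme.hv2_start_off - 1),
        "HV2": (c1 + scheme.hv2_start_off, c1 + scheme.hv2_end_off),
        "FR3a": (c1 + scheme.hv2_end_off + 1, c1 + scheme.hv4_start_off - 1),
        "HV4": (c1 + scheme.hv4_start_off, c1 + scheme.hv4_end_off),
        "FR3b": (c1 + scheme.hv4_end_off + 1, c2 + 3),
    }
    fail.annotation_status = "atypical_spacing"
    prev_end = 0
    for name in REGION_ORDER[:7]:
        start, end = bounds[name]
        if start != prev_end + 1 or end < start:
            return fail
        prev_end = end
    cdr3_start = c2 + 4
    if cdr3_start > len(aa):
        return fail
    match = re.search(scheme.fr4_motif, aa[cdr3_start - 1 :])
    if match is None:
        return fail
    fr4_start = cdr3_start + match.start()
    cdr3_length = fr4_start - cdr3_start
    if not (scheme.cdr3_min <= cdr3_length <= scheme.cdr3_max):
        fail.cdr3_length = cdr3_length
        return fail
    bounds["CDR3"] = (cdr3_start, fr4_start - 1)
    bounds["FR4"] = (fr4_start, len(aa))

    cdr1_s, cdr1_e = bounds["CDR1"]
    cdr3_s, cdr3_e = bounds["CDR3"]
    warn = []
    for hv in ("HV2", "HV4"):
        s, e = bounds[hv]
        if "C" in aa[s - 1 : e]:
            warn.append(f"cysteine in {hv}")
    return RegionMap(
        clone_id=clone_id,
        spans={name: bounds[name] for name in REGION_ORDER},
        anchor_cys1=c1,
        anchor_cys2=c2,
        cdr3_length=cdr3_length,
        leu31_present=leu31,
        annotation_status="ok",
        cdr1_seq=aa[cdr1_s - 1 : cdr1_e],
        cdr3_seq=aa[cdr3_s - 1 : cdr3_e],
        warnings=warn,
    )


def annotate_repertoire(
    records: Iterable[CloneRecord],
    scheme: RegionScheme = DEFAULT_SCHEME,
    complete_only: bool = True,
) -> list[RegionMap]:
    """Annotate every translatable clone; incomplete inserts are skipped by default."""
    maps = []
    for rec in records:
        if rec.aa is None:
            continue
        if complete_only and not rec.is_complete_insert:
            continue
        maps.append(annotate_regions(rec, scheme))
    return maps


def leu31_fraction(
    maps: Sequence[RegionMap],
    calls: Sequence | None = None,
    restrict_labels: set[str] | None = None,
) -> float:
    """Fraction of annotated clones with the conserved CDR1 leucine (position 31).

    With ``calls`` and ``restrict_labels`` (e.g. ``{"IIa", "IIb"}``) the
    denominator is restricted to clones of those vNAR types.
    """
    ok_maps = [m for m in maps if m.ok]
    if restrict_labels is not None:
        if calls is None:
            raise ValueError("restrict_labels requires matching type calls")
        wanted = {c.clone_id for c in calls if c.label in restrict_labels}
        ok_maps = [m for m in ok_maps if m.clone_id in wanted]
    if not ok_maps:
        raise ValueError("no annotated clones to evaluate")
    return sum(m.leu31_present for m in ok_maps) / len(ok_maps)


def maps_table(maps: Iterable[RegionMap]) -> pd.DataFrame:
    rows = []
    for m in maps:
        row: dict[str, object] = {"clone_id": m.clone_id}
        for name in REGION_ORDER:
            if m.spans and name in m.spans:
                s, e = m.spans[name]
                row[name] = f"{s}-{e}"
            else:
                row[name] = ""
        row.update(
            cdr3_length=m.cdr3_length if m.cdr3_length is not None else "",
            leu31_present=m.leu31_present,
            annotation_status=m.annotation_status,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def maps_to_bed(maps: Iterable[RegionMap]) -> pd.DataFrame:
    """BED-like 0-based half-open export (a dialect conversion of the 1-based spans)."""
    rows = []
    for m in maps:
        if not m.spans:
            continue
        for name in REGION_ORDER:
            s, e = m.spans[name]
            rows.append({"clone_id": m.clone_id, "start": s - 1, "end": e, "region": name})
    return pd.DataFrame(rows)
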