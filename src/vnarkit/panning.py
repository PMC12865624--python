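"""Biopanning / phage-ELISA screening arithmetic.

A clone is phage-ELISA positive when its antigen OD is at least four-fold the
strongest negative-control signal (BSA, milk, unrelated antigen); the
comparison against the *maximum* negative is the conservative reading and the
threshold is inclusive (fold >= 4). Positives are binned by OD — high
(> 1.0), medium (0.5-1.0, boundary inclusive in medium), low (< 0.5) — and
per-round positivity and per-antigen unique-binder percentages track the
enrichment trajectory across rounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percentage


@dataclass
class ElisaRecord:
    """One well set: a clone's antigen OD plus its negative-control ODs."""

    clone_id: str
    round_index: int
    od_antigen: float
    od_negatives: dict[str, float]
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.od_negatives:
            raise ValueError(f"clone {self.clone_id!r}: at least one negative control required")
        values = [self.od_antigen, *self.od_negatives.values()]
        if any((not math.isfinite(v)) or v < 0 for v in values):
            raise ValueError(f"clone {self.clone_id!r}: ODs must be finite and non-negative")


@dataclass
class PositiveCall:
    positive: bool
    fold: float  # nan when undefined (all negatives zero)
    undefined: bool = False


@dataclass
class PanningRoundSummary:
    round_index: int
    n_screened: int
    n_positive: int
    positivity_pct: int
    od_bins: dict[str, int]
    high_od_fraction_of_positives: float


@dataclass
class AntigenScreenSummary:
    antigen: str
    n_sequenced: int
    n_unique: int
    unique_pct: int


@dataclass
class Trajectory:
    table: pd.DataFrame
    positivity_nondecreasing: bool
    uniqueness_nonincreasing: bool | None


def call_positive(rec: ElisaRecord, fold_threshold: float = 4.0) -> PositiveCall:
    """Fold-over-background positivity call for a single well set.

    fold = od_antigen / max(negatives); positive iff fold >= threshold. When
    every negative reads zero the fold is undefined and the record is flagged
    rather than called positive.
    """
    max_neg = max(rec.od_negatives.values())
    if max_neg == 0:
        return PositiveCall(positive=False, fold=float("nan"), undefined=True)
    fold = rec.od_antigen / max_neg
    return PositiveCall(positive=fold >= fold_threshold, fold=fold)


def consistent_binders(
    records: Sequence[ElisaRecord],
    fold_threshold: float = 4.0,
    min_replicates: int = 3,
) -> set[str]:
    """Clones positive in >= ``min_replicates`` independent replicate assays."""
    hits: dict[str, int] = {}
    for rec in records:
        if call_positive(rec, fold_threshold).positive:
            hits[rec.clone_id] = hits.get(rec.clone_id, 0) + 1
    return {cid for cid, k in hits.items() if k >= min_replicates}


def _clone_groups(records: Sequence[ElisaRecord]) -> dict[str, list[ElisaRecord]]:
    groups: dict[str, list[ElisaRecord]] = {}
    for rec in records:
        groups.setdefault(rec.clone_id, []).append(rec)
    return groups


def summarize_round(
    records: Sequence[ElisaRecord],
    fold_threshold: float = 4.0,
    min_positive_replicates: int = 3,
) -> PanningRoundSummary:
    """Positivity and OD-bin summary for one panning round.

    With replicate assays a clone counts as positive when positive in
    ``min_positive_replicates`` replicates (or in all of them when fewer were
    run); with single wells this reduces to the plain fold rule. Bins are
    taken over positives using each clone's mean antigen OD.
    """
    if not records:
        raise ValueError("empty round")
    rounds = {rec.round_index for rec in records}
    if len(rounds) != 1:
        raise ValueError(f"records span multiple rounds: {sorted(rounds)}")
    (round_index,) = rounds

    bins = {"high": 0, "medium": 0, "low": 0}
    n_positive = 0
    groups = _clone_groups(records)
    for recs in groups.values():
        calls = [call_positive(r, fold_threshold) for r in recs]
        needed = min(min_positive_replicates, len(recs))
        if sum(c.positive for c in calls) >= needed:
            n_positive += 1
            mean_od = sum(r.od_antigen for r in recs) / len(recs)
            if mean_od > 1.0:
                bins["high"] += 1
            elif mean_od >= 0.5:
                bins["medium"] += 1
            else:
                bins["low"] += 1
    n_screened = len(groups)
    return PanningRoundSummary(
        round_index=round_index,
        n_screened=n_screened,
        n_positive=n_positive,
        positivity_pct=percentage(n_positive, n_screened, 0),
        od_bins=bins,
        high_od_fraction_of_positives=(bins["high"] / n_positive) if n_positive else 0.0,
    )


def summarize_antigen(
    antigen: str,
    sequenced_ids: Sequence[str],
    sequences: Mapping[str, str],
) -> AntigenScreenSummary:
    """Unique-binder percentage among the clones sent for sequencing."""
    if not sequenced_ids:
        raise ValueError(f"antigen {antigen!r}: no sequenced clones")
    seqs = []
    for cid in sequenced_ids:
        if cid not in sequences:
            raise KeyError(f"antigen {antigen!r}: no sequence for clone {cid!r}")
        seqs.append(sequences[cid])
    n_unique = len(set(seqs))
    return AntigenScreenSummary(
        antigen=antigen,
        n_sequenced=len(seqs),
        n_unique=n_unique,
        unique_pct=percentage(n_unique, len(seqs), 0),
    )


def enrichment_trajectory(
    round_summaries: Sequence[PanningRoundSummary],
    antigen_summaries: Mapping[int, AntigenScreenSummary] | None = None,
) -> Trajectory:
    """Round-by-round positivity (and optionally uniqueness) trajectory.

    Monotonicity flags report whether positivity is nondecreasing and
    uniqueness nonincreasing across rounds — the expected enrichment pattern
    — without enforcing either.
    """
    if len(round_summaries) < 2:
        raise ValueError("a trajectory needs at least two rounds")
    ordered = sorted(round_summaries, key=lambda s: s.round_index)
    rows = []
    for s in ordered:
        row: dict[str, object] = {
            "round": s.round_index,
            "n_screened": s.n_screened,
            "n_positive": s.n_positive,
            "positivity_pct": s.positivity_pct,
        }
        if antigen_summaries and s.round_index in antigen_summaries:
            row["unique_pct"] = antigen_summaries[s.round_index].unique_pct
        rows.append(row)
    table = pd.DataFrame(rows)
    pos = [s.positivity_pct for s in ordered]
    pos_flag = all(b >= a for a, b in zip(pos, pos[1:]))
    uniq_flag: bool | None = None
    if antigen_summaries and "unique_pct" in table:
        uniq = table["unique_pct"].dropna().tolist()
        if len(uniq) >= 2:
            uniq_flag = all(b <= a for a, b in zip(uniq, uniq[1:]))
    return Trajectory(table=table, positivity_nondecreasing=pos_flag, uniqueness_nonincreasing=uniq_flag)


def records_from_table(df: pd.DataFrame) -> list[ElisaRecord]:
    """Long-format ELISA table -> records.

    Expected columns: clone_id, round, replicate, channel, od. The channel
    ``antigen`` is the signal; every other channel is a negative control.
    """
    records = []
    keys = ["clone_id", "round", "replicate"]
    for (cid, rnd, rep), grp in df.groupby(keys, sort=False):
        od_antigen = None
        negatives: dict[str, float] = {}
        for _, row in grp.iterrows():
            if row["channel"] == "antigen":
                od_antigen = float(row["od"])
            else:
                negatives[str(row["channel"])] = float(row["od"])
        if od_antigen is None:
            raise ValueError(f"clone {cid!r} round {rnd} rep {rep}: no antigen channel")
        records.append(
            ElisaRecord(
                clone_id=str(cid),
                round_index=int(rnd),
                od_antigen=od_antigen,
                od_negatives=negatives,
                replicate=int(rep),
            )
        )
    return records


def records_to_table(records: Iterable[ElisaRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {"clone_id": rec.clone_id, "round": rec.round_index, "replicate": rec.replicate,
             "channel": "antigen", "od": rec.od_antigen}
        )
        for name, od in rec.od_negatives.items():
            rows.append(
                {"clone_id": rec.clone_id, "round": rec.round_index, "replicate": rec.replicate,
                 "channel": name, "od": od}
            )
    return pd.DataFrame(rows)


def read_elisa_tsv(path: str | Path) -> list[ElisaRecord]:
    return records_from_table(pd.read_csv(path, sep="\t"))


def write_elisa_tsv(records: Iterable[ElisaRecord], path: str | Path) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)
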