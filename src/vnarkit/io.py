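"""Sequence input/output and open-reading-frame quality control.

vNAR inserts are cloned between an NcoI site (CCATGG, which embeds the ATG
start codon) and a NotI site (GCGGCCGC). A clone is useful downstream only if
both flanks are present and the region from the ATG translates without a stop
codon or frameshift — defective ("bald") clones carry exactly those lesions.

Reading-frame geometry. In this construct the NotI site sits in frame such
that its first two bases complete the final codon of the insert: the coding
region runs from the ATG inside CCATGG through the ``GC`` that opens
GCGGCCGC. Its length therefore equals ``NotI_start - NcoI_start`` and is a
multiple of three for an intact insert (e.g. CCATGG + 330 nt + GCGGCCGC gives
a 336-nt coding region and a 112-residue domain).
"""

from __future__ import annotations

import gzip
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

NCOI_SITE = "CCATGG"
NOTI_SITE = "GCGGCCGC"

_NT_ALPHABET = frozenset("ACGTN")

QcFlag = Literal[
    "missing_5p_flank",
    "missing_3p_flank",
    "premature_stop",
    "frameshift",
    "too_short",
    "untranslatable",
]

#: Flags that preclude a usable translation product.
FATAL_FLAGS = frozenset({"premature_stop", "frameshift", "untranslatable"})


@dataclass
class NucleotideClone:
    """One cloned insert read from Sanger/NGS/synthetic sequencing."""

    clone_id: str
    sequence: str
    source: str = "synthetic"
    round_index: int | None = None
    mean_quality: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id!r}: empty sequence")
        bad = set(self.sequence) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"clone {self.clone_id!r}: invalid nucleotide(s) {sorted(bad)}"
            )


@dataclass
class FlankScan:
    """Result of searching a clone for its cloning-site flanks."""

    found_5p: bool
    found_3p: bool
    insert_span: tuple[int, int] | None  # 0-based half-open, coding region
    orientation: Literal["forward", "reverse"]
    oriented_sequence: str
    flank_5p_start: int | None = None
    flank_3p_start: int | None = None


@dataclass
class CloneRecord:
    """A clone after translation and QC.

    ``aa`` is present exactly when no fatal flag (premature_stop, frameshift,
    untranslatable) is set; ``too_short`` marks a suspiciously short but
    otherwise clean product without discarding it.
    """

    clone_id: str
    nt: str
    aa: str | None
    frame_offset: int
    qc_flags: set[str] = field(default_factory=set)
    is_complete_insert: bool = False

    def __post_init__(self) -> None:
        fatal = self.qc_flags & FATAL_FLAGS
        if (self.aa is None) != bool(fatal):
            raise ValueError(
                f"clone {self.clone_id!r}: aa presence inconsistent with flags {self.qc_flags}"
            )
        if self.aa is not None and "*" in self.aa:
            raise ValueError(f"clone {self.clone_id!r}: internal stop in aa")


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _infer_format(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def read_sequences(
    path: str | Path,
    format: str | None = None,
    source: str = "ngs",
) -> list[NucleotideClone]:
    """Read FASTA/FASTQ (gzip-transparent) into NucleotideClone records.

    FASTQ qualities are reduced to a per-read mean and not otherwise used.
    Duplicate IDs raise; an empty file returns ``[]`` with a warning.
    """
    fmt = format or _infer_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {fmt!r}")
    clones: list[NucleotideClone] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {fmt} record #{index}: {exc}") from exc
            if rec.id in seen:
                raise ValueError(f"duplicate sequence ID {rec.id!r}")
            seen.add(rec.id)
            mean_q = None
            if fmt == "fastq":
                quals = rec.letter_annotations.get("phred_quality")
                if quals:
                    mean_q = float(statistics.fmean(quals))
            clones.append(
                NucleotideClone(
                    clone_id=rec.id,
                    sequence=str(rec.seq),
                    source=source,
                    mean_quality=mean_q,
                )
            )
            index += 1
    if not clones:
        warnings.warn(f"no sequence records in {path}", stacklevel=2)
    return clones


def write_fasta(clones: Iterable[NucleotideClone], path: str | Path) -> None:
    with open(path, "w") as handle:
        for clone in clones:
            handle.write(f">{clone.clone_id}\n{clone.sequence}\n")


def _reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_strand(seq: str, flank_5p: str, flank_3p: str):
    """First 5' occurrence, last 3' occurrence: maximizes the insert length."""
    i5 = seq.find(flank_5p)
    j3 = seq.rfind(flank_3p)
    found_5p = i5 >= 0
    found_3p = j3 >= 0
    span = None
    if found_5p and found_3p and j3 >= i5 + len(flank_5p):
        atg = flank_5p.find("ATG")
        if atg >= 0:
            # coding region: ATG inside the 5' site through the first two
            # bases of the 3' site (which complete the final codon)
            span = (i5 + atg, j3 + 2)
    return found_5p, found_3p, span, (i5 if found_5p else None), (j3 if found_3p else None)


def detect_flanks(
    clone: NucleotideClone | str,
    flank_5p: str = NCOI_SITE,
    flank_3p: str = NOTI_SITE,
    try_reverse_complement: bool = True,
) -> FlankScan:
    """Locate the cloning-site flanks and the coding insert span.

    The search is exact-match. Because both restriction sites are palindromic
    they appear on either strand of a true read; the strand is therefore
    chosen as the one with a valid 5'-site-before-3'-site span (amplicon
    reads may come in either orientation), and the reported span refers to
    the re-oriented sequence.
    """
    if not flank_5p or not flank_3p:
        raise ValueError("flank motifs must be non-empty")
    seq = clone.sequence if isinstance(clone, NucleotideClone) else clone.upper()
    f5, f3, span, i5, j3 = _scan_strand(seq, flank_5p, flank_3p)
    orientation = "forward"
    oriented = seq
    if span is None and try_reverse_complement:
        rc = _reverse_complement(seq)
        rf5, rf3, rspan, ri5, rj3 = _scan_strand(rc, flank_5p, flank_3p)
        if rspan is not None or (not f5 and rf5):
            f5, f3, span, i5, j3 = rf5, rf3, rspan, ri5, rj3
            orientation = "reverse"
            oriented = rc
    return FlankScan(
        found_5p=f5,
        found_3p=f3,
        insert_span=span,
        orientation=orientation,
        oriented_sequence=oriented,
        flank_5p_start=i5,
        flank_3p_start=j3,
    )


def translate_and_qc(
    clone: NucleotideClone,
    min_aa_length: int = 80,
    flank_5p: str = NCOI_SITE,
    flank_3p: str = NOTI_SITE,
) -> CloneRecord:
    """Translate a cloned insert and attach the QC flags of defective clones.

    Translation starts at the ATG embedded in the 5' flank. ``frameshift`` is
    set when the coding region (ATG through the frame-completing bases of the
    3' flank) is not a codon multiple; ``premature_stop`` when a stop codon
    occurs before the 3' flank; ``untranslatable`` when no ATG is available
    under the flank policy; ``too_short`` (non-fatal) when the product is
    shorter than ``min_aa_length`` residues.
    """
    scan = detect_flanks(clone, flank_5p=flank_5p, flank_3p=flank_3p)
    flags: set[str] = set()
    if not scan.found_5p:
        flags.add("missing_5p_flank")
    if not scan.found_3p:
        flags.add("missing_3p_flank")
    complete = scan.found_5p and scan.found_3p

    aa: str | None = None
    frame_offset = 0
    atg_rel = flank_5p.find("ATG")
    if not scan.found_5p or atg_rel < 0:
        flags.add("untranslatable")
    else:
        seq = scan.oriented_sequence
        atg = scan.flank_5p_start + atg_rel
        frame_offset = atg % 3
        if scan.insert_span is not None:
            coding = seq[scan.insert_span[0] : scan.insert_span[1]]
            if len(coding) % 3 != 0:
                flags.add("frameshift")
        else:
            # 3' flank missing: translate to the last complete codon; the
            # frame at the 3' end cannot be assessed.
            tail = seq[atg:]
            coding = tail[: len(tail) - len(tail) % 3]
        if "frameshift" not in flags:
            if not coding:
                flags.add("untranslatable")
            else:
                product = str(Seq(coding).translate())
                if "*" in product:
                    flags.add("premature_stop")
                else:
                    aa = product
                    if len(aa) < min_aa_length:
                        flags.add("too_short")
    return CloneRecord(
        clone_id=clone.clone_id,
        nt=clone.sequence,
        aa=aa,
        frame_offset=frame_offset,
        qc_flags=flags,
        is_complete_insert=complete,
    )


def completeness_rate(records: Sequence[CloneRecord]) -> float:
    """Fraction of clones carrying both cloning-site flanks."""
    if not records:
        raise ValueError("completeness_rate of an empty record list")
    return sum(r.is_complete_insert for r in records) / len(records)


def records_table(records: Iterable[CloneRecord]) -> pd.DataFrame:
    """CloneRecords as a flat table (TSV-friendly)."""
    return pd.DataFrame(
        {
            "clone_id": r.clone_id,
            "frame_offset": r.frame_offset,
            "qc_flags": ";".join(sorted(r.qc_flags)),
            "is_complete_insert": r.is_complete_insert,
            "aa": r.aa or "",
        }
        for r in records
    )


def write_records_tsv(records: Iterable[CloneRecord], path: str | Path) -> None:
    records_table(records).to_csv(path, sep="\t", index=False)
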