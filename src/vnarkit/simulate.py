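"""Synthetic vNAR repertoire and panning-dataset generation.

Sequencing reads for the characterized naive library are not publicly
deposited, so every pipeline stage is exercised on labeled synthetic
libraries that reproduce the published *statistical structure*: the
five-type composition, CDR3 lengths on 6-28 with roughly
half the clones at 15-16, per-type CDR3 cysteine counts on 0-5, a conserved
CDR1 leucine (position 31, default probability 0.95), NcoI/NotI cloning-site
flanks, and controllable clone-defect rates.

Clones are built on a single fixed framework scaffold (canonical cysteines at
scheme positions 22 and 83, a ``YG.G``-type FR4 anchor) with light framework
substitution noise; loop content is random but constructed so the clone's
evidence tuple fires exactly its intended classification rule. Type counts,
duplicate counts and defect counts are apportioned exactly (largest
remainder / rounding) rather than sampled, so small libraries match their
spec precisely while the sequence content stays stochastic. All randomness
flows through one seeded generator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from math import exp
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .classify import TYPE_LABELS
from .io import NCOI_SITE, NOTI_SITE, NucleotideClone
from .panning import ElisaRecord

# Fixed framework scaffold, segment by segment (1-based scheme positions).
SCAFFOLD_FR1 = "MARVDQTPQTITKETGESLTICVL"  # 1-24, Cys22
CDR1_TEMPLATE = "TSSNAYLST"  # 25-33; position 29='A', 30='Y', Leu31
SCAFFOLD_FR2 = "ESISDLTYRE"  # 34-43
SCAFFOLD_HV2 = "TSKDNKAS"  # 44-51
SCAFFOLD_FR3A = "GRFVETVN"  # 52-59
SCAFFOLD_HV4 = "SNKERM"  # 60-65
SCAFFOLD_FR3B = "SLTIRDLRVEDSGTYKACKVE"  # 66-86, Cys83
SCAFFOLD_FR4 = "YGGGTAVTVNPGSGSS"  # FR4 anchor [YW]G.G at its start

_FRAMEWORK_LEN = (
    len(SCAFFOLD_FR1) + len(CDR1_TEMPLATE) + len(SCAFFOLD_FR2) + len(SCAFFOLD_HV2)
    + len(SCAFFOLD_FR3A) + len(SCAFFOLD_HV4) + len(SCAFFOLD_FR3B) + len(SCAFFOLD_FR4)
)  # 102; protein length = 102 + CDR3 length

#: One sense codon per amino acid. Ala starts with G (completing CCATG|G...)
#: and Ser ends with GC (the NotI site's GC completes the final codon).
CODON = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

_PAD_5P = "GATT"
_PAD_3P = "AATTC"

_LOOP_ALPHABET = "ADEFGHIKLMNPQRSTVWY"  # no Cys: cysteines are placed explicitly
_CDR1_MUT_ALPHABET = "ADEFGHIKMNPQRSTVY"  # no C/W/L
# substitution alphabet excludes C, G, W, Y so anchors, the FR4 motif and the
# type rules can never be disturbed by framework noise
_SUB_ALPHABET = "ADEFHIKLMNPQRSTV"

_FR4_MOTIF = re.compile(r"[YW]G.G")


def default_cdr3_length_model(
    lo: int = 6, hi: int = 28, band: tuple[int, int] = (15, 16), band_mass: float = 0.5
) -> dict[int, float]:
    """Discrete CDR3 length model: Gaussian-shaped on [lo, hi] with the modal
    band (default 15-16) renormalized to carry ``band_mass`` of the total."""
    center = (band[0] + band[1]) / 2
    raw = {L: exp(-((L - center) ** 2) / (2 * 4.5**2)) for L in range(lo, hi + 1)}
    in_band = {L: w for L, w in raw.items() if band[0] <= L <= band[1]}
    out_band = {L: w for L, w in raw.items() if L not in in_band}
    model = {}
    for L, w in in_band.items():
        model[L] = band_mass * w / sum(in_band.values())
    for L, w in out_band.items():
        model[L] = (1 - band_mass) * w / sum(out_band.values())
    return dict(sorted(model.items()))


#: Per-type CDR3 cysteine-count models, each consistent with its type rule.
DEFAULT_CDR3_CYS_MODELS: dict[str, dict[int, float]] = {
    "I": {2: 0.85, 4: 0.15},
    "IIa": {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03},
    "IIb": {1: 0.85, 3: 0.15},  # CDR3-only branch; CDR1-only branch uses 0
    "III": {1: 1.0},
    "IV": {0: 1.0},
}

DEFECT_KINDS = ("missing_flank", "premature_stop", "frameshift")


@dataclass
class LibrarySpec:
    """Parameters of a synthetic naive library.

    Defaults encode the study conditions: type composition from the NGS
    characterization, CDR3 lengths 6-28 with ~50% mass at 15-16, per-type
    CDR3 cysteine counts on 0-5, Leu31 probability 0.95.
    """

    n_clones: int
    type_proportions: dict[str, float] = field(default_factory=lambda: fig3a_proportions())
    cdr3_length_model: dict[int, float] = field(default_factory=default_cdr3_length_model)
    cdr3_cys_models: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CDR3_CYS_MODELS.items()}
    )
    leu31_prob: float = 0.95
    defect_rates: dict[str, float] = field(default_factory=dict)
    duplicate_rate: float = 0.0
    framework_sub_rate: float = 0.01
    iib_cdr1_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if set(self.type_proportions) - set(TYPE_LABELS):
            raise ValueError(f"unknown type labels {set(self.type_proportions) - set(TYPE_LABELS)}")
        if abs(sum(self.type_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if any(p < 0 for p in self.type_proportions.values()):
            raise ValueError("type proportions must be non-negative")
        total = sum(self.cdr3_length_model.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("CDR3 length model must sum to 1")
        if any(L < 5 for L in self.cdr3_length_model):
            raise ValueError("CDR3 lengths below 5 cannot hold the maximum Cys count")
        for label, model in self.cdr3_cys_models.items():
            if abs(sum(model.values()) - 1.0) > 1e-9:
                raise ValueError(f"type {label} Cys model must sum to 1")
            if any(k < 0 or k > 5 for k in model):
                raise ValueError(f"type {label} Cys counts must lie in 0..5")
            if label == "I" and any(k < 2 or k % 2 for k in model):
                raise ValueError("type I requires even CDR3 Cys counts >= 2")
            if label == "IIa" and any(k < 1 for k in model):
                raise ValueError("type IIa requires >= 1 CDR3 Cys")
            if label == "IIb" and any(k % 2 == 0 for k in model):
                raise ValueError("type IIb CDR3-branch requires odd CDR3 Cys counts")
            if label == "IV" and set(model) != {0}:
                raise ValueError("type IV admits no CDR3 Cys")
        for kind, rate in self.defect_rates.items():
            if kind not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind {kind!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"defect rate for {kind!r} outside [0,1]")
        if sum(self.defect_rates.values()) > 1:
            raise ValueError("defect rates sum above 1")
        for name in ("leu31_prob", "duplicate_rate", "framework_sub_rate", "iib_cdr1_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0,1]")


@dataclass
class SyntheticClone:
    """A generated clone with its ground truth."""

    clone_id: str
    nt: str
    protein: str | None
    true_label: str
    true_regions: dict[str, tuple[int, int]]
    true_cdr3_span: tuple[int, int]
    defect: str | None = None


def largest_remainder(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` seats to labels by the largest-remainder method.

    Deterministic: floors first, then distributes the remaining seats in
    decreasing order of fractional remainder (ties broken by label order).
    """
    order = [label for label in TYPE_LABELS if label in proportions]
    order += [label for label in proportions if label not in order]
    quotas = {label: proportions[label] * n for label in order}
    counts = {label: int(quotas[label]) for label in order}
    short = n - sum(counts.values())
    by_remainder = sorted(
        order, key=lambda lb: (-(quotas[lb] - counts[lb]), order.index(lb))
    )
    for label in by_remainder[:short]:
        counts[label] += 1
    return counts


def _true_regions(cdr3_len: int) -> dict[str, tuple[int, int]]:
    return {
        "FR1": (1, 24),
        "CDR1": (25, 33),
        "FR2": (34, 43),
        "HV2": (44, 51),
        "FR3a": (52, 59),
        "HV4": (60, 65),
        "FR3b": (66, 86),
        "CDR3": (87, 86 + cdr3_len),
        "FR4": (87 + cdr3_len, 102 + cdr3_len),
    }


def _sample_cdr1(label: str, leu31: bool, rng: np.random.Generator) -> str:
    cdr1 = list(CDR1_TEMPLATE)
    if label == "III":
        cdr1[4] = "C"  # scheme position 29
        cdr1[5] = "W"  # scheme position 30
    elif label == "IIa" or label == "_IIb_cdr1":
        cdr1[2] = "C"  # scheme position 27 (not 29: rule III must not fire)
    if not leu31:
        cdr1[6] = str(rng.choice(list(_CDR1_MUT_ALPHABET)))
    return "".join(cdr1)


def _sample_cdr3(length: int, n_cys: int, rng: np.random.Generator) -> str:
    """Random CDR3 with exactly ``n_cys`` cysteines and no premature FR4-motif
    match (so annotation recovers the true span)."""
    for _ in range(1000):
        chars = [str(c) for c in rng.choice(list(_LOOP_ALPHABET), size=length)]
        if n_cys:
            for pos in rng.choice(length, size=n_cys, replace=False):
                chars[pos] = "C"
        cdr3 = "".join(chars)
        m = _FR4_MOTIF.search(cdr3 + SCAFFOLD_FR4)
        if m is not None and m.start() == length:
            return cdr3
    raise RuntimeError("could not sample a motif-free CDR3")  # pragma: no cover


def _apply_framework_noise(protein: list[str], rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    # FR2 + HV2 + FR3a + HV4: scheme positions 34-65 (0-based 33..64)
    for idx in range(33, 65):
        if rng.random() < rate:
            current = protein[idx]
            choices = [c for c in _SUB_ALPHABET if c != current]
            protein[idx] = str(rng.choice(choices))


def reverse_translate(protein: str) -> str:
    """Embed a scaffold protein in its cloning construct (fixed codon table).

    The first codon is the ATG inside CCATGG; the final codon is completed by
    the first two bases of GCGGCCGC.
    """
    coding = "".join(CODON[a] for a in protein)
    if not coding.startswith("ATGG") or not coding.endswith("GC"):
        raise ValueError("protein incompatible with the flank-embedded reading frame")
    return _PAD_5P + NCOI_SITE + coding[4:-2] + NOTI_SITE + _PAD_3P


def _build_clone(
    clone_id: str, label: str, spec: LibrarySpec, rng: np.random.Generator
) -> SyntheticClone:
    lengths = list(spec.cdr3_length_model)
    probs = np.array([spec.cdr3_length_model[L] for L in lengths])
    cdr3_len = int(rng.choice(lengths, p=probs / probs.sum()))

    cdr1_label = label
    cys_model = spec.cdr3_cys_models[label]
    if label == "IIb":
        if rng.random() < spec.iib_cdr1_fraction:
            cdr1_label = "_IIb_cdr1"  # Cys in CDR1 only
            n_cys = 0
        else:
            counts = list(cys_model)
            p = np.array([cys_model[k] for k in counts])
            n_cys = int(rng.choice(counts, p=p / p.sum()))
    else:
        counts = list(cys_model)
        p = np.array([cys_model[k] for k in counts])
        n_cys = int(rng.choice(counts, p=p / p.sum()))

    leu31 = bool(rng.random() < spec.leu31_prob)
    cdr1 = _sample_cdr1(cdr1_label, leu31, rng)
    cdr3 = _sample_cdr3(cdr3_len, n_cys, rng)
    protein = list(
        SCAFFOLD_FR1 + cdr1 + SCAFFOLD_FR2 + SCAFFOLD_HV2 + SCAFFOLD_FR3A
        + SCAFFOLD_HV4 + SCAFFOLD_FR3B + cdr3 + SCAFFOLD_FR4
    )
    _apply_framework_noise(protein, spec.framework_sub_rate, rng)
    aa = "".join(protein)
    return SyntheticClone(
        clone_id=clone_id,
        nt=reverse_translate(aa),
        protein=aa,
        true_label=label,
        true_regions=_true_regions(cdr3_len),
        true_cdr3_span=(87, 86 + cdr3_len),
        defect=None,
    )


def _inject_defect(clone: SyntheticClone, kind: str) -> None:
    """Corrupt a clone's nucleotide sequence in place.

    missing_flank: one-base change in the NotI site; premature_stop: the FR2
    codon at scheme position 40 becomes TAA; frameshift: one base deleted
    mid-insert.
    """
    nt = clone.nt
    atg = len(_PAD_5P) + 2
    if kind == "missing_flank":
        j = nt.rfind(NOTI_SITE)
        nt = nt[: j + 3] + "T" + nt[j + 4 :]
    elif kind == "premature_stop":
        k = atg + 3 * 39  # codon for scheme position 40
        nt = nt[:k] + "TAA" + nt[k + 3 :]
    elif kind == "frameshift":
        k = atg + 3 * 50
        nt = nt[:k] + nt[k + 1 :]
    else:  # pragma: no cover
        raise ValueError(f"unknown defect kind {kind!r}")
    clone.nt = nt
    clone.defect = kind
    clone.protein = None  # ground-truth protein no longer applies


def generate_library(
    spec: LibrarySpec, rng: np.random.Generator | None = None
) -> list[SyntheticClone]:
    """Generate a labeled synthetic library.

    Per-type counts follow largest-remainder apportionment of the spec
    proportions (exact at any n); duplicate and defect counts are rounded
    counts, not Bernoulli draws. Deterministic for a given seed.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = largest_remainder(spec.type_proportions, spec.n_clones)
    labels: list[str] = []
    for label in TYPE_LABELS:
        labels.extend([label] * counts.get(label, 0))
    rng.shuffle(labels)

    clones = [
        _build_clone(f"syn{i + 1:06d}", label, spec, rng)
        for i, label in enumerate(labels)
    ]

    n_dup = int(round_half_up(spec.duplicate_rate * spec.n_clones))
    if n_dup:
        targets = rng.choice(spec.n_clones, size=n_dup, replace=False)
        by_label: dict[str, list[int]] = {}
        for i, clone in enumerate(clones):
            by_label.setdefault(clone.true_label, []).append(i)
        for t in sorted(int(x) for x in targets):
            pool = [i for i in by_label[clones[t].true_label] if i != t]
            if not pool:
                continue
            src = clones[int(rng.choice(pool))]
            clones[t] = replace(src, clone_id=clones[t].clone_id)

    defect_counts = {
        kind: int(round_half_up(rate * spec.n_clones))
        for kind, rate in sorted(spec.defect_rates.items())
    }
    n_defect = sum(defect_counts.values())
    if n_defect:
        chosen = [int(x) for x in rng.choice(spec.n_clones, size=n_defect, replace=False)]
        pos = 0
        for kind, k in defect_counts.items():
            for idx in chosen[pos : pos + k]:
                _inject_defect(clones[idx], kind)
            pos += k
    return clones


def library_to_clones(library: Iterable[SyntheticClone], source: str = "synthetic") -> list[NucleotideClone]:
    """Synthetic clones as read-like NucleotideClone inputs for the pipeline."""
    return [NucleotideClone(c.clone_id, c.nt, source=source) for c in library]


def ground_truth_table(library: Iterable[SyntheticClone]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clone_id": c.clone_id,
            "true_label": c.true_label,
            "cdr3_start": c.true_cdr3_span[0],
            "cdr3_end": c.true_cdr3_span[1],
            "defect": c.defect or "",
        }
        for c in library
    )


def write_library(
    library: Sequence[SyntheticClone], fasta_path: str | Path, truth_path: str | Path
) -> None:
    with open(fasta_path, "w") as handle:
        for c in library:
            handle.write(f">{c.clone_id}\n{c.nt}\n")
    ground_truth_table(library).to_csv(truth_path, sep="\t", index=False)


def generate_panning_dataset(
    binder_fraction_by_round: Sequence[float],
    n_screened_per_round: int = 30,
    seed: int = 0,
    od_model: Mapping[str, object] | None = None,
    first_round: int = 2,
    controls: Sequence[str] = ("BSA", "milk"),
    replicates: int = 1,
) -> tuple[list[ElisaRecord], dict[tuple[int, str], bool]]:
    """Synthetic phage-ELISA screens with known binders per round.

    Positive counts per round are exact (rounded from the fraction). Positive
    clones draw antigen ODs from a truncated normal whose mean rises across
    rounds (default 0.75 -> 1.2, sd 0.35, emulating the observed shift toward
    high-OD binders by round four) and always clears four-fold over the
    strongest negative; non-binders draw folds strictly below four. Returns
    the records plus ground truth keyed by (round, clone_id).
    """
    if any(not 0 <= f <= 1 for f in binder_fraction_by_round):
        raise ValueError("binder fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)
    model = {
        "neg_lo": 0.05,
        "neg_hi": 0.15,
        "pos_sigma": 0.35,
        "pos_cap": 3.5,
        "pos_mu": None,
    }
    if od_model:
        model.update(od_model)
    n_rounds = len(binder_fraction_by_round)
    if model["pos_mu"] is None:
        mus = np.linspace(0.75, 1.2, n_rounds) if n_rounds > 1 else [1.2]
    else:
        mus = model["pos_mu"]
        if np.isscalar(mus):
            mus = [float(mus)] * n_rounds

    n = n_screened_per_round
    records: list[ElisaRecord] = []
    truth: dict[tuple[int, str], bool] = {}
    for ri, frac in enumerate(binder_fraction_by_round):
        rnd = first_round + ri
        n_pos = int(round_half_up(frac * n))
        positives = set(int(x) for x in rng.choice(n, size=n_pos, replace=False)) if n_pos else set()
        for i in range(n):
            cid = f"BP{rnd}_{i + 1:03d}"
            is_pos = i in positives
            truth[(rnd, cid)] = is_pos
            for rep in range(1, replicates + 1):
                negs = {
                    c: float(rng.uniform(model["neg_lo"], model["neg_hi"])) for c in controls
                }
                max_neg = max(negs.values())
                if is_pos:
                    od = float(rng.normal(mus[ri], model["pos_sigma"]))
                    od = float(np.clip(od, 4.0 * max_neg * 1.02, model["pos_cap"]))
                else:
                    od = float(rng.uniform(0.2, 3.0)) * max_neg
                records.append(
                    ElisaRecord(
                        clone_id=cid,
                        round_index=rnd,
                        od_antigen=od,
                        od_negatives=negs,
                        replicate=rep,
                    )
                )
    return records, truth


# ---------------------------------------------------------------------------
# Published-count presets (inputs for scaled replication and worked examples)

#: Per-type counts of unique vNAR protein sequences in the naive-library NGS
#: characterization (238,415 total).
FIG3A_COUNTS: dict[str, int] = {
    "I": 36_256,
    "IIa": 57_112,
    "IIb": 98_849,
    "III": 8,
    "IV": 46_190,
}

#: Number of clones whose CDR3 is unique among the 238,415 unique sequences.
N_UNIQUE_CDR3 = 91_600

#: CDR3 cysteine-count composition among the unique CDR3s.
FIG3C_CDR3_CYS_COUNTS: dict[int, int] = {0: 29_367, 1: 46_823, 2: 14_395, 3: 934}

#: Per-antigen screening outcomes: antigen -> (clones sequenced, unique clones).
TABLE1_SCREENING: dict[str, tuple[int, int]] = {
    "RBD": (10, 3),
    "JEV Env": (16, 12),
    "SORT1": (8, 8),
    "BAFF": (13, 7),
    "parasite protein": (11, 9),
    "plant protein": (14, 12),
    "toxin": (11, 8),
    "algal protein": (14, 7),
    "SEZ6": (10, 7),
}

#: Per-round phage-ELISA positivity: round -> (positives, screened).
ROUND_POSITIVITY: dict[int, tuple[int, int]] = {2: (3, 30), 3: (6, 30), 4: (12, 30)}


def fig3a_proportions() -> dict[str, float]:
    total = sum(FIG3A_COUNTS.values())
    return {label: n / total for label, n in FIG3A_COUNTS.items()}


def fig3a_spec(n_clones: int, seed: int = 0, **overrides) -> LibrarySpec:
    """LibrarySpec preset with the published type composition and no defects,
    for scaled replication of the repertoire characterization."""
    kwargs = dict(
        n_clones=n_clones,
        type_proportions=fig3a_proportions(),
        defect_rates={},
        duplicate_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return LibrarySpec(**kwargs)
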