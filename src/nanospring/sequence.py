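"""Sequence-level disorder metrics for elastomeric proteins.

Intrinsically disordered proteins are classically separated from natively
folded ones on the charge-hydropathy plane: low mean Kyte-Doolittle
hydropathy (5-residue window, rescaled to [0, 1]) combined with high mean
net charge predicts disorder, with the empirical boundary
R = 2.785 H - 1.151.  Silk-like elastomers such as Cnidoin are unusual in
combining high hydrophobicity (folded side of the boundary) with
glycine/proline-rich composition that nevertheless prevents folding, so the
module also reports amino-acid composition and scans for the conserved
elastic motif GXGQQ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DisorderMetrics",
    "KYTE_DOOLITTLE",
    "read_fasta",
    "aa_composition",
    "uversky_metrics",
    "classify_charge_hydropathy",
    "scan_motif",
    "CNIDOIN_REPEAT_1",
    "CNIDOIN_REPEAT_2",
    "CRD_ANTIGEN",
    "YBBR_TAG",
]

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_VALID = set(KYTE_DOOLITTLE) | {"X"}

# Peptides printed with the study: two Cnidoin repetitive sequence units,
# the cysteine-rich-domain antigen, and the ybbR attachment tag.
CNIDOIN_REPEAT_1 = "QMQGCGQQMPPMMSGCGG"
CNIDOIN_REPEAT_2 = "QMQGCGQQLPLMMPGCVG"
CRD_ANTIGEN = "GCAPSCQQQCIPSCPRGCCGA"
YBBR_TAG = "DSLEFIASKLA"

#: Charge-hydropathy boundary R = CH_SLOPE * H - CH_INTERCEPT.
CH_SLOPE = 2.785
CH_INTERCEPT = 1.151


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (one-letter codes; X tolerated)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - _VALID
        if bad:
            raise ValueError(f"invalid residues in {self.id}: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class DisorderMetrics:
    """Charge-hydropathy classification and composition of one sequence."""

    mean_hydropathy: float
    mean_net_charge: float
    boundary_distance: float
    classification: str  # "ordered-region" | "disordered-region"
    composition: dict[str, float] = field(default_factory=dict)


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def aa_composition(seq: SequenceRecord) -> dict[str, float]:
    """Per-residue-type fractions; X is excluded from the denominator."""
    residues = [r for r in seq.residues if r != "X"]
    if not residues:
        raise ValueError("empty sequence (or X only)")
    n = len(residues)
    comp: dict[str, float] = {}
    for r in residues:
        comp[r] = comp.get(r, 0.0) + 1.0
    return {r: c / n for r, c in sorted(comp.items())}


def _rescaled_hydropathy(residues: str) -> list[float]:
    return [(KYTE_DOOLITTLE[r] + 4.5) / 9.0 for r in residues if r != "X"]


def classify_charge_hydropathy(mean_hydropathy: float, mean_net_charge: float):
    """Charge-hydropathy boundary rule.

    Disordered iff R > 2.785 H - 1.151; points exactly on the boundary are
    assigned to the ordered side.  Returns ``(classification,
    boundary_distance)`` where the distance is R - (2.785 H - 1.151)
    (positive on the disordered side).
    """
    boundary = CH_SLOPE * mean_hydropathy - CH_INTERCEPT
    distance = mean_net_charge - boundary
    label = "disordered-region" if distance > 0 else "ordered-region"
    return label, distance


def uversky_metrics(
    seq: SequenceRecord, window: int = 5, mode: str = "windowed"
) -> DisorderMetrics:
    """Mean hydropathy, mean net charge and the boundary classification.

    Hydropathy is the Kyte-Doolittle value rescaled to [0, 1] via
    (h + 4.5)/9, averaged over sliding windows of ``window`` residues
    (``mode="windowed"``, the plot convention) or per residue
    (``mode="residue"``).  Net charge counts K/R as +1 and D/E as -1 at
    neutral pH and reports |net| / length.
    """
    residues = seq.residues.replace("X", "")
    if len(residues) < window:
        raise ValueError(f"sequence shorter than the {window}-residue window")
    h = _rescaled_hydropathy(residues)
    if mode == "windowed":
        means = [
            sum(h[i : i + window]) / window for i in range(len(h) - window + 1)
        ]
        mean_h = sum(means) / len(means)
    elif mode == "residue":
        mean_h = sum(h) / len(h)
    else:
        raise ValueError("mode must be 'windowed' or 'residue'")
    pos = sum(residues.count(r) for r in "KR")
    neg = sum(residues.count(r) for r in "DE")
    mean_r = abs(pos - neg) / len(residues)
    label, distance = classify_charge_hydropathy(mean_h, mean_r)
    return DisorderMetrics(
        mean_hydropathy=mean_h,
        mean_net_charge=mean_r,
        boundary_distance=distance,
        classification=label,
        composition=aa_composition(seq),
    )


def scan_motif(seq: SequenceRecord, pattern: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of a motif.

    ``X`` in the pattern matches any residue (conventionally written GXGQQ
    for the shared silk/Cnidoin elastic motif).
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    regex = "".join("." if ch == "X" else re.escape(ch) for ch in pattern.upper())
    return [m.start() + 1 for m in re.finditer(f"(?=({regex}))", seq.residues)]
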