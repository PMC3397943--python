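"""Shannon-entropy sequence conservation over a multiple alignment.

Per-column entropy is computed for two alphabets: the full 21-letter
alphabet (20 amino acids plus the gap character) and a reduced 7-letter
alphabet in which amino acids are pooled into six physicochemical
classes (plus gap).  Scores are normalised to [0, 1] so that fully
conserved columns score 1 and maximally diverse columns score 0:

    C = 1 - S / log2(N),   S = -sum_i p_i log2 p_i

with N the alphabet size.  Columns where more than 30% of sequences
carry a gap are masked out of all conservation calls; a column is
called conserved when either normalised score exceeds 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "Alignment",
    "SEVEN_CLASS_GROUPS",
    "column_entropy",
    "normalized_conservation",
    "mask_gappy",
    "call_conserved",
    "conservation_profile",
    "map_alignment_to_structure",
    "read_alignment",
]

#: Reduced-alphabet pooling: aliphatic, aromatic, polar, positive,
#: negative, special-conformation; gap is its own seventh class.
SEVEN_CLASS_GROUPS: dict[str, tuple[str, ...]] = {
    "aliphatic": ("A", "V", "L", "I", "M", "C"),
    "aromatic": ("F", "W", "Y", "H"),
    "polar": ("S", "T", "N", "Q"),
    "positive": ("K", "R"),
    "negative": ("D", "E"),
    "special": ("G", "P"),
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CLASS_OF = {aa: cls for cls, members in SEVEN_CLASS_GROUPS.items() for aa in members}


@dataclass
class Alignment:
    """A gapped multiple sequence alignment.

    All rows have equal length; letters are the 20 amino acids, the gap
    character, or 'X' (treated as missing and dropped column-wise).
    """

    sequences: list[tuple[str, str]]
    gap: str = "-"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        self.sequences = [(i, s.upper().replace(".", self.gap)) for i, s in self.sequences]

    @property
    def n_seq(self) -> int:
        return len(self.sequences)

    @property
    def n_col(self) -> int:
        return len(self.sequences[0][1])

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.sequences)

    def row(self, row_id: str) -> str:
        for i, s in self.sequences:
            if i == row_id:
                return s
        raise KeyError(f"no alignment row with id {row_id!r}")


def read_alignment(source, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file into an Alignment."""
    msa = AlignIO.read(source, fmt)
    return Alignment(sequences=[(rec.id, str(rec.seq)) for rec in msa])


def _column_counts(column, alphabet: int, gap: str) -> np.ndarray:
    symbols = [c for c in column if c != "X"]
    if not symbols:
        raise ValueError("column empty after dropping missing (X) entries")
    if alphabet == 21:
        classes = list(_AA20) + [gap]
        keyed = symbols
    elif alphabet == 7:
        classes = list(SEVEN_CLASS_GROUPS) + [gap]
        keyed = [gap if c == gap else _CLASS_OF.get(c, c) for c in symbols]
    else:
        raise ValueError("alphabet must be 21 or 7")
    counts = np.zeros(len(classes))
    index = {c: i for i, c in enumerate(classes)}
    for c in keyed:
        if c not in index:
            raise ValueError(f"unknown letter {c!r} in alignment column")
        counts[index[c]] += 1
    return counts


def column_entropy(column, alphabet: int = 21, gap: str = "-") -> float:
    """Shannon entropy S (bits) of one alignment column.

    ``alphabet`` is 21 (amino acids + gap) or 7 (six physicochemical
    classes + gap).  Rows with 'X' are dropped first; any other
    unrecognised letter raises.
    """
    counts = _column_counts(column, alphabet, gap)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def normalized_conservation(s_bits: float, alphabet: int) -> float:
    """Normalise entropy to a conservation score C = 1 - S/log2(N) in [0,1]."""
    smax = np.log2(alphabet)
    if not 0 <= s_bits <= smax + 1e-9:
        raise ValueError(f"entropy {s_bits} outside [0, log2({alphabet})]")
    return float(1.0 - min(s_bits, smax) / smax)


def mask_gappy(alignment: Alignment, max_gap_fraction: float = 0.30) -> np.ndarray:
    """Mask columns whose gap fraction strictly exceeds the threshold."""
    n = alignment.n_seq
    fractions = np.array(
        [alignment.column(j).count(alignment.gap) / n for j in range(alignment.n_col)]
    )
    return fractions > max_gap_fraction


def call_conserved(profile: pd.DataFrame, threshold: float = 0.6) -> np.ndarray:
    """Conserved iff (C21 > threshold OR C7 > threshold) and not masked."""
    hit = (profile["c21"] > threshold) | (profile["c7"] > threshold)
    return (hit & ~profile["masked"]).to_numpy()


def conservation_profile(
    alignment: Alignment,
    threshold: float = 0.6,
    max_gap_fraction: float = 0.30,
) -> pd.DataFrame:
    """Per-column conservation table.

    Columns: entropy21, entropy7 (bits), c21, c7 (normalised scores),
    gap_fraction, masked, conserved.  Metadata ``attrs['n_seq']`` is
    retained.
    """
    rows = []
    masked = mask_gappy(alignment, max_gap_fraction)
    for j in range(alignment.n_col):
        col = alignment.column(j)
        s21 = column_entropy(col, 21, alignment.gap)
        s7 = column_entropy(col, 7, alignment.gap)
        rows.append(
            {
                "entropy21": s21,
                "entropy7": s7,
                "c21": normalized_conservation(s21, 21),
                "c7": normalized_conservation(s7, 7),
                "gap_fraction": col.count(alignment.gap) / alignment.n_seq,
                "masked": bool(masked[j]),
            }
        )
    profile = pd.DataFrame(rows, index=pd.RangeIndex(alignment.n_col, name="column"))
    profile["conserved"] = call_conserved(profile, threshold)
    profile.attrs["n_seq"] = alignment.n_seq
    return profile


def map_alignment_to_structure(
    alignment: Alignment,
    reference_id: str,
    structure_labels: list[str],
    structure_sequence: str | None = None,
) -> dict[int, str]:
    """Map alignment columns to structure residue labels via a reference row.

    The reference row's ungapped sequence is matched to the structure's
    residue labels in order; the structure may be truncated at either
    terminus.  When ``structure_sequence`` is given it is checked
    against the reference (first mismatch reported).

    Returns {column index -> residue label}; gapped columns are absent.
    """
    ref = alignment.row(reference_id)
    ungapped_cols = [j for j, c in enumerate(ref) if c != alignment.gap]
    ref_seq = "".join(ref[j] for j in ungapped_cols)
    offset = 0
    if structure_sequence is not None:
        n = len(structure_sequence)
        if n > len(ref_seq):
            raise ValueError("structure sequence longer than reference row")
        for off in range(len(ref_seq) - n + 1):
            window = ref_seq[off : off + n]
            if all(a == b or a == "X" or b == "X" for a, b in zip(window, structure_sequence)):
                offset = off
                break
        else:
            mism = next(
                i for i in range(n) if ref_seq[i] != structure_sequence[i]
            )
            raise ValueError(
                f"reference row does not match structure sequence; first mismatch at "
                f"structure position {mism} ({ref_seq[mism]!r} vs {structure_sequence[mism]!r})"
            )
    n_map = min(len(structure_labels), len(ref_seq) - offset)
    return {
        ungapped_cols[offset + i]: structure_labels[i] for i in range(n_map)
    }
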