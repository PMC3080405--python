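"""Residue substitution matrices over the 20 amino acids plus the ``*`` padding symbol.

Peptide windows that overhang a protein terminus are completed with ``*``
pseudo-residues. A ``*`` carries no information, so every score involving it
is fixed at 0 — at initialization and forever after: the training mutation
operator is not allowed to touch ``*`` rows or columns.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids, in conventional BLOSUM row order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: Pseudo-residue used to pad windows past protein termini.
PAD = "*"
#: Full scoring alphabet.
ALPHABET = AMINO_ACIDS + PAD

_INDEX = {c: i for i, c in enumerate(ALPHABET)}
PAD_INDEX = _INDEX[PAD]
N_SYMBOLS = len(ALPHABET)

# fast char-code -> alphabet-index table; 255 marks an invalid symbol
_CODE_TABLE = np.full(128, 255, dtype=np.uint8)
for _c, _i in _INDEX.items():
    _CODE_TABLE[ord(_c)] = _i


def encode(sequence: str, allow_pad: bool = True) -> np.ndarray:
    """Encode a residue string as alphabet indices (uint8).

    Raises ``ValueError`` naming the offending symbol and its 1-based
    position if the string contains anything outside the alphabet.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _CODE_TABLE[np.minimum(raw, 127)]
    bad = np.nonzero(idx == 255)[0]
    if not allow_pad:
        bad = np.union1d(bad, np.nonzero(idx == PAD_INDEX)[0])
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"invalid residue symbol {sequence[i]!r} at position {i + 1}"
        )
    return idx


def decode(indices: Iterable[int]) -> str:
    """Inverse of :func:`encode`."""
    return "".join(ALPHABET[i] for i in indices)


class SubstitutionMatrix:
    """Integer score lookup over the 21-symbol alphabet.

    Value semantics: :meth:`mutate` returns a new matrix and never modifies
    the receiver, so a rejected training mutation can simply be discarded.
    """

    def __init__(self, scores: np.ndarray, label: str = ""):
        scores = np.asarray(scores)
        if scores.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError(
                f"expected a {N_SYMBOLS}x{N_SYMBOLS} score table, got {scores.shape}"
            )
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise ValueError("substitution scores must be integers")
        self._scores = scores.astype(np.int32, copy=True)
        self._scores.setflags(write=False)
        self.label = label

    # -- construction -----------------------------------------------------

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """Standard BLOSUM62, extended so every ``*``-involving score is 0."""
        src = substitution_matrices.load("BLOSUM62")
        table = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.int32)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                table[i, j] = int(src[a, b])
        # '*' row/column already 0
        return cls(table, label="BLOSUM62")

    # -- lookup ------------------------------------------------------------

    @property
    def array(self) -> np.ndarray:
        """Read-only (21, 21) int32 view of the score table."""
        return self._scores

    def score(self, a: str, b: str) -> int:
        """Score(a, b) for single symbols; rejects unknown symbols by name."""
        for pos, sym in (("first", a), ("second", b)):
            if sym not in _INDEX:
                raise ValueError(
                    f"invalid residue symbol {sym!r} in {pos} argument"
                )
        return int(self._scores[_INDEX[a], _INDEX[b]])

    # -- mutation ----------------------------------------------------------

    def mutate(self, a: str, b: str, delta: int, symmetric: bool = False) -> "SubstitutionMatrix":
        """Return a copy with entry (a, b) shifted by ``delta`` (+1 or -1).

        ``*`` entries are frozen at 0 and cannot be mutated. With
        ``symmetric=True`` the mirror entry (b, a) is shifted too.
        """
        if delta not in (1, -1):
            raise ValueError(f"delta must be +1 or -1, got {delta}")
        if a == PAD or b == PAD:
            raise ValueError("'*' scores are frozen at 0 and cannot be mutated")
        for sym in (a, b):
            if sym not in _INDEX:
                raise ValueError(f"invalid residue symbol {sym!r}")
        new = self._scores.copy()
        new[_INDEX[a], _INDEX[b]] += delta
        if symmetric and a != b:
            new[_INDEX[b], _INDEX[a]] += delta
        return SubstitutionMatrix(new, label=self.label)

    # -- serialization -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the full 21x21 table as TSV with symbol header row/column."""
        lines = ["\t" + "\t".join(ALPHABET)]
        for i, a in enumerate(ALPHABET):
            lines.append(a + "\t" + "\t".join(str(int(v)) for v in self._scores[i]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "SubstitutionMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        cols = header[1:] if header[0] == "" else header
        if "".join(cols) != ALPHABET:
            raise ValueError(
                f"matrix file {path}: header alphabet {''.join(cols)!r} "
                f"does not match {ALPHABET!r}"
            )
        table = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.int32)
        if len(lines) - 1 != N_SYMBOLS:
            raise ValueError(f"matrix file {path}: expected {N_SYMBOLS} rows")
        for ln in lines[1:]:
            parts = ln.split("\t")
            sym = parts[0]
            if sym not in _INDEX:
                raise ValueError(f"matrix file {path}: unknown row symbol {sym!r}")
            table[_INDEX[sym]] = [int(v) for v in parts[1:]]
        return cls(table, label=label or str(path))

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstitutionMatrix):
            return NotImplemented
        return bool(np.array_equal(self._scores, other._scores))

    def __hash__(self):  # immutable enough for set/dict membership by content
        return hash(self._scores.tobytes())

    def diff(self, other: "SubstitutionMatrix") -> list[tuple[str, str, int]]:
        """Entries where self differs from ``other``: (a, b, self-other)."""
        rows, cols = np.nonzero(self._scores != other._scores)
        return [
            (ALPHABET[i], ALPHABET[j], int(self._scores[i, j] - other._scores[i, j]))
            for i, j in zip(rows, cols)
        ]

    def __repr__(self) -> str:
        return f"SubstitutionMatrix(label={self.label!r})"


def score_pair(matrix: SubstitutionMatrix, a: str, b: str) -> int:
    """Score(a, b) under ``matrix`` — functional form of :meth:`SubstitutionMatrix.score`."""
    return matrix.score(a, b)


def load_blosum62() -> SubstitutionMatrix:
    """BLOSUM62 with all ``*``-involving scores redefined to 0."""
    return SubstitutionMatrix.blosum62()


def mutate_entry(matrix: SubstitutionMatrix, a: str, b: str, delta: int) -> SubstitutionMatrix:
    """Return a new matrix with the single ordered entry (a, b) shifted by delta."""
    return matrix.mutate(a, b, delta)
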