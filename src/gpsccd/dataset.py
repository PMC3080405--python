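"""Substrates, cleavage-site tables, and cleavage-peptide window extraction.

Coordinates are 1-based: a site recorded at position ``p1`` means the scissile
bond lies between residues ``p1`` and ``p1 + 1``; the bond after the terminal
residue does not exist, so scannable positions run ``1 .. L-1``. A cleavage
peptide window CCP(m, n) takes the m residues ending at P1 and the n residues
starting at P1', padding with ``*`` where the window overhangs a terminus.

Under the benchmark convention every verified site of a substrate is a
positive, and every *other* bond of the same substrate is a negative; proteins
without any verified site contribute nothing to training.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrix import PAD, PAD_INDEX, encode


class DataError(ValueError):
    """Invalid input data (bad FASTA, bad site table, inconsistent sites)."""


@dataclass(frozen=True)
class Substrate:
    """A protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"substrate {self.id}: empty sequence")
        encode(self.sequence, allow_pad=False)  # validates alphabet

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class CleavageSite:
    """A verified scissile bond: cleavage occurs after residue ``p1`` (1-based)."""

    substrate_id: str
    p1: int


@dataclass(frozen=True)
class CleavagePeptide:
    """Fixed-length window of m upstream + n downstream residues around a bond.

    ``residues[0:m]`` are P_m..P_1 and ``residues[m:m+n]`` are P_1'..P_n';
    ``origin`` identifies the bond the window came from.
    """

    residues: str
    m: int
    n: int
    origin: tuple[str, int] | None = None

    def __post_init__(self):
        if len(self.residues) != self.m + self.n:
            raise DataError(
                f"peptide {self.residues!r}: length {len(self.residues)} != m+n = {self.m + self.n}"
            )

    def __str__(self) -> str:
        return self.residues[: self.m] + "|" + self.residues[self.m :]


def _fasta_record_id(raw_id: str) -> str:
    # UniProt convention: sp|ACC|NAME or tr|ACC|NAME -> ACC
    parts = raw_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return raw_id


def read_fasta(path: str | Path) -> list[Substrate]:
    """Read substrates from FASTA; ids are the header token up to whitespace
    (UniProt ``sp|ACC|NAME`` headers reduce to the accession)."""
    path = Path(path)
    substrates: list[Substrate] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    for rec in records:
        sid = _fasta_record_id(rec.id)
        if sid in seen:
            raise DataError(f"{path}: duplicate substrate id {sid!r}")
        seen.add(sid)
        seq = str(rec.seq).upper()
        try:
            substrates.append(Substrate(id=sid, sequence=seq))
        except ValueError as exc:
            raise DataError(f"{path}, record {sid!r}: {exc}") from exc
    return substrates


_ACCESSION_COLS = {"accession", "uniprot", "id", "substrate", "substrate_id", "protein"}
_POSITION_COLS = {"position", "p1", "site", "pos"}


def read_site_table(
    path: str | Path,
    substrates: Sequence[Substrate] | None = None,
) -> list[CleavageSite]:
    """Read a cleavage-site table (TSV/CSV with accession + 1-based position columns).

    Duplicate rows collapse to one site. When ``substrates`` is given, every
    site must fall within its substrate's sequence (1 <= p1 <= L).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.strip().lower(): c for c in df.columns}
    acc_col = next((cols[c] for c in cols if c in _ACCESSION_COLS), None)
    pos_col = next((cols[c] for c in cols if c in _POSITION_COLS), None)
    if acc_col is None or pos_col is None:
        raise DataError(
            f"{path}: need accession and position columns, found {list(df.columns)}"
        )
    by_id = {s.id: s for s in substrates} if substrates is not None else None
    sites: list[CleavageSite] = []
    seen: set[tuple[str, int]] = set()
    for row_no, (acc, pos) in enumerate(zip(df[acc_col], df[pos_col]), start=2):
        acc = str(acc).strip()
        try:
            p1 = int(pos)
        except (TypeError, ValueError):
            raise DataError(f"{path} line {row_no}: position {pos!r} is not an integer")
        if p1 < 1:
            raise DataError(
                f"{path} line {row_no}: position {p1} invalid (positions are 1-based)"
            )
        if by_id is not None:
            sub = by_id.get(acc)
            if sub is None:
                raise DataError(f"{path} line {row_no}: unknown substrate {acc!r}")
            if p1 > len(sub):
                raise DataError(
                    f"{path} line {row_no}: site {acc}:{p1} beyond sequence length {len(sub)}"
                )
        key = (acc, p1)
        if key in seen:
            continue
        seen.add(key)
        sites.append(CleavageSite(substrate_id=acc, p1=p1))
    return sites


def extract_peptide(sequence: str, p1: int, m: int, n: int) -> CleavagePeptide:
    """CCP(m, n) window around the bond after ``p1``, '*'-padded at termini."""
    if not 1 <= p1 <= len(sequence):
        raise DataError(f"p1={p1} outside sequence of length {len(sequence)}")
    if m < 1 or n < 1:
        raise DataError(f"window sizes must be >= 1, got m={m}, n={n}")
    up = sequence[max(0, p1 - m) : p1]
    down = sequence[p1 : p1 + n]
    residues = PAD * (m - len(up)) + up + down + PAD * (n - len(down))
    return CleavagePeptide(residues=residues, m=m, n=n)


@dataclass
class TrainingSet:
    """Positive and negative cleavage peptides at a fixed (m, n) window."""

    positives: list[CleavagePeptide]
    negatives: list[CleavagePeptide]
    m: int
    n: int
    _pos_idx: np.ndarray | None = field(default=None, repr=False, compare=False)
    _neg_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def positive_array(self) -> np.ndarray:
        """Encoded positives, shape (P, m+n) uint8."""
        if self._pos_idx is None:
            self._pos_idx = np.stack([encode(p.residues) for p in self.positives])
        return self._pos_idx

    @property
    def negative_array(self) -> np.ndarray:
        """Encoded negatives, shape (N, m+n) uint8."""
        if self._neg_idx is None:
            self._neg_idx = np.stack([encode(p.residues) for p in self.negatives])
        return self._neg_idx

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for label, peps in (("+", self.positives), ("-", self.negatives)):
            for p in peps:
                sid, p1 = p.origin if p.origin else ("", "")
                rows.append((label, sid, p1, p.residues))
        pd.DataFrame(rows, columns=["label", "substrate", "p1", "peptide"]).to_csv(
            path, sep="\t", index=False
        )


def build_training_set(
    substrates: Sequence[Substrate],
    sites: Iterable[CleavageSite],
    m: int,
    n: int,
    negatives_from_all_substrates: bool = False,
) -> TrainingSet:
    """Enumerate positives (verified bonds) and negatives (all other bonds).

    Negatives come only from substrates carrying at least one verified site
    unless ``negatives_from_all_substrates`` is set. Sites annotated at the
    terminal residue (p1 = L, no bond follows) are dropped with a warning.
    Deterministic and order-stable: substrates in input order, bonds by
    position within each substrate.
    """
    by_id = {s.id: s for s in substrates}
    site_map: dict[str, set[int]] = {}
    for site in sites:
        sub = by_id.get(site.substrate_id)
        if sub is None:
            raise DataError(f"site {site.substrate_id}:{site.p1} has no loaded substrate")
        if not 1 <= site.p1 <= len(sub):
            raise DataError(
                f"site {site.substrate_id}:{site.p1} outside sequence length {len(sub)}"
            )
        if site.p1 == len(sub):
            warnings.warn(
                f"site {site.substrate_id}:{site.p1} is at the terminal residue "
                "(no downstream bond); dropped",
                stacklevel=2,
            )
            site_map.setdefault(sub.id, set())  # substrate still counts as site-bearing
            continue
        site_map.setdefault(sub.id, set()).add(site.p1)

    positives: list[CleavagePeptide] = []
    negatives: list[CleavagePeptide] = []
    for sub in substrates:
        if sub.id not in site_map and not negatives_from_all_substrates:
            continue
        positions = site_map.get(sub.id, set())
        for p1 in range(1, len(sub)):
            pep = extract_peptide(sub.sequence, p1, m, n)
            pep = CleavagePeptide(pep.residues, m, n, origin=(sub.id, p1))
            (positives if p1 in positions else negatives).append(pep)
    return TrainingSet(positives=positives, negatives=negatives, m=m, n=n)


def window_arrays(
    substrates: Sequence[Substrate],
    sites: Iterable[CleavageSite],
    m: int,
    n: int,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]], list[tuple[str, int]]]:
    """Encoded positive/negative window arrays plus their (substrate, p1) origins.

    Array-level counterpart of :func:`build_training_set` used on hot paths.
    """
    ts = build_training_set(substrates, sites, m, n)
    return (
        ts.positive_array,
        ts.negative_array,
        [p.origin for p in ts.positives],
        [p.origin for p in ts.negatives],
    )


def encode_substrate_windows(sequence: str, m: int, n: int) -> np.ndarray:
    """Encoded CCP(m, n) windows for every bond 1..L-1 of a sequence, shape (L-1, m+n)."""
    L = len(sequence)
    idx = encode(sequence, allow_pad=False)
    padded = np.full(L + m + n, PAD_INDEX, dtype=np.uint8)
    padded[m : m + L] = idx
    if L < 2:
        return np.empty((0, m + n), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(padded, m + n)
    # bond after residue p1 uses padded slice starting at p1 (0-based: p1-1+1)
    return windows[1 : L].copy()
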