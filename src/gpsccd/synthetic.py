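"""Synthetic substrates with planted cleavage sites.

Calpain recognition is position-specific rather than consensus-driven:
peptide-library work found Leu/Thr/Val favored at P2 and Lys/Tyr/Arg at P1,
with weaker preferences at neighboring positions (the designed
super-substrate TPLK|SPPPSPR follows exactly this pattern). The generator
emulates that structure: background residues are drawn i.i.d. and each
planted site overwrites a small window around the scissile bond with draws
from a per-position motif distribution, mixed with the background by a
signal strength lambda (0 = pure background/null, 1 = pure motif).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import CleavageSite, Substrate
from .matrix import AMINO_ACIDS

N_AA = len(AMINO_ACIDS)
_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


def _distribution(weights: dict[str, float], rest: float = 0.0) -> np.ndarray:
    """Probability vector over the 20 amino acids: named masses + the
    remainder ``rest`` spread uniformly over the unnamed residues."""
    vec = np.zeros(N_AA)
    for aa, w in weights.items():
        vec[_AA_INDEX[aa]] = w
    others = [i for i in range(N_AA) if AMINO_ACIDS[i] not in weights]
    if others and rest > 0:
        vec[others] = rest / len(others)
    total = vec.sum()
    if not np.isclose(total, 1.0):
        raise ValueError(f"distribution sums to {total}, expected 1")
    return vec


@dataclass
class MotifProfile:
    """Per-position residue distributions around the scissile bond.

    ``positions`` maps signed offsets to 20-vectors: offset -k is the
    upstream position P_k (so -1 is P1, the residue whose following bond is
    cut) and +k is the downstream position P_k'. Other positions follow
    ``background``. ``lam`` mixes motif and background per planted position.
    """

    positions: dict[int, np.ndarray]
    background: np.ndarray = field(
        default_factory=lambda: np.full(N_AA, 1.0 / N_AA)
    )
    lam: float = 0.8

    def __post_init__(self):
        if 0 in self.positions:
            raise ValueError("offset 0 is not a position; use -1 (P1) or +1 (P1')")
        for off, vec in self.positions.items():
            if not np.isclose(np.sum(vec), 1.0):
                raise ValueError(f"profile at offset {off} does not sum to 1")
        if not np.isclose(np.sum(self.background), 1.0):
            raise ValueError("background distribution does not sum to 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")

    @property
    def upstream_span(self) -> int:
        return max((-o for o in self.positions if o < 0), default=0)

    @property
    def downstream_span(self) -> int:
        return max((o for o in self.positions if o > 0), default=0)

    def mixed(self, offset: int) -> np.ndarray:
        """lam * motif + (1 - lam) * background at ``offset``."""
        motif = self.positions.get(offset, self.background)
        return self.lam * motif + (1.0 - self.lam) * self.background


def default_calpain_profile(lam: float = 0.8) -> MotifProfile:
    """Default motif: strong {L,T,V}@P2 and {K,Y,R}@P1, mild preferences for
    T@P4, P@P3, S@P1' and P@P2', over a uniform background."""
    return MotifProfile(
        positions={
            -4: _distribution({"T": 0.30}, rest=0.70),
            -3: _distribution({"P": 0.30}, rest=0.70),
            -2: _distribution({"L": 0.40, "T": 0.30, "V": 0.30}),
            -1: _distribution({"K": 0.40, "Y": 0.30, "R": 0.30}),
            1: _distribution({"S": 0.30}, rest=0.70),
            2: _distribution({"P": 0.30}, rest=0.70),
        },
        lam=lam,
    )


def generate_benchmark(
    n_substrates: int = 130,
    length_range: tuple[int, int] = (200, 600),
    sites_per_substrate_range: tuple[int, int] = (1, 5),
    profile: MotifProfile | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[list[Substrate], list[CleavageSite]]:
    """Random substrates with non-overlapping planted cleavage sites.

    Background residues are i.i.d. from the profile background; each planted
    site redraws its profiled window positions from the lambda-mixed motif.
    Site P1 positions keep at least a window span from either terminus and
    their windows do not overlap, so positives are independent draws.
    """
    profile = profile or default_calpain_profile()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lo, hi = length_range
    s_lo, s_hi = sites_per_substrate_range
    if lo < 2 or hi < lo:
        raise ValueError(f"bad length range {length_range}")
    if s_lo < 0 or s_hi < s_lo:
        raise ValueError(f"bad sites-per-substrate range {sites_per_substrate_range}")
    up, down = max(profile.upstream_span, 1), max(profile.downstream_span, 1)
    span = up + down  # exclusion span between neighbouring sites

    substrates: list[Substrate] = []
    sites: list[CleavageSite] = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for i in range(n_substrates):
        L = int(rng.integers(lo, hi + 1))
        n_sites = int(rng.integers(s_lo, s_hi + 1))
        # candidate P1 positions leaving a full window inside the sequence
        first, last = up, L - down  # 1-based bounds for P1
        if first > last:
            raise ValueError(
                f"sequence length {L} cannot host a site with window span {span}"
            )
        placed: list[int] = []
        candidates = np.arange(first, last + 1)
        for _ in range(n_sites):
            free = candidates[
                [all(abs(c - p) > span for p in placed) for c in candidates]
            ]
            if free.size == 0:
                raise ValueError(
                    f"cannot place {n_sites} non-overlapping sites in length {L}"
                )
            placed.append(int(rng.choice(free)))
        placed.sort()

        seq_idx = rng.choice(N_AA, size=L, p=profile.background)
        for p1 in placed:
            for off in profile.positions:
                col = p1 + off if off < 0 else p1 + off - 1  # 0-based index
                seq_idx[col] = rng.choice(N_AA, p=profile.mixed(off))
        seq = aa[seq_idx].tobytes().decode()
        sid = f"SYN{i:04d}"
        substrates.append(Substrate(id=sid, sequence=seq))
        sites.extend(CleavageSite(substrate_id=sid, p1=p) for p in placed)
    return substrates, sites


def write_fasta(substrates: Sequence[Substrate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in substrates:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 60):
                fh.write(s.sequence[i : i + 60] + "\n")


def write_site_table(sites: Sequence[CleavageSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\n")
        for s in sites:
            fh.write(f"{s.substrate_id}\t{s.p1}\n")
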