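"""Normalized B-factor profiles and pairwise sequence identity.

The order-disorder picture of DNA binding is read from temperature
factors: per-residue mean B, mean-centred per chain (so profiles from
crystals with different overall mobility are comparable on one axis).  A
recognition helix that rigidifies on DNA binding moves from above-average
to below-average normalized B.

Sequence identity uses Needleman-Wunsch global alignment (match +1,
mismatch 0, gap -1 by default, via Bio.Align.PairwiseAligner) with the
identity denominator excluding terminal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .errors import EtsfaceError
from .structure_io import Structure

__all__ = ["BProfile", "IdentityResult", "bfactor_profile", "pairwise_identity"]


@dataclass
class BProfile:
    residue_numbers: list
    raw_mean_b: np.ndarray         # Angstrom^2
    normalized_b: np.ndarray       # mean-centred, dimensionless scale
    chain_id: str
    structure_id: str
    atom_scope: str

    def value_at(self, seq_id: int, normalized: bool = True) -> float:
        idx = self.residue_numbers.index(seq_id)
        return float((self.normalized_b if normalized else self.raw_mean_b)[idx])

    def window_mean(self, lo: int, hi: int, normalized: bool = True) -> float:
        vals = [self.value_at(n, normalized) for n in self.residue_numbers
                if lo <= n <= hi]
        if not vals:
            raise EtsfaceError(f"no residues in window {lo}-{hi}")
        return float(np.mean(vals))


_BACKBONE_ATOMS = {"N", "CA", "C", "O"}


def bfactor_profile(structure: Structure, chain_id: str,
                    atom_scope: str = "all") -> BProfile:
    """Per-residue mean B, chain-mean subtracted.

    ``atom_scope`` 'all' averages every atom of the residue; 'backbone'
    restricts to N/CA/C/O.
    """
    ch = structure.chain(chain_id)
    if ch is None:
        raise EtsfaceError(f"no chain {chain_id!r} in {structure.id}")
    numbers, means = [], []
    for res in ch.residues:
        if res.kind == "water":
            continue
        atoms = res.atoms if atom_scope == "all" else \
            [a for a in res.atoms if a.name in _BACKBONE_ATOMS]
        if not atoms:
            continue
        numbers.append(res.seq_id)
        means.append(float(np.mean([a.bfactor for a in atoms])))
    if not numbers:
        raise EtsfaceError(f"chain {chain_id}: no residues with B-factors")
    raw = np.array(means)
    return BProfile(residue_numbers=numbers, raw_mean_b=raw,
                    normalized_b=raw - raw.mean(), chain_id=chain_id,
                    structure_id=structure.id, atom_scope=atom_scope)


@dataclass
class IdentityResult:
    percent_identity: float
    aligned_length: int            # columns counted in the denominator
    identities: int
    score: float
    gap_policy: str = "terminal gaps excluded"


def pairwise_identity(seq_a: str, seq_b: str, match: float = 1.0,
                      mismatch: float = 0.0, gap: float = -1.0
                      ) -> IdentityResult:
    """Global-alignment percent identity between two protein sequences."""
    if not seq_a or not seq_b:
        raise EtsfaceError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    # trim terminal-gap columns from the identity denominator
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-") and \
            (_is_terminal_gap(row_a, start, True) or _is_terminal_gap(row_b, start, True)):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-") and \
            (_is_terminal_gap(row_a, end - 1, False) or _is_terminal_gap(row_b, end - 1, False)):
        end -= 1
    identities = sum(1 for k in range(start, end)
                     if row_a[k] == row_b[k] and row_a[k] != "-")
    counted = end - start
    pct = 100.0 * identities / counted if counted else 0.0
    return IdentityResult(percent_identity=pct, aligned_length=counted,
                          identities=identities, score=float(aln.score))


def _is_terminal_gap(row: str, k: int, leading: bool) -> bool:
    if row[k] != "-":
        return False
    return set(row[:k + 1]) <= {"-"} if leading else set(row[k:]) <= {"-"}
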