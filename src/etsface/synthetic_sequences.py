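"""Synthetic Ets-domain sequence family (stand-ins, not database sequences).

The real Etv1/Etv4/Etv5/Fev domain sequences are database entries that this
package does not bundle; instead a synthetic family is generated that
plants the family's published divergence structure so the alignment and
identity machinery can be validated against known ground truth:

* four ~104-residue domains on a shared scaffold;
* the conserved functional residues at their author-numbered positions
  (Gln-336, Trp-375, Lys-379, Asp-387, Lys-388, Arg-391, Ser-392, Arg-394,
  Tyr-395/396/397, Lys-399, Lys-404, Arg-409, Tyr-410, Cys-416 in Etv1-like
  numbering; constant offsets +6 / +33 / -288 for the Etv4/Etv5/Fev-like
  members);
* the PEA3-subfamily members (Etv1/4/5-like) >90% pairwise identical, the
  Fev-like member ~65% identical to them, carrying the subfamily-specific
  substitutions (Ser-392 -> Ala, Cys-416 -> Phe) and a two-residue deletion
  near the C-terminal helix.

Everything is deterministic (fixed seed) so identities are stable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ets_domain_sequences", "DOMAIN_STARTS"]

_LEN = 104
_SEED = 7

# author residue number of the first domain residue per family member
DOMAIN_STARTS = {"ETV1": 326, "ETV4": 332, "ETV5": 359, "FEV": 38}

# conserved anchors as (index into the domain, residue); index = resnum - 326
_ANCHORS = {
    8: "S",    # Ser-334, PKA site
    10: "Q", 11: "L",            # Gln-336, Leu-337
    49: "W", 53: "K", 55: "R",   # Trp-375, Lys-379, Arg-381
    60: "Y", 61: "D", 62: "K",   # Tyr-386, Asp-387, Lys-388
    64: "S", 65: "R", 66: "S",   # Ser-390, Arg-391, Ser-392
    68: "R", 69: "Y", 70: "Y", 71: "Y",  # Arg-394, Tyr-395/396/397
    73: "K", 78: "K",            # Lys-399, Lys-404
    83: "R", 84: "Y", 86: "Y",   # Arg-409, Tyr-410, Tyr-412
    90: "C",                     # Cys-416 (redox-sensitive)
}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _scaffold(rng: np.random.Generator) -> str:
    """Base Etv1-like domain with anchors imposed."""
    # composition-weighted draw (globular-domain-like frequencies)
    weights = np.array([0.08, 0.015, 0.05, 0.06, 0.04, 0.07, 0.02, 0.05,
                        0.06, 0.09, 0.02, 0.045, 0.045, 0.04, 0.05, 0.07,
                        0.055, 0.07, 0.012, 0.033])
    weights /= weights.sum()
    seq = list(rng.choice(list(_AA), size=_LEN, p=weights))
    for idx, aa in _ANCHORS.items():
        seq[idx] = aa
    return "".join(seq)


def _mutate(seq: str, positions: list[int], rng: np.random.Generator,
            forbid: set[int]) -> str:
    out = list(seq)
    for pos in positions:
        assert pos not in forbid
        current = out[pos]
        choices = [a for a in _AA if a != current]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def ets_domain_sequences() -> dict[str, str]:
    """The four synthetic domain sequences, keyed ETV1/ETV4/ETV5/FEV."""
    rng = np.random.default_rng(_SEED)
    anchors = set(_ANCHORS)
    etv1 = _scaffold(rng)

    free = [i for i in range(_LEN) if i not in anchors]
    picks = list(rng.choice(free, size=12, replace=False))
    shared = picks[:5]       # common-ancestor substitutions in Etv4 and Etv5
    only4 = picks[5:7]
    only5 = picks[7:9]
    etv_shared = _mutate(etv1, shared, rng, anchors)
    # identical substitutions at shared sites, member-specific ones elsewhere
    etv4 = _mutate(etv_shared, only4, rng, anchors)
    etv5 = _mutate(etv_shared, only5, rng, anchors)

    # Fev-like: heavily diverged scaffold, same anchors except the
    # subfamily-specific Ala-104 (Ser-392 equivalent) and Phe (Cys-416 eq.)
    fev_sites = [i for i in free if i not in picks]
    fev_positions = list(rng.choice(fev_sites, size=34, replace=False))
    fev = list(_mutate(etv1, fev_positions, rng, anchors))
    fev[66] = "A"   # Ser-392 -> Ala-104
    fev[90] = "F"   # Cys-416 -> Phe-126
    # two-residue deletion in the C-terminal helix region (alpha-4)
    del fev[97:99]
    return {"ETV1": etv1, "ETV4": etv4, "ETV5": etv5, "FEV": "".join(fev)}
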