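"""Synthetic reference protein families for profile construction.

Marker screening needs a reference alignment per marker (to build a
position-specific scoring profile) and, for MerB, a numbering reference for
the catalytic-cysteine check.  This module provides *synthetic* stand-ins for
curated reference sets: deterministic pseudo-random protein families built
around the conserved features the screening rules actually test —

* HgcA: the cap-helix motif ``G(I/V)NVWCA(A/G)`` at a fixed alignment column;
* HgcB: two ``CX2CX2CX3C`` ferredoxin motifs;
* MerB: cysteines at reference positions 96 and 159 (the conventional
  organomercury-lyase numbering);
* MerA / MerP / MerT / MerR: conserved families with no positional gate.

The families carry no real biological sequence; every sequence is generated
from a fixed internal seed so profiles are identical across runs and
machines.  Column conservation outside the motifs is ~92%, enough contrast
for the log-odds profiles to separate family members from background.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: per-marker reference length and internal seed
_FAMILY_PLAN = {
    "hgcA": dict(length=150, seed=101),
    "hgcB": dict(length=96, seed=102),
    "merB": dict(length=210, seed=103),
    "merA": dict(length=160, seed=104),
    "merP": dict(length=70, seed=105),
    "merT": dict(length=80, seed=106),
    "merR": dict(length=90, seed=107),
}

#: 0-based column where the HgcA cap-helix motif starts in the reference
HGCA_MOTIF_START = 60
#: 0-based columns where the two HgcB CX2CX2CX3C motifs start
HGCB_MOTIF_STARTS = (20, 60)
#: 1-based reference positions of the MerB catalytic cysteines
MERB_CYS_POSITIONS = (96, 159)

_MUTATION_RATE = 0.08
_N_SEQS = 8


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _consensus(marker: str) -> tuple[str, set[int]]:
    """Build the family consensus and the set of frozen (motif) columns."""
    plan = _FAMILY_PLAN[marker]
    rng = np.random.default_rng(plan["seed"])
    seq = list(_random_protein(rng, plan["length"]))
    frozen: set[int] = set()
    if marker == "hgcA":
        motif = "GINVWCAA"
        for i, aa in enumerate(motif):
            seq[HGCA_MOTIF_START + i] = aa
        # mandatory columns: every motif position except the two degenerate ones
        frozen = {HGCA_MOTIF_START + i for i in range(len(motif)) if i not in (1, 7)}
    elif marker == "hgcB":
        motif = "CAACDDCGGGC"
        for start in HGCB_MOTIF_STARTS:
            for i, aa in enumerate(motif):
                seq[start + i] = aa
            # only the four cysteines are mandatory; the X positions may drift
            frozen |= {start + i for i in (0, 3, 6, 10)}
    elif marker == "merB":
        for pos in MERB_CYS_POSITIONS:
            seq[pos - 1] = "C"
            frozen.add(pos - 1)
    return "".join(seq), frozen


@lru_cache(maxsize=None)
def reference_alignment(marker: str, n_seqs: int = _N_SEQS) -> tuple[str, ...]:
    """Deterministic gap-free reference alignment for ``marker``.

    Rows are the consensus mutated at ~8% of non-frozen columns; for HgcA the
    two degenerate motif columns vary over {I,V} and {A,G} across rows.
    """
    if marker not in _FAMILY_PLAN:
        raise KeyError(f"unknown marker {marker!r}")
    consensus, frozen = _consensus(marker)
    rng = np.random.default_rng(_FAMILY_PLAN[marker]["seed"] + 5000)
    aas = list(AA_ALPHABET)
    rows = []
    for _ in range(n_seqs):
        row = list(consensus)
        for i in range(len(row)):
            if i in frozen:
                continue
            if rng.random() < _MUTATION_RATE:
                row[i] = aas[rng.integers(len(aas))]
        if marker == "hgcA":
            row[HGCA_MOTIF_START + 1] = "I" if rng.random() < 0.5 else "V"
            row[HGCA_MOTIF_START + 7] = "A" if rng.random() < 0.5 else "G"
        rows.append("".join(row))
    return tuple(rows)


def merb_reference() -> str:
    """The MerB numbering reference (cysteines at 1-based 96 and 159)."""
    return _consensus("merB")[0]


@lru_cache(maxsize=None)
def dsrab_references() -> dict[str, str]:
    """Labelled reductive/oxidative dsrAB reference sequences.

    The two types are >30% divergent so that nearest-reference typing is
    well-separated for queries within ~10% of either type.
    """
    rng = np.random.default_rng(777)
    reductive = _random_protein(rng, 180)
    aas = list(AA_ALPHABET)
    oxidative = list(reductive)
    for i in range(len(oxidative)):
        if rng.random() < 0.45:
            oxidative[i] = aas[rng.integers(len(aas))]
    return {"reductive": reductive, "oxidative": "".join(oxidative)}


def markers_available() -> tuple[str, ...]:
    return tuple(_FAMILY_PLAN)
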