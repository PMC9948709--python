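"""Marker-gene screening with conserved-motif verification.

Candidate hgcA/hgcB/merB/merA (and mer-operon accessory) proteins are found
by scoring each protein against an additive position-specific log-odds
profile built from a reference alignment, then — for the three gated markers
— verified against the conserved features that define the family:

* hgcA: the cap-helix motif ``G(I/V)NVWCA(A/G)`` must be present;
* hgcB: at least two non-overlapping ``CX2CX2CX3C`` ferredoxin motifs;
* merB: cysteines at the residues that align to reference positions 96 and
  159 (organomercury-lyase numbering), established by global pairwise
  alignment.

A genome is called a putative MeHg *producer* when it carries both an hgcA
and an hgcB call (the pair is required for methylation; the two genes need
not be adjacent), and a putative *degrader* when it carries a merB call.
Profile thresholds are calibrated from the reference set itself (minimum
reference score minus a stringency margin); hgcA uses the stringent tier,
everything else the permissive tier.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .references import (
    AA_ALPHABET,
    MERB_CYS_POSITIONS,
    markers_available,
    merb_reference,
    reference_alignment,
)

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_VALID_AA = re.compile(rf"^[{AA_ALPHABET}]+$")

HGCA_MOTIF = re.compile(r"G[IV]NVWCA[AG]")
HGCB_MOTIF = re.compile(r"C..C..C...C")

#: stringency margins (profile score units below the minimum reference score)
MARGIN_STRINGENT = 4.0
MARGIN_PERMISSIVE = 8.0

#: markers whose calls are gated on a conserved-motif check
GATED_MARKERS = ("hgcA", "hgcB", "merB")


def _validate_sequence(seq: str) -> str:
    seq = seq.upper().rstrip("*")
    if not seq:
        raise ValueError("empty amino-acid sequence")
    if not _VALID_AA.match(seq):
        bad = sorted(set(seq) - set(AA_ALPHABET))
        raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    return seq


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class Profile:
    """Additive position-specific log-odds profile for one marker family.

    ``matrix`` has one row per alignment column and one column per residue of
    the 20-letter alphabet; a sequence is scored by the best ungapped window
    of the profile's length.  ``ref_min_score`` is the lowest score of the
    reference sequences against their own profile, the anchor from which
    tiered thresholds are derived (``threshold = ref_min_score - margin``).
    """

    marker: str
    matrix: np.ndarray
    consensus: str
    ref_min_score: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def build(
        cls,
        alignment: Sequence[str],
        marker: str,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.5,
    ) -> "Profile":
        """Build a profile from a gap-free (or gapped) reference alignment."""
        if len(alignment) < 2:
            raise ValueError("need at least 2 aligned reference sequences")
        lengths = {len(s) for s in alignment}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        length = lengths.pop()
        bg = np.full(20, 0.05) if background is None else np.asarray(background, float)
        if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a 20-vector summing to 1")
        counts = np.zeros((length, 20))
        for seq in alignment:
            for i, aa in enumerate(seq.upper()):
                if aa == "-":
                    continue
                if aa not in _AA_INDEX:
                    raise ValueError(f"invalid residue {aa!r} in alignment")
                counts[i, _AA_INDEX[aa]] += 1
        col_tot = counts.sum(axis=1, keepdims=True) + 20 * pseudocount
        probs = (counts + pseudocount) / col_tot
        matrix = np.log(probs / bg)
        consensus = "".join(AA_ALPHABET[j] for j in probs.argmax(axis=1))
        prof = cls(marker=marker, matrix=matrix, consensus=consensus, ref_min_score=0.0)
        prof.ref_min_score = min(
            prof.score(seq.replace("-", "")) for seq in alignment
        )
        return prof

    def score(self, sequence: str) -> float:
        """Best ungapped window score; -inf if the sequence is shorter."""
        seq = _validate_sequence(sequence)
        n, L = len(seq), self.length
        if n < L:
            return float("-inf")
        idx = np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp, count=n)
        per_pos = self.matrix[:, idx]  # (L, n)
        n_win = n - L + 1
        totals = np.zeros(n_win)
        for i in range(L):
            totals += per_pos[i, i : i + n_win]
        return float(totals.max())

    def threshold(self, margin: float) -> float:
        return self.ref_min_score - margin

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker": self.marker,
            "alphabet": AA_ALPHABET,
            "matrix": self.matrix.tolist(),
            "consensus": self.consensus,
            "ref_min_score": self.ref_min_score,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Profile":
        payload = json.loads(Path(path).read_text())
        return cls(
            marker=payload["marker"],
            matrix=np.asarray(payload["matrix"], float),
            consensus=payload["consensus"],
            ref_min_score=float(payload["ref_min_score"]),
        )


def build_profile(alignment: Sequence[str], marker: str, **kw) -> Profile:
    """Functional wrapper around :meth:`Profile.build`."""
    return Profile.build(alignment, marker, **kw)


def default_profiles() -> dict[str, Profile]:
    """Profiles for all seven markers from the bundled reference families."""
    return {m: Profile.build(reference_alignment(m), m) for m in markers_available()}


# ---------------------------------------------------------------------------
# motif gates
# ---------------------------------------------------------------------------


def check_hgca_motif(sequence: str) -> tuple[bool, str | None]:
    """Cap-helix motif G(I/V)NVWCA(A/G); returns (ok, matched substring)."""
    seq = _validate_sequence(sequence)
    m = HGCA_MOTIF.search(seq)
    return (True, m.group(0)) if m else (False, None)


def check_hgcb_motif(sequence: str) -> tuple[bool, list[str]]:
    """At least two non-overlapping CX2CX2CX3C motifs; returns (ok, matches)."""
    seq = _validate_sequence(sequence)
    matches = [m.group(0) for m in HGCB_MOTIF.finditer(seq)]
    return len(matches) >= 2, matches


def _merb_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def check_merb_cysteines(
    sequence: str,
    reference: str | None = None,
    positions: tuple[int, int] = MERB_CYS_POSITIONS,
) -> tuple[bool, dict]:
    """Check for cysteines at the residues aligned to reference 96 and 159.

    The candidate is globally aligned to the numbering reference (BLOSUM62,
    affine gaps); the check passes iff both reference columns align to a
    cysteine in the candidate.  A gap at either column fails with reason
    ``"gapped"``.
    """
    seq = _validate_sequence(sequence)
    ref = _validate_sequence(reference or merb_reference())
    aln = _merb_aligner().align(ref, seq)[0]
    evidence: dict = {"aligned": {}, "reason": None}
    ok = True
    for pos in positions:  # 1-based reference numbering
        ref_idx = pos - 1
        query_idx = None
        for (rs, re_), (qs, _qe) in zip(*aln.aligned):
            if rs <= ref_idx < re_:
                query_idx = int(qs + (ref_idx - rs))
                break
        if query_idx is None:
            evidence["aligned"][pos] = None
            evidence["reason"] = "gapped"
            ok = False
        else:
            residue = seq[query_idx]
            evidence["aligned"][pos] = (query_idx, residue)
            if residue != "C":
                ok = False
                evidence["reason"] = evidence["reason"] or "not-cysteine"
    return ok, evidence


# ---------------------------------------------------------------------------
# scanning and roles
# ---------------------------------------------------------------------------


@dataclass
class MarkerCall:
    """One detected marker protein, with its score and motif evidence."""

    mag_id: str
    protein_id: str
    marker: str
    score: float
    motif_ok: bool
    evidence: str = ""


@dataclass
class RoleAssignment:
    mag_id: str
    is_producer: bool
    is_degrader: bool


@dataclass
class MagRecord:
    """Per-genome metadata: taxonomy and assembly-quality metrics."""

    mag_id: str
    taxonomy: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    calls: list = field(default_factory=list)


def scan_mag(
    proteome: Iterable[tuple[str, str]] | str | Path,
    profiles: Mapping[str, Profile] | None = None,
    mag_id: str | None = None,
    merb_ref: str | None = None,
    margin_stringent: float = MARGIN_STRINGENT,
    margin_permissive: float = MARGIN_PERMISSIVE,
) -> list[MarkerCall]:
    """Scan one proteome for all seven markers.

    ``proteome`` is either a path to a protein FASTA (headers ``mag|protein``)
    or an iterable of ``(protein_id, sequence)`` pairs.  hgcA calls require
    the stringent score tier plus the cap-helix motif; hgcB and merB require
    the permissive tier plus their respective gates; merA/merP/merT/merR
    require only the permissive score.  Unreadable records are skipped with a
    logged warning; an empty proteome yields an empty list.
    """
    profiles = profiles or default_profiles()
    records: list[tuple[str, str]] = []
    if isinstance(proteome, (str, Path)):
        for rec in SeqIO.parse(str(proteome), "fasta"):
            header = rec.id
            if "|" in header:
                mag_from_header, protein_id = header.split("|", 1)
                mag_id = mag_id or mag_from_header
            else:
                protein_id = header
            records.append((protein_id, str(rec.seq)))
        if mag_id is None:
            mag_id = Path(proteome).stem
    else:
        records = list(proteome)
        mag_id = mag_id or "MAG"

    calls: list[MarkerCall] = []
    for protein_id, seq in records:
        try:
            seq = _validate_sequence(seq)
        except ValueError as exc:
            logger.warning("skipping %s|%s: %s", mag_id, protein_id, exc)
            continue
        for marker, profile in profiles.items():
            margin = margin_stringent if marker == "hgcA" else margin_permissive
            score = profile.score(seq)
            if score < profile.threshold(margin):
                continue
            if marker == "hgcA":
                ok, match = check_hgca_motif(seq)
                evidence = match or ""
            elif marker == "hgcB":
                ok, matches = check_hgcb_motif(seq)
                evidence = ";".join(matches)
            elif marker == "merB":
                ok, detail = check_merb_cysteines(seq, merb_ref)
                evidence = json.dumps(detail["aligned"])
            else:
                ok, evidence = True, ""
            if marker in GATED_MARKERS and not ok:
                continue
            calls.append(
                MarkerCall(mag_id, protein_id, marker, score, ok, evidence)
            )
    return calls


def assign_roles(calls_by_mag: Mapping[str, Sequence[MarkerCall]]) -> list[RoleAssignment]:
    """Producer iff hgcA and hgcB both called in the MAG; degrader iff merB.

    The hgcA/hgcB pair need not be adjacent in the genome — co-occurrence
    within the MAG suffices.  Both flags may be true.
    """
    out = []
    for mag_id, calls in calls_by_mag.items():
        markers = {c.marker for c in calls}
        out.append(
            RoleAssignment(
                mag_id=mag_id,
                is_producer=("hgcA" in markers and "hgcB" in markers),
                is_degrader=("merB" in markers),
            )
        )
    return out


def group_calls(calls: Iterable[MarkerCall]) -> dict[str, list[MarkerCall]]:
    grouped: dict[str, list[MarkerCall]] = {}
    for call in calls:
        grouped.setdefault(call.mag_id, []).append(call)
    return grouped


QUALITY_TIERS = {"good": (75.0, 10.0), "high": (90.0, 5.0)}


def filter_quality(mags: Iterable[MagRecord], tier: str = "good") -> list[MagRecord]:
    """Keep MAGs passing a quality tier (strict inequalities).

    ``good``: completeness > 75 and contamination < 10;
    ``high``: completeness > 90 and contamination < 5.
    Metrics outside [0, 100] are rejected with an error.
    """
    if tier not in QUALITY_TIERS:
        raise ValueError(f"unknown tier {tier!r}; choose from {sorted(QUALITY_TIERS)}")
    min_comp, max_cont = QUALITY_TIERS[tier]
    kept = []
    for mag in mags:
        if not (0 <= mag.completeness <= 100 and 0 <= mag.contamination <= 100):
            raise ValueError(
                f"{mag.mag_id}: completeness/contamination out of [0, 100]"
            )
        if mag.completeness > min_comp and mag.contamination < max_cont:
            kept.append(mag)
    return kept


def calls_to_frame(calls: Iterable[MarkerCall]):
    """Marker calls as a tidy table (mag, protein, marker, score, motif_ok)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                mag=c.mag_id,
                protein=c.protein_id,
                marker=c.marker,
                score=c.score,
                motif_ok=c.motif_ok,
                evidence=c.evidence,
            )
            for c in calls
        ],
        columns=["mag", "protein", "marker", "score", "motif_ok", "evidence"],
    )
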