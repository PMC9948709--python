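"""Marker screening: motif gates, profile scoring, scanning, quality tiers."""

import random

import numpy as np
import pytest

from mehg_guild import (
    Profile,
    assign_roles,
    check_hgca_motif,
    check_hgcb_motif,
    check_merb_cysteines,
    filter_quality,
    scan_mag,
)
from mehg_guild.markers import MagRecord, group_calls
from mehg_guild.references import AA_ALPHABET, merb_reference, reference_alignment


# ---------------------------------------------------------------------------
# motif gates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "core, expected",
    [
        ("GINVWCAA", True),   # I + A variant
        ("GVNVWCAG", True),   # V + G variant
        ("GINVWCAG", True),
        ("GVNVWCAA", True),
        ("GLNVWCAA", False),  # L not in {I, V}
        ("AINVWCAA", False),
        ("GINVWCAC", False),  # C not in {A, G}
        ("GINVWAAA", False),
        ("GINVYCAA", False),
    ],
)
def test_hgca_cap_helix_motif(core, expected):
    ok, match = check_hgca_motif("MKK" + core + "LLP")
    assert ok is expected
    if expected:
        assert match == core


def test_hgca_motif_exhaustive_single_breaks():
    """Breaking any mandatory residue of the cap-helix motif kills the match."""
    core = "GINVWCAA"
    mandatory = [0, 2, 3, 4, 5, 6]  # all but the two degenerate positions
    for pos in mandatory:
        for repl in AA_ALPHABET:
            if repl == core[pos]:
                continue
            broken = core[:pos] + repl + core[pos + 1 :]
            if check_hgca_motif(broken)[0]:
                # the only acceptable breakages are the allowed degeneracies
                assert pos in (1, 7)
            else:
                assert not check_hgca_motif("AA" + broken + "AA")[0]


@pytest.mark.parametrize(
    "seq, expected, n_matches",
    [
        ("MCAACDDCGGGCKKKCAACDDCGGGC", True, 2),   # two non-overlapping motifs
        ("MCAACDDCGGGC", False, 1),                # one motif only
        ("CACCACCAC", False, 0),                   # wrong spacings
        ("CAACDDCGGGCCAACDDCGGGC", True, 2),       # back-to-back
        ("MAAAAAA", False, 0),
    ],
)
def test_hgcb_twin_ferredoxin_motifs(seq, expected, n_matches):
    ok, matches = check_hgcb_motif(seq)
    assert ok is expected
    assert len(matches) == n_matches


def test_motif_checks_reject_non_amino_acids():
    for bad in ("GINVWCAA1", "GINV WCAA", "ginvxcaa*z", ""):
        with pytest.raises(ValueError):
            check_hgca_motif(bad)
        with pytest.raises(ValueError):
            check_hgcb_motif(bad)


def test_merb_reference_aligned_to_itself_passes():
    ref = merb_reference()
    ok, detail = check_merb_cysteines(ref)
    assert ok
    assert detail["aligned"][96] == (95, "C")
    assert detail["aligned"][159] == (158, "C")


def test_merb_cys96_substitution_fails():
    ref = merb_reference()
    mutated = ref[:95] + "A" + ref[96:]
    ok, detail = check_merb_cysteines(mutated)
    assert not ok
    assert detail["aligned"][96][1] == "A"


def test_merb_insertion_shifts_raw_index_but_alignment_recovers():
    """A 5-residue insertion at position 50 moves Cys96 to raw index 100
    (0-based); the aligned check still passes.  The aligned position is
    verified against an independent edit-distance alignment (edlib)."""
    ref = merb_reference()
    candidate = ref[:50] + "AGAGA" + ref[50:]
    ok, detail = check_merb_cysteines(candidate)
    assert ok
    assert detail["aligned"][96] == (100, "C")

    edlib = pytest.importorskip("edlib")
    result = edlib.align(ref, candidate, task="path", mode="NW")
    # replay the CIGAR to find the candidate index aligned to ref index 95
    import re as _re

    ref_i = cand_i = 0
    aligned_at_95 = None
    for count, op in _re.findall(r"(\d+)([=XIDM])", result["cigar"]):
        count = int(count)
        if op in "=XM":
            if ref_i <= 95 < ref_i + count:
                aligned_at_95 = cand_i + (95 - ref_i)
            ref_i += count
            cand_i += count
        elif op == "D":  # edlib: consumes the target (candidate) only
            cand_i += count
        else:  # "I": consumes the query (reference) only
            if ref_i <= 95 < ref_i + count:
                aligned_at_95 = None
            ref_i += count
    assert aligned_at_95 == 100


def test_merb_gap_over_cysteine_reports_gapped():
    ref = merb_reference()
    truncated = ref[:90]  # ends before position 96
    ok, detail = check_merb_cysteines(truncated)
    assert not ok
    assert detail["reason"] == "gapped"


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def test_profile_identical_references_score_at_maximum():
    aln = ["MKWVAEDQRL" * 12] * 5
    prof = Profile.build(aln, "toy")
    best_possible = prof.matrix.max(axis=1).sum()
    assert prof.score(aln[0]) == pytest.approx(best_possible)
    assert prof.ref_min_score == pytest.approx(best_possible)


def test_profile_rejects_ragged_alignment():
    with pytest.raises(ValueError, match="ragged"):
        Profile.build(["AAAA", "AAA"], "toy")
    with pytest.raises(ValueError):
        Profile.build(["AAAA"], "toy")


@pytest.mark.parametrize("marker", ["hgcA", "hgcB", "merB"])
def test_references_score_above_threshold_shuffles_below(marker):
    """All family members pass at margin 0; 100 shuffles of each never do."""
    aln = reference_alignment(marker)
    prof = Profile.build(aln, marker)
    threshold = prof.threshold(0.0)
    rng = random.Random(42)
    for seq in aln:
        assert prof.score(seq) >= threshold
        residues = list(seq)
        for _ in range(100 // len(aln) + 1):
            rng.shuffle(residues)
            assert prof.score("".join(residues)) < threshold


def test_profile_serialization_round_trip(tmp_path, profiles):
    prof = profiles["hgcA"]
    path = tmp_path / "hgcA.json"
    prof.to_json(path)
    loaded = Profile.from_json(path)
    probe = reference_alignment("hgcA")[0]
    assert loaded.score(probe) == pytest.approx(prof.score(probe))
    assert loaded.ref_min_score == prof.ref_min_score


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def test_scan_closed_loop_roles(planted_four, profiles):
    proteomes, truth = planted_four
    calls = {m: scan_mag(recs, profiles, mag_id=m) for m, recs in proteomes.items()}
    roles = {r.mag_id: r for r in assign_roles(calls)}
    assert roles["MAG001"].is_producer and not roles["MAG001"].is_degrader
    assert roles["MAG002"].is_degrader and not roles["MAG002"].is_producer
    assert roles["MAG003"].is_producer and roles["MAG003"].is_degrader
    assert not roles["MAG004"].is_producer and not roles["MAG004"].is_degrader
    # every planted marker is called exactly once; no decoy is ever called
    planted = truth[truth["kind"] == "planted"]
    decoys = truth[truth["kind"] == "decoy"]
    called = {
        (c.mag_id, c.protein_id, c.marker) for cs in calls.values() for c in cs
    }
    for _, row in planted.iterrows():
        assert (row["mag"], row["protein"], row["marker"]) in called
    decoy_proteins = set(zip(decoys["mag"], decoys["protein"]))
    gated_calls = {
        (c.mag_id, c.protein_id)
        for cs in calls.values()
        for c in cs
        if c.marker in ("hgcA", "hgcB", "merB")
    }
    assert not (decoy_proteins & gated_calls)


def test_scan_is_order_invariant(planted_four, profiles):
    proteomes, _ = planted_four
    records = proteomes["MAG003"]
    forward = scan_mag(records, profiles, mag_id="MAG003")
    backward = scan_mag(list(reversed(records)), profiles, mag_id="MAG003")
    key = lambda c: (c.protein_id, c.marker)
    assert sorted((key(c) for c in forward)) == sorted(key(c) for c in backward)


def test_scan_supports_two_marker_copies(profiles):
    """A genome with two hgcAB pairs yields two calls per marker."""
    from mehg_guild.synthdata import PlantingSpec, generate_proteomes

    proteomes, _ = generate_proteomes(PlantingSpec(roles=["producer"], seed=5))
    extra, truth2 = generate_proteomes(PlantingSpec(roles=["producer"], seed=6))
    second_pair = [
        (pid + "b", seq)
        for pid, seq in extra["MAG001"]
        if pid in set(truth2["protein"])
    ]
    records = list(proteomes["MAG001"]) + second_pair
    calls = scan_mag(records, profiles, mag_id="MAG001")
    by_marker = {}
    for c in calls:
        by_marker.setdefault(c.marker, []).append(c)
    assert len(by_marker["hgcA"]) == 2
    assert len(by_marker["hgcB"]) == 2


def test_hgca_without_hgcb_is_not_a_producer(profiles):
    aln = reference_alignment("hgcA")
    calls = {"M": scan_mag([("p1", aln[0])], profiles, mag_id="M")}
    assert {c.marker for c in calls["M"]} == {"hgcA"}
    role = assign_roles(calls)[0]
    assert not role.is_producer


def test_scan_empty_and_unreadable_records(profiles, caplog):
    assert scan_mag([], profiles, mag_id="empty") == []
    with caplog.at_level("WARNING"):
        calls = scan_mag([("bad", "XXX123"), ("ok", "ACDEFGHIKL" * 20)],
                         profiles, mag_id="M")
    assert all(c.protein_id != "bad" for c in calls)


# ---------------------------------------------------------------------------
# quality tiers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "completeness, contamination, good, high",
    [
        (99.39, 0.04, True, True),
        (75.0, 5.0, False, False),  # strict inequality on completeness
        (80.0, 3.0, True, False),
        (95.0, 9.0, True, False),
        (76.0, 10.0, False, False),
    ],
)
def test_quality_tiers(completeness, contamination, good, high):
    mag = MagRecord("m", completeness=completeness, contamination=contamination)
    assert bool(filter_quality([mag], "good")) is good
    assert bool(filter_quality([mag], "high")) is high


def test_quality_rejects_out_of_range():
    with pytest.raises(ValueError):
        filter_quality([MagRecord("m", completeness=101.0)], "good")
    with pytest.raises(ValueError):
        filter_quality([MagRecord("m", contamination=-1.0)], "good")
    with pytest.raises(ValueError):
        filter_quality([MagRecord("m")], "excellent")
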