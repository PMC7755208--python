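"""Two-segment epitope search: objective functions, scanning, tiers, graft."""

import numpy as np
import pytest

from rescaff import fixtures
from rescaff.rescaffold import (EpitopeQuery, TierConfig, build_query,
                                graft_epitope, parse_hotspot, scan_structure,
                                score_dihedrals, score_orientation,
                                score_termini, tiered_search)
from rescaff.structio import BackboneSegment, Residue


def fake_segment(ca_coords, phi=None, psi=None):
    """Build a CA-only segment for direct formula tests."""
    ca_coords = np.asarray(ca_coords, float)
    n = len(ca_coords)
    residues = [Residue(name="ALA", resseq=i + 1, atoms={"CA": c})
                for i, c in enumerate(ca_coords)]
    return BackboneSegment(
        residues=residues,
        phi=np.asarray(phi if phi is not None else [np.nan] * n, float),
        psi=np.asarray(psi if psi is not None else [np.nan] * n, float))


def fake_query(ca1, ca2, **kw):
    return EpitopeQuery(segment1=fake_segment(ca1, **kw),
                        segment2=fake_segment(ca2, **kw))


# ----------------------------------------------------------------- build_query


def test_build_query_shapes(query):
    assert query.k1 + 1 == 12 and query.k2 + 1 == 4
    assert query.q.shape == (16, 3)


def test_build_query_hotspot_validation(donor):
    seq = donor["A"].sequence  # all-Ala synthetic donor
    assert seq[3] == "A"
    q = build_query(donor, "A", (4, 15), (22, 25), ["A4", "A22"])
    assert q.hotspots == [(0, 0, "A"), (1, 0, "A")]
    with pytest.raises(ValueError, match="donor has"):
        build_query(donor, "A", (4, 15), (22, 25), ["K4"])
    with pytest.raises(ValueError, match="outside"):
        build_query(donor, "A", (4, 15), (22, 25), ["A1"])
    with pytest.raises(ValueError):
        parse_hotspot("16K")


def test_query_dihedrals_match_construction(query):
    # donor segments are ideal helices at (-57, -47)
    assert np.nanmax(np.abs(query.segment1.phi[1:] + 57)) < 1e-6
    assert np.nanmax(np.abs(query.segment1.psi + 47)) < 1e-6  # interior context


# ------------------------------------------------------------------ f1 / f2 / f3


def test_f1_zero_on_rigid_copy(query, rng):
    rot = fixtures.random_rotation(rng)
    t = rng.normal(size=3) * 30
    s1 = query.segment1.ca @ rot.T + t
    s2 = query.segment2.ca @ rot.T + t
    assert score_orientation(query, s1, s2) == pytest.approx(0.0, abs=1e-6)
    # fixed frame is NOT invariant; canonicalisation is the default
    assert score_orientation(query, s1, s2, frame="fixed") > 1.0


def test_f1_reversed_segment_two():
    q = fake_query([[0, 0, 0], [10, 0, 0]], [[0, 5, 0], [0, 5, 10]])
    a = q.segment1.ca[0] - q.segment1.ca[-1]
    b = q.segment2.ca[0] - q.segment2.ca[-1]
    expected = 2 * np.linalg.norm(np.cross(a, b))
    f1 = score_orientation(q, q.segment1.ca, q.segment2.ca[::-1], frame="fixed")
    assert f1 == pytest.approx(expected, rel=1e-9)


def test_f1_magnitude_mode_invariance(query, rng):
    rot = fixtures.random_rotation(rng)
    s1 = query.segment1.ca @ rot.T
    s2 = query.segment2.ca @ rot.T
    assert score_orientation(query, s1, s2, frame="magnitude") == pytest.approx(
        0.0, abs=1e-8)


def test_f2_formula():
    # collinear layout: both cross-segment distances inflate by exactly 1 Å
    q = fake_query([[0, 0, 0], [3, 0, 0]], [[10, 0, 0], [13, 0, 0]])
    s2 = q.segment2.ca + np.array([1.0, 0, 0])
    assert score_termini(q, q.segment1.ca, s2) == pytest.approx(2.0)
    assert score_termini(q, q.segment1.ca, q.segment2.ca) == 0.0


def test_f2_rigid_invariance(query, rng):
    s1, s2 = query.segment1.ca * 1.1, query.segment2.ca * 1.1
    base = score_termini(query, s1, s2)
    rot = fixtures.random_rotation(rng)
    t = rng.normal(size=3) * 15
    assert score_termini(query, s1 @ rot.T + t, s2 @ rot.T + t) == pytest.approx(
        base, abs=1e-6)


def test_f3_identity_offset_and_wrap(query):
    phi_q, psi_q = query.phi_psi()
    assert score_dihedrals(query, phi_q, psi_q) == 0.0
    # +10 deg on every psi, phi identical -> sqrt(n*100 / 2n) = sqrt(50)
    assert score_dihedrals(query, phi_q, psi_q + 10) == pytest.approx(
        np.sqrt(50.0))
    # wrap: 179 vs -179 must contribute 2 deg, not 358
    q = fake_query([[0, 0, 0], [1, 0, 0]], [[5, 0, 0], [6, 0, 0]],
                   phi=[np.nan, 179.0], psi=[179.0, np.nan])
    phi_s = np.array([np.nan, -179.0, np.nan, -179.0])
    psi_s = np.array([-179.0, np.nan, -179.0, np.nan])
    # 4 comparable angles over 4 residues, each deviation 2 deg
    assert score_dihedrals(q, phi_s, psi_s) == pytest.approx(
        np.sqrt(4 * 4.0 / (2 * 4)))


def test_f3_no_comparable_angles_raises():
    q = fake_query([[0, 0, 0], [1, 0, 0]], [[5, 0, 0], [6, 0, 0]])
    with pytest.raises(ValueError):
        score_dihedrals(q, np.full(4, np.nan), np.full(4, np.nan))


# --------------------------------------------------------------------- scanning


def test_scan_exhaustive_count(query):
    # break-free chain: for each gap g, L - k1 - k2 - g windows
    subject = fixtures.random_coil(40, seed=11)
    wins = scan_structure(subject, query, order="forward")["A"]
    L, k1, k2 = 40, query.k1, query.k2
    expected = sum(L - k1 - k2 - g for g in range(1, L - k1 - k2))
    assert len(wins) == expected
    assert all(w.l + k1 + w.g + k2 < L for w in wins)
    assert all(w.f1 >= 0 and w.f2 >= 0 and w.f3 >= 0 for w in wins)


def test_scan_short_chain_empty(query):
    k1, k2 = query.k1, query.k2
    subject = fixtures.random_coil(k1 + k2 + 1, seed=3)  # one short of a window
    assert scan_structure(subject, query, order="forward")["A"] == []


def test_planted_motif_rank_one(donor, query, planted):
    subject, offset = planted
    hits = tiered_search([subject], query, TierConfig(top_m=100))
    best = hits[0]
    assert best.window.l == offset + 3  # donor flank = 3
    assert best.window.g == 7           # gap 6 residues = index offset 7
    assert not best.window.swapped
    assert best.rmsd < 1e-6
    assert best.window.f1 < 1e-6 and best.window.f2 < 1e-6
    assert best.window.f3 < 1e-3
    assert len(best.mapping) == query.k1 + query.k2 + 2


def test_self_hit_on_donor(donor, query):
    hits = tiered_search([donor], query, TierConfig(top_m=50), order="forward")
    assert hits[0].window.l == 3 and hits[0].window.g == 7
    assert hits[0].rmsd < 1e-9


def test_tier_monotonicity(donor, query, planted):
    subject, _ = planted
    loose: dict = {}
    tight: dict = {}
    h_loose = tiered_search([subject], query,
                            TierConfig(f1_max=50.0, f2_max=50.0, f3_max=100.0),
                            attrition=loose)
    h_tight = tiered_search([subject], query,
                            TierConfig(f1_max=10.0, f2_max=50.0, f3_max=100.0),
                            attrition=tight)
    assert len(h_tight) <= len(h_loose)
    keys = {(h.structure_id, h.chain_id, h.window.l, h.window.g, h.window.swapped)
            for h in h_loose}
    assert all((h.structure_id, h.chain_id, h.window.l, h.window.g,
                h.window.swapped) in keys for h in h_tight)
    assert tight["f1"] <= loose["f1"]


def test_rmsd_invariant_under_subject_rigid_motion(query, planted, rng):
    subject, _ = planted
    moved = fixtures.transform_structure(
        subject, fixtures.random_rotation(rng), rng.normal(size=3) * 40)
    h1 = tiered_search([subject], query, TierConfig(top_m=20))
    h2 = tiered_search([moved], query, TierConfig(top_m=20))
    r1 = [(h.window.l, h.window.g, round(h.rmsd, 6)) for h in h1]
    r2 = [(h.window.l, h.window.g, round(h.rmsd, 6)) for h in h2]
    assert r1 == r2


def test_swapped_order_finds_reversed_topology(donor, query):
    # scaffold with identical 3D epitope geometry but the two segments
    # appearing in reverse order along the sequence
    from rescaff.structio import Chain, Structure

    src = donor["A"].residues
    reordered = src[21:25] + src[15:21] + src[3:15]  # seg2, gap, seg1
    chain = Chain(id="A")
    for i, res in enumerate(reordered):
        chain.residues.append(Residue(name=res.name, resseq=i + 1,
                                      atoms=dict(res.atoms)))
    rev = Structure(id="reversed", chains=[chain])
    hits = tiered_search([rev], query, TierConfig(top_m=200), order="both")
    assert hits[0].window.swapped
    assert hits[0].window.l == 0 and hits[0].window.g == 7
    assert hits[0].rmsd < 1e-6


# ---------------------------------------------------------------------- grafting


def test_identity_graft_is_noop(donor):
    q = build_query(donor, "A", (4, 15), (22, 25), ["A4", "A15", "A22"])
    hits = tiered_search([donor], q, TierConfig(top_m=10), order="forward")
    plan, grafted, seq = graft_epitope(hits[0], q, donor)
    assert plan.n_effective == 0
    assert seq == donor["A"].sequence


def test_graft_onto_all_gly_scaffold(donor, query, planted):
    subject, _ = planted
    # rename every scaffold residue to glycine, then graft 8 hot spots
    for res in subject["A"].residues:
        res.name = "GLY"
    q = build_query(donor, "A", (4, 15), (22, 25),
                    ["A4", "A7", "A8", "A10", "A11", "A15", "A22", "A25"])
    hits = tiered_search([subject], q, TierConfig(top_m=10))
    plan, grafted, seq = graft_epitope(hits[0], q, subject)
    assert len(plan.substitutions) == 8
    assert plan.n_effective == 8
    assert seq.count("A") == 8
    # grafted positions carry the hot-spot identity
    subs = {lbl: to for lbl, _, to in plan.substitutions}
    assert all(to == "A" for to in subs.values())


def test_graft_fasta_round_trip(tmp_path, donor, query, planted):
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    subject, _ = planted
    q = build_query(donor, "A", (4, 15), (22, 25), ["A4"])
    hits = tiered_search([subject], q, TierConfig(top_m=5))
    _, _, seq = graft_epitope(hits[0], q, subject)
    f = tmp_path / "graft.fasta"
    SeqIO.write([SeqRecord(Seq(seq), id="graft")], f, "fasta")
    assert str(next(SeqIO.parse(f, "fasta")).seq) == seq
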