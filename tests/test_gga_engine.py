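"""Digestion/ligation chemistry and the hierarchical assembly grammar."""

import itertools
import random

import pytest

from moclokit import (
    AssemblyFailure,
    AssemblyPlan,
    DigestionError,
    FusionSiteTable,
    GrammarError,
    PlasmidRecord,
    digest,
    generate_fixture_part,
    ligate_pool,
    max_transcription_units,
    plan_bb2,
    plan_bb3,
    scan_recognition_sites,
    simulate_gga,
    validate_fusion_site_set,
)
from moclokit.fixtures import build_bb2_recipient, build_bb3_recipient, build_bb3_recipient_fs14, make_tu_parts
from moclokit.gga_engine import Fragment, canonical_circular, enumerate_circles
from moclokit.seqcore import reverse_complement

FORBIDDEN = ["GGTCTC", "GAAGAC"]


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def hand_built_circle():
    """60-nt circle with two outward-facing BsaI sites.

    Manual strand bookkeeping (independent of the digest implementation):
    the + site GGTCTC at 0 cuts the top strand after one spacer base, i.e.
    at index 7, and the bottom strand 4 later, excising top-strand word
    seq[7:11] = CATG. The - site GAGACC at 38 cuts the bottom strand two
    bases left of its recognition (top index 37) and the top strand 4
    earlier, at 33, excising seq[33:37] = GCTT. The insert fragment between
    the windows therefore carries left overhang CATG and right overhang
    GCTT around the 22-nt payload seq[11:33].
    """
    payload = "TTACGGATTCAGGTCAATCCAT"  # 22 nt, no BsaI site either strand
    filler = "CATTACCAATTAGCAA"  # 16 nt backbone filler
    seq = "GGTCTC" + "A" + "CATG" + payload + "GCTT" + "A" + "GAGACC" + filler
    assert len(seq) == 60
    return PlasmidRecord(id="hand60", sequence=seq), payload


class TestDigest:
    def test_two_sites_two_fragments_with_expected_overhangs(self, enzymes):
        plasmid, payload = hand_built_circle()
        frags = digest(plasmid, enzymes["BsaI"])
        assert len(frags) == 2
        insert = next(f for f in frags if not f.carries_recognition_site["BsaI"])
        backbone = next(f for f in frags if f.carries_recognition_site["BsaI"])
        assert insert.left_overhang == "CATG"
        assert insert.right_overhang == "GCTT"
        assert insert.core_sequence == payload
        assert backbone.left_overhang == "GCTT"
        assert backbone.right_overhang == "CATG"

    def test_base_conservation(self, enzymes):
        plasmid, _ = hand_built_circle()
        frags = digest(plasmid, enzymes["BsaI"])
        assert sum(len(f.owned_top) for f in frags) == len(plasmid.sequence)

    def test_zero_sites_left_uncut_with_flag(self, enzymes):
        plasmid = PlasmidRecord(id="p", sequence="ACGTAC" * 20)
        (frag,) = digest(plasmid, enzymes["BsaI"])
        assert frag.uncut
        assert any("uncut" in d for d in frag.diagnostics)

    def test_overlapping_cut_windows_unresolvable(self, enzymes):
        # + site cuts window [7,11); - site GAGACC at 13 cuts window [8,12)
        seq = "GGTCTC" + "A" + "TTACCG" + "GAGACC" + "CATTACCAATTAGCAACGTTACCAATTAGCAACG"
        plasmid = PlasmidRecord(id="p", sequence=seq)
        with pytest.raises(DigestionError):
            digest(plasmid, enzymes["BsaI"])

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_sites_k_fragments(self, enzymes, k):
        unit = "GGTCTC" + "A" + "ACGTTGCAGACCAATCCGGTTAAC"
        plasmid = PlasmidRecord(id="p", sequence=unit * k)
        frags = digest(plasmid, enzymes["BsaI"])
        assert len(frags) == k


# ---------------------------------------------------------------------------
# ligation
# ---------------------------------------------------------------------------


def frag(left, core, right, sid="f", sites=()):
    flags = {"BsaI": "BsaI" in sites, "BpiI": "BpiI" in sites}
    return Fragment(
        core_sequence=core, left_overhang=left, right_overhang=right,
        source_id=sid, carries_recognition_site=flags,
    )


def brute_force_circles(frags):
    """Independent enumerator: all subsets x orders x orientations."""
    found = set()
    n = len(frags)
    for k in range(1, n + 1):
        for subset in itertools.combinations(range(n), k):
            for perm in itertools.permutations(subset):
                for orient in itertools.product([False, True], repeat=k):
                    chain = [frags[i].flipped() if fl else frags[i] for i, fl in zip(perm, orient)]
                    if all(
                        chain[i].right_overhang == chain[(i + 1) % k].left_overhang
                        for i in range(k)
                    ):
                        found.add(canonical_circular("".join(f.owned_top for f in chain)))
    return found


class TestLigatePool:
    def test_forced_two_fragment_closure(self):
        a = frag("CATG", "AAATTTCCC", "GCTT", "A")
        b = frag("GCTT", "GGGTTTAAA", "CATG", "B")
        products = ligate_pool([a, b])
        assert len(products) == 1
        assert {j[0] for j in products[0].junctions} == {"CATG", "GCTT"}

    def test_recuttable_product_excluded(self, enzymes):
        a = frag("CATG", "AAGGTCTCAAA", "GCTT", "A", sites=("BsaI",))
        b = frag("GCTT", "GGGTTTAAA", "CATG", "B")
        assert ligate_pool([a, b], enzyme=enzymes["BsaI"]) == []
        kept = ligate_pool([a, b], enzyme=enzymes["BsaI"], include_recuttable=True)
        assert len(kept) == 1 and kept[0].recuttable

    def test_palindromic_two_copy_ambiguity(self):
        a = frag("CATG", "ATTATTACGAG", "CATG", "A")
        b = frag("CATG", "ATTATTACGAG", "CATG", "B")
        products = ligate_pool([a, b])
        # monomer circle, head-to-tail dimer and head-to-head dimer
        assert len(products) > 1

    def test_matches_brute_force_on_random_small_pools(self):
        overhangs = ["CATG", "GCTT", "CCGG", "GGAG", "ACTG", "TGCC"]
        rng = random.Random(20240917)
        for trial in range(40):
            pool = []
            for i in range(rng.randint(2, 5)):
                core = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 14)))
                pool.append(frag(rng.choice(overhangs), core, rng.choice(overhangs), f"f{i}"))
            got = {canonical_circular(p.plasmid.sequence) for p in ligate_pool(pool)}
            assert got == brute_force_circles(pool), f"trial {trial}"

    def test_empty_outcome_is_valid(self):
        a = frag("CATG", "AAATTTCCC", "GCTT", "A")
        b = frag("ACTG", "GGGTTTAAA", "TGCC", "B")
        assert ligate_pool([a, b]) == []


# ---------------------------------------------------------------------------
# grammar-level planning and simulation
# ---------------------------------------------------------------------------


class TestBB2:
    def test_promoter_cds_terminator_junctions(self, fs, enzymes):
        p, c, t = make_tu_parts(fs, seed=21)
        rec = build_bb2_recipient(fs, position=1, seed=1)
        product = simulate_gga(plan_bb2(p, c, t, rec, fs, position=1))
        words = [j[0] for j in product.junctions]
        assert words == fs.bb2_sites
        by_pair = {(j[1][0], j[1][1]): j[0] for j in product.junctions}
        assert by_pair[(p.id, c.id)] == "CATG"
        assert by_pair[(c.id, t.id)] == "GCTT"
        assert not scan_recognition_sites(product.plasmid, enzymes["BpiI"])

    def test_role_mismatch_rejected(self, fs):
        p, c, t = make_tu_parts(fs, seed=22)
        rec = build_bb2_recipient(fs, position=1, seed=1)
        with pytest.raises(GrammarError, match="role"):
            plan_bb2(p, t, c, rec, fs)

    def test_positional_recipient_enforced(self, fs):
        p, c, t = make_tu_parts(fs, seed=23)
        rec_ab = build_bb2_recipient(fs, position=1, seed=1)
        with pytest.raises(GrammarError, match="slot 2"):
            plan_bb2(p, c, t, rec_ab, fs, position=2)
        rec_bc = build_bb2_recipient(fs, position=2, seed=1)
        plan_bb2(p, c, t, rec_bc, fs, position=2)  # does not raise

    def test_incompatible_cds_overhang_fails_at_the_named_junction(self, fs, enzymes):
        p, _, t = make_tu_parts(fs, seed=24)
        bad_cds = generate_fixture_part("cds", 300, "AATG", fs.bb2_sites[2], FORBIDDEN, seed=5)
        rec = build_bb2_recipient(fs, position=1, seed=1)
        plan = AssemblyPlan(
            level="BB2",
            enzyme=enzymes["BpiI"],
            inserts=[p, bad_cds, t],
            recipient=rec,
            expected_junctions=fs.bb2_sites,
        )
        with pytest.raises(AssemblyFailure) as err:
            simulate_gga(plan)
        assert "CATG" in err.value.per_junction

    def test_insert_permutation_invariance(self, fs):
        p, c, t = make_tu_parts(fs, seed=25)
        rec = build_bb2_recipient(fs, position=1, seed=1)
        ref = None
        for perm in itertools.permutations([p, c, t]):
            plan = plan_bb2(p, c, t, rec, fs)
            plan.inserts = list(perm)
            seq = canonical_circular(simulate_gga(plan).plasmid.sequence)
            ref = ref or seq
            assert seq == ref


def _bb2_unit(fs, position, seed):
    p, c, t = make_tu_parts(fs, seed=seed)
    rec = build_bb2_recipient(fs, position=position, seed=seed)
    return simulate_gga(plan_bb2(p, c, t, rec, fs)), (p, c, t)


class TestBB3:
    def test_two_units_crispr_layout(self, fs, enzymes):
        units = [_bb2_unit(fs, pos, 30 + pos)[0].plasmid for pos in (1, 2)]
        rec = build_bb3_recipient(fs, n_units=2, seed=2, locus="CEN_ARS", marker="kanMX")
        product = simulate_gga(plan_bb3(units, rec, fs))
        words = [j[0] for j in product.junctions]
        assert words == fs.bb3_sites[:3]
        assert words[1] == "CCGG"  # unit1-unit2 junction
        assert not scan_recognition_sites(product.plasmid, enzymes["BsaI"])

    def test_eight_units_supported(self, fs):
        units = [_bb2_unit(fs, pos, 40 + pos)[0].plasmid for pos in range(1, 9)]
        rec = build_bb3_recipient(fs, n_units=8, seed=3)
        product = simulate_gga(plan_bb3(units, rec, fs))
        assert [j[0] for j in product.junctions] == fs.bb3_sites

    def test_positional_gap_rejected(self, fs):
        u1 = _bb2_unit(fs, 1, 51)[0].plasmid
        u3 = _bb2_unit(fs, 3, 53)[0].plasmid
        rec = build_bb3_recipient(fs, n_units=2, seed=4)
        with pytest.raises(GrammarError, match="contiguous"):
            plan_bb3([u1, u3], rec, fs)

    def test_direct_single_unit_route(self, fs):
        p, c, t = make_tu_parts(fs, seed=60)
        rec = build_bb3_recipient_fs14(fs, seed=6)
        plan = plan_bb3([(p, c, t)], rec, fs)
        assert plan.level == "BB3" and plan.enzyme.name == "BpiI"
        product = simulate_gga(plan)
        assert [j[0] for j in product.junctions] == fs.bb2_sites

    def test_bb2_product_is_a_valid_bb3_insert(self, fs, enzymes):
        """Hierarchy round trip: re-digesting a unit recovers payloads intact."""
        product, (p, c, t) = _bb2_unit(fs, 1, 70)
        frags = digest(product.plasmid, enzymes["BsaI"])
        free = [f for f in frags if not f.carries_recognition_site["BsaI"]]
        assert len(free) == 1
        tu = free[0]
        assert tu.left_overhang == fs.bb3_sites[0]
        assert tu.right_overhang == fs.bb3_sites[1]
        for part in (p, c, t):
            assert part.sequence in tu.full_span


class TestFusionSiteGrammar:
    @pytest.mark.parametrize(
        "n_sites,expected", [(9, 8), (3, 2), (2, 1)]
    )
    def test_max_units(self, fs, n_sites, expected):
        table = FusionSiteTable(bb2_sites=fs.bb2_sites, bb3_sites=fs.bb3_sites[:n_sites])
        assert max_transcription_units(table) == expected

    def test_default_table_clean_with_palindrome_warnings(self, fs):
        diags = validate_fusion_site_set(fs)
        assert not [d for d in diags if d["level"] == "error"]
        warned = {d["message"].split()[0] for d in diags if d["code"] == "palindrome"}
        assert warned == {"Fs2", "FsB"}

    def test_duplicate_site_error(self, fs):
        table = FusionSiteTable(
            bb2_sites=[fs.bb2_sites[0], fs.bb2_sites[1], fs.bb2_sites[2], fs.bb2_sites[0]],
            bb3_sites=fs.bb3_sites,
        )
        assert any(d["code"] == "duplicate" for d in validate_fusion_site_set(table))

    def test_reverse_complement_pair_error(self, fs):
        bb3 = list(fs.bb3_sites)
        bb3[3] = reverse_complement(bb3[2])
        table = FusionSiteTable(bb2_sites=fs.bb2_sites, bb3_sites=bb3)
        assert any(d["code"] == "directionality" for d in validate_fusion_site_set(table))

    def test_non_atg_fs2_flagged(self, fs):
        table = FusionSiteTable(
            bb2_sites=[fs.bb2_sites[0], "TTTT", fs.bb2_sites[2], fs.bb2_sites[3]],
            bb3_sites=fs.bb3_sites,
        )
        assert any(d["code"] == "start_codon" for d in validate_fusion_site_set(table))


class TestProtocolMetadata:
    def test_cycles_scale_with_insert_count(self, fs):
        from moclokit.gga_engine import thermocycling_protocol

        assert thermocycling_protocol(1)["cycles"] == 8
        assert thermocycling_protocol(8)["cycles"] == 50
        assert thermocycling_protocol(12)["cycles"] == 50
        cycles = [thermocycling_protocol(n)["cycles"] for n in range(1, 9)]
        assert cycles == sorted(cycles)
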