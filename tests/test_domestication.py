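"""Site removal by point mutation: correctness, minimality, codon awareness."""

import itertools

import pytest

from moclokit import (
    DomesticationError,
    PartRecord,
    domesticate_cds,
    domesticate_noncoding,
    find_internal_sites,
    generate_fixture_part,
    load_codon_usage,
)
from moclokit.seqcore import _motif_positions, translate_cds

FORBIDDEN = ["GGTCTC", "GAAGAC"]


def oracle_min_edit_count(seq, enzymes, max_k, margin, require_synonymous):
    """Exhaustive search: smallest number of base substitutions confined to the
    recognition spans that leaves the sequence site-free on both strands for
    all enzymes (and, for a CDS, translation-invariant). Independent of the
    production search: plain combinations over (position, base) candidates."""
    spans = set()
    for enz in enzymes:
        for pos, _strand in _motif_positions(seq, enz.recognition):
            spans.update(range(pos, pos + len(enz.recognition)))
    candidates = [
        (p, alt)
        for p in sorted(spans)
        if margin <= p < len(seq) - margin
        for alt in "ACGT"
        if alt != seq[p]
    ]
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(candidates, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) < k:
                continue
            cand = list(seq)
            for p, alt in combo:
                cand[p] = alt
            cand = "".join(cand)
            if any(_motif_positions(cand, e.recognition) for e in enzymes):
                continue
            if require_synonymous and translate_cds(cand) != translate_cds(seq):
                continue
            return k
    return None


class TestFindInternalSites:
    def test_planted_fixture_count(self, enzyme_list):
        part = generate_fixture_part(
            "cds", 600, "CATG", "GCTT", FORBIDDEN, n_internal_sites=1, seed=17
        )
        assert len(find_internal_sites(part, enzyme_list)) == 1

    def test_annotated_flanks_excluded(self, enzyme_list):
        seq = "GGTCTCA" + "ACGTTGCAGTTCCAATCCGGTTAAC" + "AGAGACC"
        part = PartRecord(
            id="flanked",
            role="linker",
            sequence=seq,
            metadata={"cloning_flanks": [(0, 7), (len(seq) - 7, len(seq))]},
        )
        assert find_internal_sites(part, enzyme_list) == []
        bare = PartRecord(id="bare", role="linker", sequence=seq)
        assert len(find_internal_sites(bare, enzyme_list)) == 2

    def test_reverse_strand_only_site(self, enzyme_list):
        part = PartRecord(id="rc", role="linker", sequence="AAATTTGAGACCAAATTTCC")
        hits = find_internal_sites(part, enzyme_list)
        assert [(h.enzyme_name, h.strand) for h in hits] == [("BsaI", "-")]


class TestDomesticateCds:
    def test_worked_example_single_synonymous_edit(self, usage, enzyme_list):
        # frame ATG|GGT|CTC|TAA carries an internal BsaI site
        cds = PartRecord(id="toy", role="cds", sequence="ATGGGTCTCTAA")
        out, edits = domesticate_cds(cds, usage, enzyme_list, boundary_margin=0)
        assert len(edits) == 1
        assert edits[0].synonymous
        assert translate_cds(out.sequence) == translate_cds(cds.sequence) == "MGL*"
        assert find_internal_sites(out, enzyme_list) == []

    def test_clean_cds_is_identity(self, usage, enzyme_list):
        cds = generate_fixture_part("cds", 300, "CATG", "GCTT", FORBIDDEN, seed=3)
        out, edits = domesticate_cds(cds, usage, enzyme_list)
        assert edits == []
        assert out.sequence == cds.sequence

    def test_idempotent(self, usage, enzyme_list):
        cds = generate_fixture_part(
            "cds", 450, "CATG", "GCTT", FORBIDDEN, n_internal_sites=2, seed=9
        )
        once, edits = domesticate_cds(cds, usage, enzyme_list)
        assert edits
        twice, edits2 = domesticate_cds(once, usage, enzyme_list)
        assert edits2 == []
        assert twice.sequence == once.sequence

    @pytest.mark.parametrize("seed", range(40))
    def test_random_fixtures_site_free_translation_invariant_minimal(
        self, usage, enzyme_list, seed
    ):
        n_sites = 1 + seed % 2
        motif = FORBIDDEN[seed % 2]
        cds = generate_fixture_part(
            "cds", 390, "CATG", "GCTT", FORBIDDEN,
            n_internal_sites=n_sites, seed=5000 + seed, internal_site_motif=motif,
        )
        out, edits = domesticate_cds(cds, usage, enzyme_list)
        assert find_internal_sites(out, enzyme_list) == []
        assert translate_cds(out.sequence) == translate_cds(cds.sequence)
        assert all(e.synonymous for e in edits)
        k_min = oracle_min_edit_count(
            cds.sequence, enzyme_list, max_k=len(edits), margin=10, require_synonymous=True
        )
        assert len(edits) == k_min

    def test_usage_maximised_among_minimal_sets(self, usage, enzyme_list):
        # GGT|CTC spans two codons; several single-base synonymous edits kill
        # the site — the chosen one must carry the most-used resulting codon
        pad = "GCTGCAGCCGCAGCT"  # A A A A A padding codons
        cds = PartRecord(id="two_codon", role="cds", sequence=pad + "GGTCTC" + pad)
        out, edits = domesticate_cds(cds, usage, enzyme_list, boundary_margin=0)
        assert len(edits) == 1
        chosen = edits[0]
        start = chosen.codon_index * 3
        new_codon = out.sequence[start : start + 3]
        # recompute the best reachable usage among all destroying single edits
        best = 0.0
        for p in range(len(pad), len(pad) + 6):
            ci = p // 3
            old = cds.sequence[ci * 3 : ci * 3 + 3]
            for alt in "ACGT":
                if alt == cds.sequence[p]:
                    continue
                cand_codon = old[: p % 3] + alt + old[p % 3 + 1 :]
                cand_seq = cds.sequence[:p] + alt + cds.sequence[p + 1 :]
                if translate_cds(cand_seq) != translate_cds(cds.sequence):
                    continue
                if any(_motif_positions(cand_seq, e.recognition) for e in enzyme_list):
                    continue
                best = max(best, usage.frequency[cand_codon])
        assert usage.frequency[new_codon] == pytest.approx(best)

    def test_unremovable_when_margin_excludes_all_edits(self, usage, enzyme_list):
        cds = PartRecord(id="tight", role="cds", sequence="ATGGGTCTCTAA")
        with pytest.raises(DomesticationError, match="undomesticatable|not .*removable"):
            domesticate_cds(cds, usage, enzyme_list, boundary_margin=10)

    def test_rejects_non_cds(self, usage, enzyme_list):
        part = generate_fixture_part("promoter", 100, None, None, FORBIDDEN, seed=1)
        with pytest.raises(DomesticationError):
            domesticate_cds(part, usage, enzyme_list)


class TestDomesticateNoncoding:
    def test_promoter_edit_carries_warning(self, enzyme_list):
        part = generate_fixture_part(
            "promoter", 500, None, None, FORBIDDEN,
            n_internal_sites=1, seed=3, internal_site_motif="GAAGAC",
        )
        out, edits, warnings = domesticate_noncoding(part, enzyme_list)
        assert len(edits) == 1
        assert len(warnings) == 1 and "regulatory" in warnings[0]
        assert find_internal_sites(out, enzyme_list) == []

    def test_linker_identity_without_sites(self, enzyme_list):
        part = generate_fixture_part("linker", 80, None, None, FORBIDDEN, seed=4)
        out, edits, warnings = domesticate_noncoding(part, enzyme_list)
        assert (out.sequence, edits, warnings) == (part.sequence, [], [])

    def test_candidate_creating_new_site_is_skipped(self, enzyme_list):
        # editing A->G at offset 1 of GAAGACC would create GAGACC, a BsaI site
        # on the bottom strand; the chosen edit must avoid that trap
        seq = "TTCCATTGCC" + "GAAGACC" + "ATTGGCCTTA"
        part = PartRecord(id="trap", role="linker", sequence=seq)
        out, edits, _ = domesticate_noncoding(part, enzyme_list, boundary_margin=0)
        assert find_internal_sites(out, enzyme_list) == []
        assert (11, "G") not in {(e.position, e.alt_base) for e in edits}

    @pytest.mark.parametrize("seed", range(15))
    def test_random_noncoding_minimality(self, enzyme_list, seed):
        part = generate_fixture_part(
            "promoter", 400, None, None, FORBIDDEN,
            n_internal_sites=1 + seed % 2, seed=7000 + seed,
            internal_site_motif=FORBIDDEN[seed % 2],
        )
        out, edits, _ = domesticate_noncoding(part, enzyme_list)
        assert find_internal_sites(out, enzyme_list) == []
        k_min = oracle_min_edit_count(
            part.sequence, enzyme_list, max_k=len(edits), margin=10, require_synonymous=False
        )
        assert len(edits) == k_min


class TestCodonUsage:
    def test_families_sum_to_one(self, usage):
        sums = {}
        for codon, f in usage.frequency.items():
            aa = translate_cds(codon)
            sums[aa] = sums.get(aa, 0.0) + f
        for aa, total in sums.items():
            assert total == pytest.approx(1.0, abs=1e-9), aa

    def test_all_64_codons_present(self, usage):
        assert len(usage.frequency) == 64
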