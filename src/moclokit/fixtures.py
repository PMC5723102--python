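"""Synthetic donor/recipient plasmid builders for assembly simulation.

The published module and backbone sequences live in supplementary material
and a deposited kit, so simulations run on synthetic stand-ins: payloads are
random fixture parts and the plasmids built here reproduce the *geometry*
that matters for Golden Gate chemistry — recognition sites placed so the cut
windows fall exactly on the fusion-site words, recognition sequences retained
on the fragment that must be re-cut, and backbones free of stray sites.

All randomness is driven by :class:`moclokit.seqcore.PortableRNG`, so every
builder is bit-reproducible given its arguments and seed.
"""

from __future__ import annotations

from .exceptions import GenerationError
from .seqcore import (
    Enzyme,
    PartRecord,
    PlasmidRecord,
    PortableRNG,
    _motif_positions,
    generate_fixture_part,
    load_enzymes,
    reverse_complement,
    scan_recognition_sites,
)

#: default motifs scrubbed from every fixture backbone/payload (both strands)
def _default_forbidden():
    enz = load_enzymes()
    return [enz["BsaI"].recognition, enz["BpiI"].recognition]


def random_clean_sequence(length: int, forbidden, seed: int) -> str:
    """Random sequence free of the forbidden motifs on either strand."""
    rng = PortableRNG(seed)
    for _ in range(200):
        seq = "".join(rng.choice("ACGT") for _ in range(length))
        for _ in range(200):
            dirty = [(p, m) for m in forbidden for p, _ in _motif_positions(seq, m)]
            if not dirty:
                return seq
            p, m = dirty[0]
            j = p + rng.randint(len(m))
            seq = seq[:j] + rng.choice("ACGT") + seq[j + 1 :]
    raise GenerationError("could not scrub forbidden motifs from backbone filler")


def _spacer(n: int) -> str:
    return "A" * n


def _validate_plasmid_sites(plasmid: PlasmidRecord, enzyme: Enzyme, expected: int, label: str):
    hits = scan_recognition_sites(plasmid, enzyme)
    if len(hits) != expected:
        raise GenerationError(
            f"{label}: expected {expected} {enzyme.name} sites, found {len(hits)} "
            "(a junction created or destroyed a site; try another seed)"
        )


def build_donor_plasmid(part: PartRecord, enzyme: Enzyme, seed: int = 0) -> PlasmidRecord:
    """Circular donor carrying ``part`` flanked by outward-cutting sites.

    Digestion with ``enzyme`` excises the payload with the part's declared
    fusion sites as its 5' overhangs; both recognition sequences stay on the
    backbone fragment, which therefore remains re-cuttable.
    """
    if part.left_fusion_site is None or part.right_fusion_site is None:
        raise GenerationError(f"part {part.id!r} lacks fusion sites; cannot build donor")
    other = [m for m in _default_forbidden() if m != enzyme.recognition]
    for attempt in range(10):
        filler = random_clean_sequence(60, _default_forbidden(), seed + 7919 * attempt)
        seq = (
            enzyme.recognition
            + _spacer(enzyme.spacer_len)
            + part.left_fusion_site
            + part.sequence
            + part.right_fusion_site
            + _spacer(enzyme.spacer_len)
            + reverse_complement(enzyme.recognition)
            + filler
        )
        plasmid = PlasmidRecord(
            id=f"donor_{part.id}",
            sequence=seq,
            features=[
                (
                    part.id,
                    len(enzyme.recognition) + enzyme.spacer_len + 4,
                    len(enzyme.recognition) + enzyme.spacer_len + 4 + len(part.sequence),
                    "+",
                )
            ],
            metadata={"payload": part.id, "enzyme": enzyme.name, "synthetic": True},
        )
        try:
            n_internal = len(_motif_positions(part.sequence, enzyme.recognition))
            _validate_plasmid_sites(plasmid, enzyme, 2 + n_internal, plasmid.id)
            for m in other:
                if _motif_positions(plasmid.sequence + plasmid.sequence[:8], m):
                    raise GenerationError(f"{plasmid.id}: stray site {m}")
        except GenerationError:
            if attempt == 9:
                raise
            continue
        return plasmid
    raise GenerationError(f"could not build donor for {part.id!r}")


def _recipient(
    plasmid_id: str,
    left_word: str,
    right_word: str,
    enzyme: Enzyme,
    seed: int,
    outer: tuple | None = None,
    outer_enzyme: Enzyme | None = None,
    features=(),
    metadata=None,
):
    """Generic recipient: a backbone whose linker is excised by ``enzyme``.

    The linker carries both recognition sequences pointing outward, so the
    excised backbone fragment is site-free with ``left_word``/``right_word``
    as its overhangs. If ``outer`` is given, the backbone additionally carries
    ``outer_enzyme`` sites cutting at the outer words, for release of the
    whole assembled region at the next hierarchy level.
    """
    rc_rec = reverse_complement(enzyme.recognition)
    for attempt in range(10):
        rngseed = seed + 104729 * attempt
        stuffer = random_clean_sequence(80, _default_forbidden(), rngseed)
        backbone = random_clean_sequence(220, _default_forbidden(), rngseed + 1)
        linker = (
            left_word
            + _spacer(enzyme.spacer_len)
            + rc_rec
            + stuffer
            + enzyme.recognition
            + _spacer(enzyme.spacer_len)
            + right_word
        )
        if outer is not None:
            left_outer, right_outer = outer
            oe = outer_enzyme
            pre = oe.recognition + _spacer(oe.spacer_len) + left_outer
            post = right_outer + _spacer(oe.spacer_len) + reverse_complement(oe.recognition)
            seq = pre + linker + post + backbone
            payload_sites = {enzyme.name: 2, oe.name: 2}
        else:
            seq = linker + backbone
            payload_sites = {enzyme.name: 2}
        feats = [("linker", 0, len(seq) - len(backbone), "+")] + [
            (label, len(seq) - len(backbone) + off, len(seq) - len(backbone) + off + 30, "+")
            for off, label in zip((10, 60, 110, 160), features)
        ]
        plasmid = PlasmidRecord(
            id=plasmid_id,
            sequence=seq,
            features=feats,
            metadata=dict(metadata or {}, synthetic=True),
        )
        try:
            enz = load_enzymes()
            for name, expected in payload_sites.items():
                _validate_plasmid_sites(plasmid, enz[name], expected, plasmid_id)
        except GenerationError:
            if attempt == 9:
                raise
            continue
        return plasmid
    raise GenerationError(f"could not build recipient {plasmid_id!r}")


def build_bb2_recipient(fs, position: int = 1, seed: int = 0) -> PlasmidRecord:
    """Recipient for one transcription unit destined for BB3 slot ``position``.

    Its BpiI linker leaves Fs4/Fs1 backbone overhangs; the backbone carries
    BsaI sites cutting at the positional words Fs(A+position-1)/Fs(A+position),
    mirroring the published BB2_AB, BB2_BC, ... series.
    """
    enz = load_enzymes()
    if not (1 <= position <= len(fs.bb3_sites) - 1):
        raise GenerationError(f"no positional recipient for slot {position}")
    left_outer = fs.bb3_sites[position - 1]
    right_outer = fs.bb3_sites[position]
    name = f"BB2_{fs.bb3_names[position - 1]}_{fs.bb3_names[position]}"
    return _recipient(
        name,
        fs.bb2_sites[0],
        fs.bb2_sites[3],
        enz["BpiI"],
        seed,
        outer=(left_outer, right_outer),
        outer_enzyme=enz["BsaI"],
        features=("BBa_B1007_terminator", "ori", "resistance_cassette"),
        metadata={
            "level": "BB2",
            "position": position,
            "outer_sites": (fs.bb3_names[position - 1], fs.bb3_names[position]),
        },
    )


def build_bb3_recipient(fs, n_units: int, seed: int = 0, locus: str = "RGI2", marker: str = "kanMX") -> PlasmidRecord:
    """Recipient for ``n_units`` transcription units (BsaI linker FsA..Fs(A+n))."""
    if not (1 <= n_units <= len(fs.bb3_sites) - 1):
        raise GenerationError(
            f"{n_units} units exceed the {len(fs.bb3_sites)}-site positional grammar"
        )
    enz = load_enzymes()
    first = fs.bb3_sites[0]
    last = fs.bb3_sites[n_units]
    name = f"BB3_{fs.bb3_names[0]}_{fs.bb3_names[n_units]}"
    return _recipient(
        name,
        first,
        last,
        enz["BsaI"],
        seed,
        features=(f"locus_{locus}", f"marker_{marker}", "ori"),
        metadata={"level": "BB3", "n_units": n_units, "locus": locus, "marker": marker},
    )


def build_bb3_recipient_fs14(fs, seed: int = 0, locus: str = "RGI2", marker: str = "kanMX") -> PlasmidRecord:
    """BB3 recipient with a BpiI Fs1-Fs4 linker for the direct single-unit route."""
    enz = load_enzymes()
    return _recipient(
        "BB3_Fs1_Fs4",
        fs.bb2_sites[0],
        fs.bb2_sites[3],
        enz["BpiI"],
        seed,
        features=(f"locus_{locus}", f"marker_{marker}", "ori"),
        metadata={"level": "BB3", "direct_route": True, "locus": locus, "marker": marker},
    )


def make_tu_parts(
    fs,
    seed: int = 0,
    promoter_len: int = 500,
    cds_len: int = 900,
    terminator_len: int = 250,
    names: tuple = ("P_fix", "cds_fix", "tt_fix"),
):
    """A promoter/CDS/terminator fixture triple wired for one transcription unit."""
    forb = _default_forbidden()
    # sub-seeds are spread multiplicatively so triples built from nearby base
    # seeds never share an RNG stream (identical prefixes would read as repeats)
    base = seed * 7919
    promoter = generate_fixture_part(
        "promoter", promoter_len, fs.bb2_sites[0], fs.bb2_sites[1], forb, seed=base + 1
    )
    cds = generate_fixture_part(
        "cds", cds_len, fs.bb2_sites[1], fs.bb2_sites[2], forb, seed=base + 2
    )
    terminator = generate_fixture_part(
        "terminator", terminator_len, fs.bb2_sites[2], fs.bb2_sites[3], forb, seed=base + 3
    )
    for part, nm in zip((promoter, cds, terminator), names):
        part.id = f"{nm}_{seed}"
        part.metadata["registry_name"] = nm
    return promoter, cds, terminator
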