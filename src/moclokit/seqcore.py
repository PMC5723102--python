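"""Sequence data model, FASTA/GenBank I/O, strand arithmetic and fixture generation.

Coordinate convention (used package-wide): 0-based, half-open intervals on the
top strand. Circular coordinates are taken modulo the sequence length and no
feature exceeds one full wrap of the circle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .exceptions import AlphabetError, GenerationError, ParseError

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PART_ROLES = (
    "promoter",
    "cds",
    "terminator",
    "linker",
    "resistance_cassette",
    "integration_locus",
    "ori",
    "reporter",
)

#: Sense codons only -- fixture CDSs must translate without internal stops.
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def check_alphabet(seq: str, context: str = "sequence") -> str:
    """Uppercase ``seq`` and reject anything outside {A,C,G,T}.

    IUPAC ambiguity codes are rejected rather than expanded: junction
    arithmetic in the assembly engine needs concrete bases.
    """
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"{context} contains non-ACGT characters: {sorted(bad)!r} "
            "(IUPAC ambiguity codes are not supported)"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (involution on valid input)."""
    seq = check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(seq: str) -> str:
    """Translate a codon-aligned CDS payload (standard code, no implicit stop)."""
    if len(seq) % 3:
        raise ValueError("CDS length must be divisible by 3")
    return str(Seq(seq).translate())


class PortableRNG:
    """Deterministic 64-bit linear congruential generator.

    Fixtures must be bit-reproducible across platforms and Python builds, so
    randomness is generated by this LCG (Knuth's MMIX multiplier) rather than
    a library generator whose stream could change between versions.
    """

    _A = 6364136223846793005
    _C = 1442695040888963407
    _MASK = (1 << 64) - 1

    def __init__(self, seed: int):
        self.state = (int(seed) ^ 0x9E3779B97F4A7C15) & self._MASK
        self._next()  # discard first output; low entropy for small seeds

    def _next(self) -> int:
        self.state = (self.state * self._A + self._C) & self._MASK
        return self.state >> 33  # top bits have the best statistics

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n) by rejection (no modulo bias)."""
        if n <= 0:
            raise ValueError("n must be positive")
        span = (1 << 31) - ((1 << 31) % n)
        while True:
            x = self._next()
            if x < span:
                return x % n

    def choice(self, seq):
        return seq[self.randint(len(seq))]


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class PartRecord:
    """A basic genetic element (always linear) with optional 4-nt fusion sites.

    The ``sequence`` is the part payload *excluding* its fusion sites; a CDS is
    stored without its start codon, which is contributed by the promoter-side
    fusion site (whose last three bases are ATG).
    """

    id: str
    role: str
    sequence: str
    left_fusion_site: str | None = None
    right_fusion_site: str | None = None
    metadata: dict = field(default_factory=dict)
    topology: str = "linear"

    def __post_init__(self):
        if self.role not in PART_ROLES:
            raise ValueError(f"unknown part role {self.role!r}")
        self.sequence = check_alphabet(self.sequence, f"part {self.id!r}")
        if not self.sequence:
            raise ValueError(f"part {self.id!r} has an empty sequence")
        for name, fs in (("left", self.left_fusion_site), ("right", self.right_fusion_site)):
            if fs is not None:
                fs = check_alphabet(fs, f"{name} fusion site of {self.id!r}")
                if len(fs) != 4:
                    raise ValueError(f"{name} fusion site of {self.id!r} must be 4 nt")
                setattr(self, f"{name}_fusion_site", fs)
        if self.role == "cds" and len(self.sequence) % 3:
            raise ValueError(
                f"CDS {self.id!r} length {len(self.sequence)} not divisible by 3 "
                "(the ATG start codon is contributed by the promoter-side fusion site)"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass
class PlasmidRecord:
    """A circular DNA molecule with (label, start, end, strand) features."""

    id: str
    sequence: str
    features: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    topology: str = "circular"

    def __post_init__(self):
        self.sequence = check_alphabet(self.sequence, f"plasmid {self.id!r}")
        if not self.sequence:
            raise ValueError(f"plasmid {self.id!r} has an empty sequence")
        n = len(self.sequence)
        for label, start, end, strand in self.features:
            if not (0 <= start < n and 0 < end <= 2 * n and end - start <= n):
                raise ValueError(
                    f"feature {label!r} of {self.id!r} exceeds one wrap of the circle"
                )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class Enzyme:
    """A type IIs restriction enzyme cutting outside its recognition sequence.

    ``spacer_len`` is the gap between the recognition sequence and the cut
    window; ``overhang_len`` is the length of the 5' single-stranded overhang
    left by the staggered cut (4 for both enzymes of this system).
    """

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int = 4

    def __post_init__(self):
        object.__setattr__(self, "recognition", check_alphabet(self.recognition))

    @property
    def rc_recognition(self) -> str:
        return reverse_complement(self.recognition)


@dataclass
class SiteHit:
    """One recognition-sequence occurrence and its computed cut window.

    ``cut_top``/``cut_bottom`` are the top-strand indices at which the top and
    bottom strands are severed; they always differ by the 4-nt overhang length,
    with ``cut_top`` the left edge of the excised 4-mer window.
    """

    enzyme_name: str
    position: int
    strand: str
    cut_top: int
    cut_bottom: int
    valid: bool = True
    diagnostic: str = ""


# ---------------------------------------------------------------------------
# Enzyme configuration
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("moclokit").joinpath("data", name)


def load_enzymes(path=None) -> dict:
    """Load enzyme definitions from YAML (shipped REBASE defaults if no path)."""
    text = Path(path).read_text() if path else _data_path("enzymes.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, d in raw["enzymes"].items():
        out[name] = Enzyme(
            name=name,
            recognition=d["recognition"],
            spacer_len=int(d["spacer_len"]),
            overhang_len=int(d.get("overhang_len", 4)),
        )
    return out


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------


def parse_sequence_record(source, format: str = "fasta", role: str = "linker"):
    """Read one FASTA/GenBank record into a PartRecord or PlasmidRecord.

    GenBank topology comes from the LOCUS line; FASTA defaults to linear.
    Circular records become :class:`PlasmidRecord`, linear ones
    :class:`PartRecord` with the supplied ``role``.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, (str, Path)) and Path(str(source)).exists():
        handle = open(source)
    else:
        handle = io.StringIO(str(source))
    try:
        records = list(SeqIO.parse(handle, format))
    except Exception as exc:  # biopython raises assorted ValueErrors
        raise ParseError(f"malformed {format} input: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise ParseError(f"no {format} record found in input")
    rec = records[0]
    seq = check_alphabet(str(rec.seq), f"record {rec.id!r}")
    topology = rec.annotations.get("topology", "linear")
    if topology == "circular":
        feats = [
            (
                f.qualifiers.get("label", [f.type])[0],
                int(f.location.start),
                int(f.location.end),
                "+" if (f.location.strand or 1) >= 0 else "-",
            )
            for f in rec.features
            if f.type != "source"
        ]
        return PlasmidRecord(id=rec.id, sequence=seq, features=feats)
    meta = {"description": rec.description} if rec.description else {}
    return PartRecord(id=rec.id, role=role, sequence=seq, metadata=meta)


def write_record(record, path, format: str = "genbank"):
    """Write a record to FASTA or GenBank (features become misc_feature/label)."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    if isinstance(record, PlasmidRecord):
        n = len(record.sequence)
        for label, start, end, strand in record.features:
            loc = FeatureLocation(start, min(end, n), strand=1 if strand == "+" else -1)
            rec.features.append(
                SeqFeature(loc, type="misc_feature", qualifiers={"label": [label]})
            )
    SeqIO.write(rec, str(path), format)
    return path


# ---------------------------------------------------------------------------
# Recognition-site scanning
# ---------------------------------------------------------------------------


def _find_all(haystack: str, needle: str):
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


def scan_recognition_sites(record, enzyme: Enzyme) -> list:
    """All recognition-sequence occurrences on both strands, with cut windows.

    On circular records matches spanning the origin are found by scanning the
    doubled sequence restricted to start positions below the length, and cut
    indices are reduced modulo the length. On linear records a cut window that
    falls off either end is reported but flagged invalid.
    """
    seq = record.sequence
    n = len(seq)
    circular = record.topology == "circular"
    search = seq + seq[: len(enzyme.recognition) - 1 + enzyme.spacer_len + enzyme.overhang_len] if circular else seq
    hits = []
    for strand, motif in (("+", enzyme.recognition), ("-", enzyme.rc_recognition)):
        for pos in _find_all(search, motif):
            if circular and pos >= n:
                continue
            if strand == "+":
                w = pos + len(enzyme.recognition) + enzyme.spacer_len
            else:
                w = pos - enzyme.spacer_len - enzyme.overhang_len
            valid, diag = True, ""
            if circular:
                w %= n
            elif w < 0 or w + enzyme.overhang_len > n:
                valid, diag = False, "cut off end of linear sequence"
            hits.append(
                SiteHit(
                    enzyme_name=enzyme.name,
                    position=pos % n if circular else pos,
                    strand=strand,
                    cut_top=w,
                    cut_bottom=w + enzyme.overhang_len,
                    valid=valid,
                    diagnostic=diag,
                )
            )
    hits.sort(key=lambda h: (h.position, 0 if h.strand == "+" else 1))
    return hits


def cut_window(record, hit: SiteHit, enzyme: Enzyme) -> str:
    """The 4-nt top-strand word excised at a hit's cut window (wraps on circles)."""
    seq = record.sequence
    n = len(seq)
    if record.topology == "circular":
        return (seq + seq)[hit.cut_top : hit.cut_top + enzyme.overhang_len]
    return seq[hit.cut_top : hit.cut_bottom]


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def _motif_positions(seq: str, motif: str):
    """Occurrence start positions of motif on either strand of a linear seq."""
    hits = [(p, "+") for p in _find_all(seq, motif)]
    rc = reverse_complement(motif)
    if rc != motif:
        hits += [(p, "-") for p in _find_all(seq, rc)]
    return hits


def _random_payload(role: str, length: int, rng: PortableRNG) -> str:
    if role == "cds":
        n_codons = length // 3
        body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons - 1))
        return body + "TAA"
    return "".join(rng.choice("ACGT") for _ in range(length))


def _cds_ok(seq: str) -> bool:
    """No internal stop codons (the final codon is the intended stop)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3)]
    return all(c not in STOP_CODONS for c in codons)


def generate_fixture_part(
    role: str,
    length: int,
    left_fs: str | None,
    right_fs: str | None,
    forbidden_motifs,
    n_internal_sites: int = 0,
    seed: int = 0,
    internal_site_motif: str | None = None,
) -> PartRecord:
    """Deterministic random part with controlled internal-site content.

    The payload contains no occurrence of any forbidden motif on either
    strand; when ``n_internal_sites`` > 0, exactly that many occurrences of
    ``internal_site_motif`` (default: the first forbidden motif) are planted
    in the interior, at least 10 nt from either boundary. CDS payloads are
    codon-aligned, free of internal stops and end with TAA.
    """
    if length < 20:
        raise GenerationError("fixture length must be >= 20 nt")
    if role == "cds" and length % 3:
        raise GenerationError("CDS fixture length must be divisible by 3")
    forbidden = [check_alphabet(m) for m in forbidden_motifs]
    plant = check_alphabet(internal_site_motif) if internal_site_motif else (forbidden[0] if forbidden else None)
    if n_internal_sites and plant is None:
        raise GenerationError("cannot plant sites without a motif")
    rng = PortableRNG(seed)
    lf, rf = left_fs or "", right_fs or ""

    for _ in range(200):
        seq = _random_payload(role, length, rng)
        # scrub forbidden motifs by local re-randomisation; scan the payload
        # together with its fusion-site context so no motif straddles the
        # payload boundary once the part is wired into a donor plasmid
        for _ in range(200):
            dirty = [(p, m) for m in forbidden for p, _s in _motif_positions(lf + seq + rf, m)]
            if not dirty:
                break
            p, m = dirty[0]
            lo = max(p - len(lf), 0)  # payload span overlapped by the motif
            hi = min(p + len(m) - len(lf), length)
            if hi <= lo:
                break  # motif sits wholly inside the fixed fusion sites
            if role == "cds":
                ci = min(((lo + hi) // 2) // 3, length // 3 - 2) * 3
                seq = seq[:ci] + rng.choice(SENSE_CODONS) + seq[ci + 3 :]
            else:
                j = lo + rng.randint(hi - lo)
                seq = seq[:j] + rng.choice("ACGT") + seq[j + 1 :]
        if any(_motif_positions(lf + seq + rf, m) for m in forbidden):
            continue
        if role == "cds" and not _cds_ok(seq):
            continue
        if n_internal_sites:
            planted = _plant_sites(seq, plant, forbidden, n_internal_sites, role, rng, lf, rf)
            if planted is None:
                continue
            seq = planted
        rec = PartRecord(
            id=f"fixture_{role}_{seed}",
            role=role,
            sequence=seq,
            left_fusion_site=left_fs,
            right_fusion_site=right_fs,
            metadata={"synthetic": True, "seed": seed},
        )
        return rec
    raise GenerationError(
        f"could not satisfy fixture constraints (role={role}, length={length}, "
        f"forbidden={forbidden}, n_internal_sites={n_internal_sites})"
    )


def _plant_sites(seq, motif, forbidden, n, role, rng, lf="", rf=""):
    length = len(seq)
    lo, hi = 10, length - 10 - len(motif)
    if hi <= lo:
        return None
    for _ in range(300):
        cand = seq
        positions = set()
        for _ in range(n):
            p = lo + rng.randint(hi - lo)
            positions.add(p)
        if len(positions) < n:
            continue
        for p in positions:
            cand = cand[:p] + motif + cand[p + len(motif) :]
        ctx = lf + cand + rf
        counts = {m: len(_motif_positions(ctx, m)) for m in set(forbidden) | {motif}}
        others_clean = all(c == 0 for m, c in counts.items() if m != motif)
        if counts[motif] == n and others_clean and (role != "cds" or _cds_ok(cand)):
            return cand
    return None
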