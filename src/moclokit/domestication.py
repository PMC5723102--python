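"""Removal of internal type IIs sites from parts by point mutation.

Parts entering the assembly hierarchy must not contain internal recognition
sites of the reaction enzymes, or they are re-cut during the one-pot cycle.
Sites are therefore "domesticated": destroyed by point mutations. In coding
sequences every edit must be synonymous — the protein is untouchable — and
among minimal edit sets the one whose resulting codons are most frequent in
the host's codon-usage table is chosen. In non-coding parts any base change
is allowed but edits in promoters/terminators carry a warning, since no
functional-neutrality rule exists for regulatory DNA.

Edits never create a new site for any named enzyme, and are kept away from
the part boundaries (default 10 nt) to avoid disturbing fusion-site context.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import DomesticationError
from .seqcore import (
    PartRecord,
    SiteHit,
    _data_path,
    _motif_positions,
    check_alphabet,
    translate_cds,
)

DEFAULT_BOUNDARY_MARGIN = 10


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

_CODON_AA = {}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            _codon = _a + _b + _c
            _CODON_AA[_codon] = translate_cds(_codon)


@dataclass
class CodonUsageTable:
    """Relative synonymous codon usage: per-codon fraction within its family."""

    organism: str
    frequency: dict  # codon -> fraction, families summing to 1

    def __post_init__(self):
        by_aa = {}
        for codon, f in self.frequency.items():
            by_aa.setdefault(_CODON_AA[codon], 0.0)
            by_aa[_CODON_AA[codon]] += f
        for aa, total in by_aa.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"codon usage for {aa!r} sums to {total}, expected 1"
                )

    def synonyms(self, codon: str):
        aa = _CODON_AA[codon]
        return [c for c, a in _CODON_AA.items() if a == aa]


def load_codon_usage(path=None, organism: str = "P. pastoris") -> CodonUsageTable:
    """Load a codon table (TSV: codon, amino_acid, per_thousand) and normalise
    counts to within-family fractions."""
    src = Path(path) if path else _data_path("codon_usage_pichia.tsv")
    df = pd.read_csv(src, sep="\t")
    df["codon"] = df["codon"].str.upper()
    fam_total = df.groupby(df["codon"].map(_CODON_AA))["per_thousand"].transform("sum")
    freq = dict(zip(df["codon"], df["per_thousand"] / fam_total))
    return CodonUsageTable(organism=organism, frequency=freq)


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomesticationEdit:
    """One point mutation: 0-based position, reference and alternate base."""

    position: int
    ref_base: str
    alt_base: str
    codon_index: int | None = None
    synonymous: bool = False
    usage_delta: float = 0.0

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("edit must change the base")


def find_internal_sites(part: PartRecord, enzymes) -> list:
    """All recognition occurrences on either strand of a part's payload.

    Occurrences overlapping annotated cloning flanks — half-open spans in
    ``part.metadata['cloning_flanks']`` — are the intended cloning sites and
    are excluded (by annotation, not by position heuristics).
    """
    flanks = [tuple(span) for span in part.metadata.get("cloning_flanks", [])]
    hits = []
    for enz in enzymes:
        m = len(enz.recognition)
        for pos, strand in _motif_positions(part.sequence, enz.recognition):
            if any(pos < e and pos + m > s for s, e in flanks):
                continue
            if strand == "+":
                w = pos + m + enz.spacer_len
            else:
                w = pos - enz.spacer_len - enz.overhang_len
            hits.append(
                SiteHit(
                    enzyme_name=enz.name,
                    position=pos,
                    strand=strand,
                    cut_top=w,
                    cut_bottom=w + enz.overhang_len,
                    valid=0 <= w and w + enz.overhang_len <= len(part.sequence),
                )
            )
    hits.sort(key=lambda h: (h.position, 0 if h.strand == "+" else 1))
    return hits


def _apply(seq: str, edits) -> str:
    s = list(seq)
    for e in edits:
        if s[e.position] != e.ref_base:
            raise DomesticationError(f"edit at {e.position} expects {e.ref_base}")
        s[e.position] = e.alt_base
    return "".join(s)


def _site_free(seq: str, enzymes) -> bool:
    return not any(_motif_positions(seq, enz.recognition) for enz in enzymes)


# ---------------------------------------------------------------------------
# CDS domestication
# ---------------------------------------------------------------------------


def _codon_swap_actions(seq, span, usage, margin):
    """Candidate synonymous codon replacements for codons overlapping a site span.

    Each action is a tuple of DomesticationEdits confined to one codon,
    ordered by cost (number of changed bases). Single-base synonymous edits
    appear as cost-1 actions; full codon swaps cover the escalation path.
    """
    n = len(seq)
    actions = []
    codons = {p // 3 for p in span if margin <= p < n - margin}
    for ci in sorted(codons):
        start = ci * 3
        old = seq[start : start + 3]
        f_old = usage.frequency.get(old, 0.0)
        for new in usage.synonyms(old):
            if new == old:
                continue
            edits = tuple(
                DomesticationEdit(
                    position=start + k,
                    ref_base=old[k],
                    alt_base=new[k],
                    codon_index=ci,
                    synonymous=True,
                    usage_delta=usage.frequency.get(new, 0.0) - f_old,
                )
                for k in range(3)
                if old[k] != new[k]
            )
            if not edits:
                continue
            if any(e.position < margin or e.position >= n - margin for e in edits):
                continue
            actions.append((edits, usage.frequency.get(new, 0.0)))
    return actions


def _choose_minimal(seq, per_site_actions, enzymes, scorer):
    """Smallest-cost combination of one action per residual site that leaves the
    sequence site-free without creating new sites; ties broken by score then
    by 5'-most position and alphabetical alternate base."""
    if not per_site_actions:
        return ()
    best = None
    # try all combinations, one action per site (actions may fix several sites
    # at once, so also try subsets via the empty action)
    pools = [acts + [((), 0.0)] for acts in per_site_actions]
    for combo in itertools.product(*pools):
        edits = []
        seen_pos = set()
        ok = True
        for action, _score in combo:
            for e in action:
                if e.position in seen_pos:
                    ok = False
                    break
                seen_pos.add(e.position)
                edits.append(e)
            if not ok:
                break
        if not ok or not edits:
            continue
        cand = _apply(seq, edits)
        if not _site_free(cand, enzymes):
            continue
        cost = len(edits)
        score = scorer(combo)
        poskey = tuple(sorted((e.position, e.alt_base) for e in edits))
        key = (cost, -score, poskey)
        if best is None or key < best[0]:
            best = (key, tuple(sorted(edits, key=lambda e: e.position)))
    return None if best is None else best[1]


def domesticate_cds(cds: PartRecord, usage: CodonUsageTable, enzymes, boundary_margin: int = DEFAULT_BOUNDARY_MARGIN):
    """Remove all internal sites from a CDS by synonymous point mutations.

    The returned part is site-free for every named enzyme on both strands and
    translates identically to the input. The edit set is minimal in count;
    among minimal sets the summed usage of the altered codons is maximal.
    Raises if a site survives every synonymous codon swap across its span.
    """
    if cds.role != "cds":
        raise DomesticationError(f"part {cds.id!r} is not a CDS")
    seq = cds.sequence
    hits = find_internal_sites(cds, enzymes)
    if not hits:
        return cds, []
    rec_len = {e.name: len(e.recognition) for e in enzymes}
    per_site = []
    for h in hits:
        span = range(h.position, h.position + rec_len[h.enzyme_name])
        actions = _codon_swap_actions(seq, span, usage, boundary_margin)
        # keep only actions that actually destroy this occurrence
        motif = seq[span.start : span.stop]
        destroying = [
            (edits, score)
            for edits, score in actions
            if _apply(seq, edits)[span.start : span.stop] != motif
        ]
        if not destroying:
            raise DomesticationError(
                f"site {h.enzyme_name}@{h.position} ({h.strand}) in {cds.id!r} is not "
                "removable by synonymous edits (undomesticatable)"
            )
        per_site.append(destroying)
    chosen = _choose_minimal(
        seq, per_site, enzymes, scorer=lambda combo: sum(s for a, s in combo if a)
    )
    if chosen is None:
        raise DomesticationError(
            f"{cds.id!r}: no synonymous edit combination removes all sites without "
            "creating new ones (undomesticatable)"
        )
    new_seq = _apply(seq, chosen)
    if translate_cds(new_seq) != translate_cds(seq):
        raise DomesticationError("internal error: non-synonymous edit slipped through")
    out = PartRecord(
        id=cds.id,
        role="cds",
        sequence=new_seq,
        left_fusion_site=cds.left_fusion_site,
        right_fusion_site=cds.right_fusion_site,
        metadata=dict(cds.metadata, domesticated=True),
    )
    return out, list(chosen)


def domesticate_noncoding(part: PartRecord, enzymes, boundary_margin: int = DEFAULT_BOUNDARY_MARGIN):
    """Remove internal sites from a non-CDS part by minimal single-base edits.

    Returns (part, edits, warnings); every edit inside a promoter or
    terminator warns that regulatory function may be altered.
    """
    if part.role == "cds":
        raise DomesticationError("use domesticate_cds for coding sequences")
    seq = part.sequence
    n = len(seq)
    hits = find_internal_sites(part, enzymes)
    if not hits:
        return part, [], []
    rec_len = {e.name: len(e.recognition) for e in enzymes}
    per_site = []
    for h in hits:
        span = range(h.position, h.position + rec_len[h.enzyme_name])
        actions = []
        for p in span:
            if p < boundary_margin or p >= n - boundary_margin:
                continue
            for alt in "ACGT":
                if alt == seq[p]:
                    continue
                e = DomesticationEdit(position=p, ref_base=seq[p], alt_base=alt)
                actions.append(((e,), 0.0))
        if not actions:
            raise DomesticationError(
                f"site {h.enzyme_name}@{h.position} in {part.id!r} lies entirely within "
                f"the {boundary_margin}-nt boundary margin (unremovable)"
            )
        per_site.append(actions)
    chosen = _choose_minimal(seq, per_site, enzymes, scorer=lambda combo: 0.0)
    if chosen is None:
        raise DomesticationError(
            f"{part.id!r}: every candidate edit creates a new site (unremovable)"
        )
    new_seq = _apply(seq, chosen)
    out = PartRecord(
        id=part.id,
        role=part.role,
        sequence=new_seq,
        left_fusion_site=part.left_fusion_site,
        right_fusion_site=part.right_fusion_site,
        metadata=dict(part.metadata, domesticated=True),
    )
    warnings = []
    if part.role in ("promoter", "terminator"):
        warnings = [
            f"edit {e.ref_base}{e.position}{e.alt_base} in a {part.role} may alter "
            "regulatory function"
            for e in chosen
        ]
    return out, list(chosen), warnings
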