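"""Repeat detection and loop-out recombination risk assessment.

Repeated homologous stretches inside a multigene construct recombine after
genome integration and excise the intervening DNA ("loop-out"), which is why
every transcription unit should use a distinct promoter and terminator. This
module finds maximal repeated substrings of a construct — direct (same
strand) and inverted (opposite strand) — and, for repeats caused by reusing
a characterized part, suggests registry substitutes of the same regulation
class with the closest strength.

Repeat semantics: a maximal match pair is a pair of equal-length substrings,
equal directly or by reverse complement, that cannot be extended by one base
on either side while remaining equal. All pairs of length >= ``min_len`` are
grouped by their word into :class:`RepeatHit` records. The default threshold
(25 nt) is a conservative package choice relative to known yeast
recombination minima; the source system reports no explicit length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import PartRecord, reverse_complement

DEFAULT_MIN_LEN = 25


@dataclass
class RepeatHit:
    word: str
    word_length: int
    occurrences: list  # (part_id, offset, strand)
    orientation_class: str  # direct | inverted


@dataclass
class RiskReport:
    construct_id: str
    hits: list
    verdict: str  # clear | at_risk
    suggested_substitutions: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Maximal match-pair extraction (seed and extend)
# ---------------------------------------------------------------------------


def _kmer_index(s: str, k: int):
    idx = {}
    for i in range(len(s) - k + 1):
        idx.setdefault(s[i : i + k], []).append(i)
    return idx


def _direct_pairs(s: str, min_len: int):
    """Maximal (i, j, length) with i<j and s[i:i+L] == s[j:j+L]."""
    n = len(s)
    idx = _kmer_index(s, min_len)
    done = set()  # (diagonal, start) already covered
    pairs = set()
    for positions in idx.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                d = j - i
                if (d, i) in done:
                    continue
                lo_i, lo_j = i, j
                while lo_i > 0 and s[lo_i - 1] == s[lo_j - 1]:
                    lo_i -= 1
                    lo_j -= 1
                hi_i, hi_j = i + min_len, j + min_len
                while hi_j < n and s[hi_i] == s[hi_j]:
                    hi_i += 1
                    hi_j += 1
                for st in range(lo_i, hi_i - min_len + 1):
                    done.add((d, st))
                pairs.add((lo_i, lo_j, hi_i - lo_i))
    return pairs


def maximal_direct_pairs(s: str, min_len: int):
    """Public wrapper for maximal same-strand match pairs (i, j, length)."""
    return _direct_pairs(s, min_len)


def maximal_inverted_pairs(s: str, min_len: int):
    """Public wrapper for maximal opposite-strand match pairs (i, j, length)."""
    return _inverted_pairs(s, min_len)


def _inverted_pairs(s: str, min_len: int):
    """Maximal (i, j, length) with s[i:i+L] == revcomp(s[j:j+L]), span i != span j."""
    n = len(s)
    t = reverse_complement(s)
    idx_t = _kmer_index(t, min_len)
    done = set()
    pairs = set()
    for i in range(n - min_len + 1):
        seed = s[i : i + min_len]
        for p in idx_t.get(seed, ()):
            d = p - i
            if (d, i) in done:
                continue
            lo_i, lo_p = i, p
            while lo_i > 0 and lo_p > 0 and s[lo_i - 1] == t[lo_p - 1]:
                lo_i -= 1
                lo_p -= 1
            hi_i, hi_p = i + min_len, p + min_len
            while hi_i < n and hi_p < n and s[hi_i] == t[hi_p]:
                hi_i += 1
                hi_p += 1
            for st in range(lo_i, hi_i - min_len + 1):
                done.add((d, st))
            length = hi_i - lo_i
            j = n - (lo_p + length)  # map revcomp coords back to s
            a, b = min(lo_i, j), max(lo_i, j)
            if (a, a + length) == (b, b + length):
                continue  # a palindromic span matching itself is not a repeat
            pairs.add((a, b, length))
    return pairs


def _group_hits(pairs, s, strandmap, orientation):
    """Group maximal pairs into per-word RepeatHits."""
    by_word = {}
    for i, j, length in pairs:
        if orientation == "direct":
            word = s[i : i + length]
            occs = {(i, "+"), (j, "+")}
        else:
            w1 = s[i : i + length]
            word = min(w1, reverse_complement(w1))
            occs = {(i, "+" if word == w1 else "-"), (j, "-" if word == w1 else "+")}
        key = (word, length)
        by_word.setdefault(key, set()).update(occs)
    hits = []
    for (word, length), occs in by_word.items():
        occurrences = sorted((strandmap(pos), strand) for pos, strand in occs)
        hits.append(
            RepeatHit(
                word=word,
                word_length=length,
                occurrences=[(pid, off, strand) for (pid, off), strand in occurrences],
                orientation_class=orientation,
            )
        )
    return hits


def find_direct_repeats(parts, min_len: int = DEFAULT_MIN_LEN):
    """All maximal repeats of length >= ``min_len`` in a concatenated construct.

    Returns direct (same-strand) and inverted (opposite-strand) hits as
    separate records, sorted by descending word length. Occurrence positions
    are reported as (part_id, offset-within-part, strand) of the repeat
    start; a long repeat may extend beyond its starting part.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 nt is not a meaningful homology threshold")
    seqs, bounds, ids = [], [], []
    pos = 0
    for part in parts:
        seq = part.sequence if isinstance(part, PartRecord) else part[1]
        pid = part.id if isinstance(part, PartRecord) else part[0]
        seqs.append(seq)
        bounds.append(pos)
        ids.append(pid)
        pos += len(seq)
    s = "".join(seqs)

    def locate(p):
        k = max(i for i, b in enumerate(bounds) if b <= p)
        return ids[k], p - bounds[k]

    hits = _group_hits(_direct_pairs(s, min_len), s, locate, "direct")
    hits += _group_hits(_inverted_pairs(s, min_len), s, locate, "inverted")
    hits.sort(key=lambda h: (-h.word_length, h.orientation_class, h.word))
    return hits


# ---------------------------------------------------------------------------
# Risk assessment
# ---------------------------------------------------------------------------


def _construct_parts(construct):
    """Flatten a plan/product/part-list into an ordered PartRecord-ish list."""
    from .gga_engine import AssemblyPlan, AssemblyProduct  # local: avoid cycle

    if isinstance(construct, AssemblyPlan):
        parts = []
        for ins in construct.inserts:
            if isinstance(ins, (tuple, list)):
                parts.extend(ins)
            elif isinstance(ins, PartRecord):
                parts.append(ins)
            else:  # a BB2 product plasmid: treat the whole unit as one block
                parts.append((ins.id, ins.sequence))
        return parts, getattr(construct.recipient, "id", "construct")
    if isinstance(construct, AssemblyProduct):
        return [(construct.plasmid.id, construct.plasmid.sequence)], construct.plasmid.id
    return list(construct), "construct"


def _registry_name(part):
    if isinstance(part, PartRecord):
        return part.metadata.get("registry_name", part.id)
    return part[0]


def assess_loopout_risk(
    construct,
    min_len: int = DEFAULT_MIN_LEN,
    registry=None,
    condition: str = "D",
    strict: bool = False,
) -> RiskReport:
    """Scan a construct for repeats and suggest substitutions for reused parts.

    The verdict is ``at_risk`` iff direct repeats are present (inverted
    repeats are reported but only escalate under ``strict``). For each
    promoter/terminator reused across units, registry alternatives of the
    same regulation class are suggested, ordered by |strength difference| in
    ``condition``.
    """
    parts, construct_id = _construct_parts(construct)
    hits = find_direct_repeats(parts, min_len=min_len)
    triggering = [
        h for h in hits if h.orientation_class == "direct" or (strict and h.orientation_class == "inverted")
    ]
    verdict = "at_risk" if triggering else "clear"
    suggestions = []
    if registry is not None and triggering:
        names = [_registry_name(p) for p in parts]
        seen = {}
        for idx, nm in enumerate(names):
            seen.setdefault(nm, []).append(idx)
        for nm, idxs in seen.items():
            if len(idxs) < 2 or nm not in registry:
                continue
            entry = registry.get(nm)
            if entry.role not in ("promoter", "terminator"):
                continue
            alts = _ranked_alternatives(registry, entry, condition)
            for idx in idxs[1:]:
                suggestions.append((idx, alts))
    return RiskReport(
        construct_id=construct_id,
        hits=hits,
        verdict=verdict,
        suggested_substitutions=suggestions,
    )


def _ranked_alternatives(registry, entry, condition: str):
    """Same-role, same-regulation-class parts nearest in strength (name tie-break)."""
    cond = condition
    if entry.role == "terminator" and condition == "M":
        cond = "D"  # terminators were not screened on methanol
    ref = entry.strength(cond)
    cands = []
    for e in registry.by_role(entry.role):
        if e.name == entry.name:
            continue
        if entry.role == "promoter" and e.regulation != entry.regulation:
            continue
        s = e.strength(cond)
        if s is None or ref is None:
            continue
        cands.append((abs(s - ref), e.name))
    cands.sort()
    return [nm for _d, nm in cands]
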