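"""Characterized parts registry: strengths, queries, part selection, timelines.

The registry ships as a TSV transcription of the toolbox's characterization
table: 20 promoters and 10 terminators with relative eGFP strengths (promoter
reference = the glyceraldehyde-3-phosphate dehydrogenase promoter P_GAP = 100
in each condition; terminator reference = ScCYC1tt = 100), plus 4 genome
integration loci, one episomal locus and 4 resistance marker cassettes.
Screening conditions: G = 2% glycerol, X = glucose feed bead (limited
glucose), D = 2% glucose, M = methanol. Blank cells mean "not tested".

Regulatable promoters additionally carry explicit repressed/induced strengths
from their paired repressed/induced screening; these are stored as their own
columns rather than inferred from the condition columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .exceptions import RegistryError
from .seqcore import _data_path

CONDITIONS = {
    "G": "2% glycerol (batch)",
    "X": "glucose feed bead, limited glucose (fed batch)",
    "D": "2% glucose (batch)",
    "M": "methanol (fed batch)",
}

REGULATIONS = (
    "constitutive",
    "methanol_induced",
    "thiamine_repressed",
    "glycerol_induced",
    "not_applicable",
)

ROLES = ("promoter", "terminator", "integration_locus", "resistance_marker", "episomal_locus")


@dataclass(frozen=True)
class Condition:
    code: str
    description: str

    def __post_init__(self):
        if self.code not in CONDITIONS:
            raise RegistryError(f"unknown condition code {self.code!r}")


@dataclass
class RegistryEntry:
    name: str
    role: str
    gene: str = ""
    orf_id: str = ""
    regulation: str = "not_applicable"
    strengths: dict = field(default_factory=dict)  # condition code -> rel eGFP %
    repressed_strength: float | None = None
    induced_strength: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise RegistryError(f"{self.name}: unknown role {self.role!r}")
        if self.regulation not in REGULATIONS:
            raise RegistryError(f"{self.name}: unknown regulation {self.regulation!r}")
        for cond, v in self.strengths.items():
            if cond not in CONDITIONS:
                raise RegistryError(f"{self.name}: unknown condition {cond!r}")
            if v < 0:
                raise RegistryError(f"{self.name}: negative strength in {cond}")

    @property
    def regulatable(self) -> bool:
        return self.role == "promoter" and self.regulation not in ("constitutive", "not_applicable")

    def strength(self, condition: str) -> float | None:
        return self.strengths.get(condition)


class Registry:
    def __init__(self, entries):
        self.entries = {}
        for e in entries:
            if e.name in self.entries:
                raise RegistryError(f"duplicate part name {e.name!r}")
            self.entries[e.name] = e
        refs = [
            e
            for e in self.by_role("promoter")
            if e.strengths and all(v == 100 for v in e.strengths.values())
        ]
        if len(refs) != 1:
            raise RegistryError(
                f"expected exactly one reference promoter at 100 in every tested "
                f"condition, found {[e.name for e in refs]}"
            )
        self.reference_promoter = refs[0].name

    def __len__(self):
        return len(self.entries)

    def __contains__(self, name):
        return name in self.entries

    def get(self, name) -> RegistryEntry:
        try:
            return self.entries[name]
        except KeyError:
            raise RegistryError(f"unknown part {name!r}") from None

    def by_role(self, role):
        return [e for e in self.entries.values() if e.role == role]


_NUMERIC = ("strength_G", "strength_X", "strength_D", "strength_M", "repressed_strength", "induced_strength")


def load_registry(path=None) -> Registry:
    """Load and validate the parts registry TSV (shipped transcription by default)."""
    src = Path(path) if path else _data_path("registry.tsv")
    df = pd.read_csv(src, sep="\t", dtype=str).fillna("")
    required = {"name", "role", "gene", "orf_id", "regulation", *_NUMERIC}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"registry missing columns: {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        strengths = {}
        for cond in CONDITIONS:
            raw = row[f"strength_{cond}"].strip()
            if raw:
                try:
                    strengths[cond] = float(raw)
                except ValueError:
                    raise RegistryError(
                        f"row {i + 2} ({row['name']}), column strength_{cond}: "
                        f"not a number: {raw!r}"
                    ) from None
        def _opt(col):
            raw = row[col].strip()
            return float(raw) if raw else None
        try:
            entries.append(
                RegistryEntry(
                    name=row["name"].strip(),
                    role=row["role"].strip(),
                    gene=row["gene"].strip(),
                    orf_id=row["orf_id"].strip(),
                    regulation=row["regulation"].strip() or "not_applicable",
                    strengths=strengths,
                    repressed_strength=_opt("repressed_strength"),
                    induced_strength=_opt("induced_strength"),
                )
            )
        except RegistryError as exc:
            raise RegistryError(f"row {i + 2}: {exc}") from None
    return Registry(entries)


def save_registry(registry: Registry, path):
    rows = []
    for e in registry.entries.values():
        row = {
            "name": e.name,
            "role": e.role,
            "gene": e.gene,
            "orf_id": e.orf_id,
            "regulation": e.regulation,
        }
        for cond in CONDITIONS:
            v = e.strengths.get(cond)
            row[f"strength_{cond}"] = "" if v is None else _fmt(v)
        row["repressed_strength"] = "" if e.repressed_strength is None else _fmt(e.repressed_strength)
        row["induced_strength"] = "" if e.induced_strength is None else _fmt(e.induced_strength)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def registry_counts(registry: Registry) -> dict:
    counts = {}
    for e in registry.entries.values():
        counts[e.role] = counts.get(e.role, 0) + 1
    return counts


def query_promoters(registry: Registry, regulation=None, condition=None, strength_range=None):
    """Promoters filtered by regulation/condition/strength, strongest first.

    With a condition, promoters lacking a value there are excluded and the
    sort is by descending strength in that condition (name tie-break).
    ``regulation`` accepts a specific class or the umbrella ``regulatable``.
    """
    if condition is not None and condition not in CONDITIONS:
        raise RegistryError(f"unknown condition code {condition!r}")
    out = []
    for e in registry.by_role("promoter"):
        if regulation == "regulatable":
            if not e.regulatable:
                continue
        elif regulation is not None and e.regulation != regulation:
            continue
        if condition is not None:
            s = e.strength(condition)
            if s is None:
                continue
            if strength_range is not None and not (strength_range[0] <= s <= strength_range[1]):
                continue
        out.append(e)
    if condition is not None:
        out.sort(key=lambda e: (-e.strength(condition), e.name))
    else:
        out.sort(key=lambda e: e.name)
    return out


def strength_extremes(registry: Registry, regulation_class: str, phase: str = "active"):
    """(min, max) relative strength for a promoter class.

    ``constitutive``/``active`` pools every tested condition of every
    constitutive promoter; ``regulatable`` with phase ``repressed`` or
    ``induced`` reads the explicit paired-screening columns.
    """
    if regulation_class == "constitutive":
        values = [
            v for e in registry.by_role("promoter")
            if e.regulation == "constitutive"
            for v in e.strengths.values()
        ]
    elif regulation_class == "regulatable":
        if phase == "repressed":
            values = [e.repressed_strength for e in registry.by_role("promoter") if e.regulatable]
        elif phase == "induced":
            values = [e.induced_strength for e in registry.by_role("promoter") if e.regulatable]
        else:
            values = [
                v for e in registry.by_role("promoter") if e.regulatable
                for v in e.strengths.values()
            ]
        values = [v for v in values if v is not None]
    else:
        raise RegistryError(f"unknown regulation class {regulation_class!r}")
    if not values:
        raise RegistryError(f"no strength values for class {regulation_class!r}")
    return min(values), max(values)


# ---------------------------------------------------------------------------
# Part selection for multi-unit designs
# ---------------------------------------------------------------------------


def _terminator_order(registry: Registry, condition: str):
    """Terminators by closeness to the reference (100), then name.

    Terminators were not screened on methanol; condition M falls back to D.
    """
    cond = condition if condition != "M" else "D"
    terms = registry.by_role("terminator")
    return sorted(
        terms,
        key=lambda e: (abs((e.strength(cond) if e.strength(cond) is not None else 100) - 100), e.name),
    )


def select_parts(registry: Registry, n_units: int, targets, forbid_reuse: bool = True):
    """Assign a (promoter, terminator) pair to each unit.

    ``targets`` is one (condition, desired %) pair per unit. Promoters are
    chosen to minimise the summed |assigned − desired| in each unit's own
    condition — exhaustively for up to 4 units, greedy with 2-swap refinement
    above — with pairwise-distinct promoters and terminators when
    ``forbid_reuse``. Ties break deterministically by part name.
    """
    if n_units < 1 or len(targets) != n_units:
        raise RegistryError("need one (condition, strength) target per unit")
    if n_units > 8:
        raise RegistryError("at most 8 units are addressable on one plasmid")
    cands = []
    for cond, _want in targets:
        pool = query_promoters(registry, condition=cond)
        if not pool:
            raise RegistryError(f"no promoter characterized in condition {cond!r}")
        cands.append(pool)
    if forbid_reuse:
        distinct = {e.name for pool in cands for e in pool}
        if n_units > len(distinct):
            raise RegistryError(
                f"{n_units} units demanded distinct promoters but only "
                f"{len(distinct)} usable promoters exist (infeasible)"
            )
        if n_units > len(registry.by_role("terminator")):
            raise RegistryError(
                f"{n_units} units demanded distinct terminators but only "
                f"{len(registry.by_role('terminator'))} exist (infeasible)"
            )

    def cost(names):
        return sum(
            abs(registry.get(nm).strength(targets[i][0]) - targets[i][1])
            for i, nm in enumerate(names)
        )

    if n_units <= 4:
        best = None
        pools = [[e.name for e in pool] for pool in cands]
        for combo in itertools.product(*pools):
            if forbid_reuse and len(set(combo)) < n_units:
                continue
            key = (cost(combo), combo)
            if best is None or key < best:
                best = key
        chosen = list(best[1])
    else:
        chosen = []
        for i, pool in enumerate(cands):
            opts = sorted(
                (abs(e.strength(targets[i][0]) - targets[i][1]), e.name) for e in pool
            )
            for _c, nm in opts:
                if not forbid_reuse or nm not in chosen:
                    chosen.append(nm)
                    break
            else:
                raise RegistryError("greedy assignment infeasible")
        improved = True
        while improved:
            improved = False
            for i, j in itertools.combinations(range(n_units), 2):
                swapped = chosen.copy()
                swapped[i], swapped[j] = swapped[j], swapped[i]
                valid = all(
                    swapped[k] in {e.name for e in cands[k]} for k in (i, j)
                )
                if valid and (cost(swapped), tuple(swapped)) < (cost(chosen), tuple(chosen)):
                    chosen = swapped
                    improved = True

    term_order = [
        [t.name for t in _terminator_order(registry, cond)] for cond, _ in targets
    ]
    terms = []
    for i in range(n_units):
        for nm in term_order[i]:
            if not forbid_reuse or nm not in terms:
                terms.append(nm)
                break
        else:
            raise RegistryError("not enough distinct terminators")
    return list(zip(chosen, terms))


# ---------------------------------------------------------------------------
# Screening summaries and strain-engineering timelines
# ---------------------------------------------------------------------------


def screening_fraction(positives: int, total: int) -> Fraction:
    """Exact positive-clone fraction as a percentage."""
    if total <= 0:
        raise RegistryError("total clone count must be positive")
    if not 0 <= positives <= total:
        raise RegistryError("positives must lie in [0, total]")
    return Fraction(100 * positives, total)


def summarize_screening(positives: int, total: int) -> int:
    """Positive-clone percentage rounded to the nearest integer for display
    (round half up); use :func:`screening_fraction` for the exact value."""
    return int(screening_fraction(positives, total) + Fraction(1, 2))


#: step durations (days): competent-cell prep, transformation incl. second
#: streak-out, clone screening; marker recycling adds one extra
#: competent+transform round.
DAYS_COMPETENT = 2
DAYS_TRANSFORM = 4
DAYS_SCREEN = 5
DAYS_RECYCLING = 8


def strategy_days(n_genes: int, method: str, marker_recyclings: int = 0) -> int:
    """Calendar days to integrate ``n_genes`` expression units.

    Conventional cloning needs one transformation+screen per gene plus fresh
    competent cells between rounds (the first round's cells pre-exist);
    multigene one-pot assembly needs a single transformation+screen
    regardless of gene count, and marker recycling does not apply.
    """
    if n_genes < 1:
        raise RegistryError("n_genes must be >= 1")
    if method == "conventional":
        return (
            n_genes * (DAYS_TRANSFORM + DAYS_SCREEN)
            + (n_genes - 1) * DAYS_COMPETENT
            + DAYS_RECYCLING * marker_recyclings
        )
    if method == "goldengate":
        return DAYS_TRANSFORM + DAYS_SCREEN
    raise RegistryError(f"unknown method {method!r}")
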