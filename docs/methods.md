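# Methods

## Scope and model

moclokit models one-pot Golden Gate assembly as pure sequence arithmetic.
A type IIs enzyme is three numbers and a word: recognition sequence, spacer
length, overhang length. Shipped defaults follow standard (REBASE) geometry —
BsaI `GGTCTC(1/5)`, BpiI `GAAGAC(2/6)`, both leaving 4-nt 5′ overhangs —
because the source system names the enzymes and the overhang length but not
the cut geometry; the definitions live in `data/enzymes.yaml` and are
swappable.

Coordinates are 0-based, half-open, on the top strand throughout; circular
indices are reduced modulo the length. For a recognition match at position
*p* the cut window is `[p + |rec| + spacer, … + 4)` on the plus strand and
`[p − spacer − 4, p − spacer)` on the minus strand; in both cases the top
strand is severed at the window's left edge, so every overhang is the
top-strand word of its window. Digesting a circle with *k* sites yields
exactly *k* fragments; each fragment owns its left overhang plus core, so
summed owned strands conserve the source bases exactly once.

**Ligation.** Two ends join iff their window words are identical; flipping a
fragment reverse-complements and swaps its words. Product enumeration is a
depth-first search over fragment subsets and orientations; circles are
deduplicated under rotation and reflection by the lexicographically minimal
rotation (Booth's algorithm) of the top strand and its reverse complement.
Circles retaining a recognition site of the reaction enzyme — including a
site formed across a fresh junction — are re-cut in the one-pot cycle and
excluded from final products. Compatibility is exact-match only: there is no
ligation-fidelity scoring of near-cognate overhangs, no methylation
sensitivity, no partial digestion.

**Grammar.** Fs1–Fs4 order promoter/CDS/terminator in a transcription unit
(level BB2, BpiI); FsA–FsI order units on a multigene plasmid (level BB3,
BsaI); *n* + 1 boundary words host *n* units, hence eight units with nine
sites. Fixed words from the published system: Fs2 `CATG` (carries the ATG
start codon — CDS parts are stored without it, codon-aligned), Fs3 `GCTT`,
FsB `CCGG`. All other words are not printed in the source and are shipped as
clearly marked non-canonical defaults chosen so the whole set has no
duplicate, no reverse-complement pair, and no palindrome beyond CATG/CCGG.
`validate_fusion_site_set` reports exactly these classes: duplicates and
reverse-complement pairs as errors (they destroy directionality),
palindromes as warnings (they permit orientation-flipped ligation; the
simulator counts the resulting misassemblies in `alternatives_count`).
The single-unit direct route (parts straight into a BB3 recipient carrying
an Fs1–Fs4 linker) is a BpiI reaction even though its product is a BB3; the
plan is labelled BB3 with enzyme BpiI for that route only.

The one-pot thermocycling program is emitted as plan metadata (8 cycles for
one insert, scaling linearly to 50 at eight or more); it is documentation,
not simulation.

## Synthetic fixtures

The published module and backbone sequences live in supplementary material
and a deposited plasmid kit and are not redistributed. The fixture layer
reproduces what matters for the chemistry:

* payloads are random sequences (role-typical lengths: promoters ~500 nt,
  CDSs ~900 nt, terminators ~250 nt) scrubbed of both enzymes' motifs on
  both strands, *including across the fusion-site junctions*; CDS payloads
  are codon-aligned, stop-free and TAA-terminated;
* donor plasmids place recognition sites cutting outward so the released
  payload carries the part's fusion sites as overhangs while both
  recognition sequences stay on the re-cuttable backbone;
* recipients carry an excisable linker (both recognition sequences inside
  it, pointing outward) plus, for BB2 recipients, outer BsaI sites that
  release the finished unit with its positional FsA…FsI words — so a BB2
  product is chemically a valid BB3 insert, and the hierarchy is exercised
  end to end rather than assumed.

Randomness comes from a 64-bit linear congruential generator (MMIX
multiplier, top-33-bit output, rejection sampling) implemented in the
package, so fixtures are bit-identical across platforms and library
versions. Sub-seeds of a part triple are spread multiplicatively (base
seed × 7919 + role offset) so nearby seeds never share an RNG stream —
shared prefixes would read as repeats.

What fixtures do **not** emulate: real promoter/terminator sequence
composition (GC skew, TATA boxes, poly-A signals), real coding sequences,
origin/marker function, or any biology of transformation. A green assembly
test therefore establishes junction logic and site bookkeeping, not that a
particular real construct will clone.

## Domestication

Internal BsaI/BpiI sites are destroyed by point mutations. For CDS parts
every edit must be synonymous; candidate actions are synonymous codon
replacements confined to codons overlapping a recognition span (single-base
variants first, full codon swaps as the escalation path when no single base
works). The chosen set is minimal in total base changes; among minimal sets
the summed within-family usage of the resulting codons is maximal, using the
shipped *P. pastoris* codon-usage table (`data/codon_usage_pichia.tsv`,
standard published counts per thousand normalised to within-amino-acid
fractions at load; the table is data, not code, and swappable). Ties break
by 5′-most position, then alphabetical alternate base. No edit may create a
new site for any named enzyme (checked globally, both strands), and edits
are forbidden within 10 nt of the part boundaries (configurable) to protect
fusion-site context. Non-coding parts accept any base change under the same
no-new-site and margin rules; every edit in a promoter or terminator carries
a warning because no functional-neutrality rule exists for regulatory DNA.
Parts whose sites survive every allowed action raise an
"undomesticatable" error rather than returning a partial result.

## Repeat detection and loop-out risk

A maximal match pair is two equal-length substrings, equal directly or by
reverse complement, that cannot be extended one base on either side.
Production uses seeding on `min_len`-mers with two-sided extension and
per-diagonal deduplication; the test oracle is an unrelated numpy
shift-and-compare enumeration, and the two must agree exactly. The default
threshold of 25 nt is a package decision — conservative relative to known
yeast recombination minima — because the source reports only "repetitive"
versus "repeat-free", not a length. Direct repeats set the verdict to
`at_risk`; inverted repeats are reported but escalate only in strict mode,
since the observed loop-out evidence concerns direct promoter/terminator
reuse. For a reused registry part the checker suggests same-role,
same-regulation-class alternatives ordered by |Δ strength| in the declared
condition.

## Registry

`data/registry.tsv` transcribes the characterization table of the source
toolbox: 20 promoters and 10 terminators with relative eGFP strengths
(reference promoter = 100 in each condition; reference terminator = 100),
4 genome integration loci, one episomal locus, 4 resistance markers.
Conditions: G = 2% glycerol, X = limited glucose (feed beads), D = 2%
glucose, M = methanol. Blank cells mean "not tested" — several promoters
were validated only in D. Regulatable promoters carry explicit
repressed/induced strengths from their paired screening (stored as their own
columns rather than inferred from condition columns). Terminator rows carry
three values, mapped here to G/X/D with methanol blank, consistent with
terminators being screened in non-methanol conditions; queries in M fall
back to D for terminators. Display rounding is to integer percent;
comparisons use stored values.

`select_parts` minimises the summed |assigned − desired| promoter strength
in each unit's own condition — exhaustively for up to four units, greedy
with 2-swap refinement above — with pairwise-distinct promoters and
terminators when reuse is forbidden. Terminator strengths cluster near the
reference, so terminators do not enter the objective; they are assigned by
closeness to 100 with name tie-breaks. Both choices are deterministic.

Timeline arithmetic: competent-cell preparation 2 days, transformation with
second streak-out 4 days, clone screening 5 days, marker recycling +8 days.
Conventional integration of *n* genes = *n*·9 + (*n*−1)·2 (+8 per
recycling); the first round's competent cells are assumed pre-existing —
this reproduces the printed 31-day figure for three genes and is documented
as a modelling decision. One-pot multigene assembly is a single 9-day round
regardless of *n*.

## Start-codon context

The promoter-CDS fusion site fixes the '-1' position of every construct.
`minus_one_check` classifies it from the site's first base (A/T/C ok; G
warns, annotated with the observed ~40% reporter drop); the effect is
advisory only and never multiplies registry strengths, because it was
measured on a single promoter. `build_pfm` counts user-supplied −8…−1
contexts into a column-stochastic position frequency matrix with optional
pseudocount; genome-wide context retrieval is out of scope.

## Numerical and degenerate-input choices

* IUPAC ambiguity codes are rejected at ingest — junction arithmetic needs
  concrete bases.
* Digesting a circle with zero sites returns it uncut, flagged, rather than
  raising; intersecting cut windows raise an unresolvable-digestion error.
* Ligation enumeration caps at 20 000 distinct circles and fails loudly
  beyond that (promiscuous pools, not design inputs).
* Screening percentages round half-up for display; the exact fraction is
  available separately.
* PFM columns sum to 1 within 1e-9; codon-usage families are normalised to
  sum to 1 at load.

## Known limitations

* Fixture parts are random DNA; conclusions about real regulatory sequence
  require the user's own part sequences.
* No recombination-frequency model: the checker returns a verdict, not a
  probability, and the published integration-efficiency percentages are
  experimental observations this package does not simulate.
* Overhang compatibility is exact-match; near-cognate mispairing rates are
  not modelled.
* BB1 entry cloning (PCR with site-adding primers) is represented only by
  parts already carrying their fusion sites.
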