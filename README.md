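# moclokit

In-silico Golden Gate modular cloning for *Pichia pastoris* (syn.
*Komagataella* spp.) strain engineering: simulate type IIs
digestion/ligation, enforce the hierarchical fusion-site grammar that turns
basic parts into transcription units and transcription units into multigene
plasmids, domesticate parts by codon-aware point mutation, flag
loop-out-prone repeats, and design against a characterized
promoter/terminator registry.

## Who this is for

Yeast cell engineers planning multigene overexpression constructs. Cloning a
pathway gene-by-gene costs one transformation round per gene (31+ days for
three genes); a one-pot multigene assembly costs a single round (9 days) —
but only if every junction is designed correctly, no internal restriction
site survives, and no promoter or terminator is reused (repeated homologous
sequence triggers "loop-out" recombination after genome integration). This
package checks all of that before any DNA is ordered.

## The model

Golden Gate assembly uses two type IIs enzymes, BsaI (GGTCTC, cutting 1 nt
downstream) and BpiI (GAAGAC, 2 nt downstream), which cut *outside* their
recognition sequence and leave freely designable 4-nt 5′ overhangs, called
fusion sites (Fs). Every overhang is represented by the top-strand word of
its cut window; two ends ligate iff their words match, and a flipped
fragment contributes reverse-complemented words — so palindromic words
(CATG, CCGG) self-pair in both orientations, and the simulator enumerates
such misassemblies rather than hiding them. A ligation circle that retains
a recognition site of the reaction enzyme is re-cut in the one-pot cycle
and never counts as a final product.

The grammar has three backbone (BB) levels:

* **BB1** — entry clones for single parts (promoter, CDS, terminator);
* **BB2** — one transcription unit, assembled with BpiI via fusion sites
  Fs1–Fs2 (promoter), Fs2–Fs3 (CDS), Fs3–Fs4 (terminator). Fs2 = `CATG`
  contributes the ATG start codon, so CDS parts are stored without it;
  Fs3 = `GCTT`;
* **BB3** — up to eight transcription units, assembled with BsaI via the
  positional sites FsA…FsI (FsB = `CCGG` joins unit 1 to unit 2).

Module and backbone sequences of the published kit are not redistributed;
a deterministic fixture generator builds synthetic parts and plasmids with
the correct junction geometry instead.

## Worked example

```python
from moclokit import *
from moclokit import fixtures

fs = load_fusion_sites()
units = []
for pos in (1, 2):                       # two transcription units
    p, c, t = fixtures.make_tu_parts(fs, seed=100 + pos)
    rec = fixtures.build_bb2_recipient(fs, position=pos, seed=pos)
    product = simulate_gga(plan_bb2(p, c, t, rec, fs, position=pos))
    print(f"BB2 unit {pos}: {len(product.plasmid)} bp,",
          f"junctions {[j[0] for j in product.junctions]},",
          f"alternatives {product.alternatives_count}")
    units.append(product.plasmid)

rec3 = fixtures.build_bb3_recipient(fs, n_units=2, seed=9)
multi = simulate_gga(plan_bb3(units, rec3, fs))
print(f"BB3 product: {len(multi.plasmid)} bp,",
      f"junctions {[j[0] for j in multi.junctions]},",
      f"alternatives {multi.alternatives_count}")
```

prints

```
BB2 unit 1: 1908 bp, junctions ['GGAG', 'CATG', 'GCTT', 'CGCT'], alternatives 0
BB2 unit 2: 1908 bp, junctions ['GGAG', 'CATG', 'GCTT', 'CGCT'], alternatives 0
BB3 product: 3564 bp, junctions ['TGCC', 'CCGG', 'ACTG'], alternatives 0
```

Each BB2 product closes through Fs1–Fs4 exactly once (`CATG` between
promoter and CDS, `GCTT` between CDS and terminator); the BB3 product
closes through FsA–FsC with `CCGG` joining the two units;
`alternatives 0` means no other circle — misassembly included — can form
from the pool, and no reaction-enzyme site survives in any product.

Design queries against the shipped registry:

```python
reg = load_registry()
select_parts(reg, 2, [("D", 100), ("D", 25)])
# [('P_GAP', 'ScCYC1tt'), ('P_GPM1', 'RPL2Att')]
strategy_days(3, "conventional"), strategy_days(3, "goldengate")
# (31, 9)
```

`select_parts` picks pairwise-distinct promoters nearest the desired
relative strengths in the stated condition (here glucose excess, "D") and
distinct terminators, so the resulting construct stays repeat-free.

## Command line

```bash
moclokit assemble --level bb2 --inserts p.gb c.gb t.gb --recipient r.gb \
    --out product.gb --report report.json
moclokit domesticate --in cds.fa --role cds --out cds_dom.fa --edits edits.json
moclokit check-repeats --construct product.gb --min-len 25 --report risk.json
moclokit select-parts --units 3 --condition D --strengths 100,50,20 --registry registry.tsv
moclokit plan --genes 3 --method conventional
moclokit kozak --contexts contexts.fa --pfm pfm.tsv
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch at the given seed:
builds synthetic parts, runs the BB2→BB3 assembly chain and verifies
junction words and the absence of surviving recognition sites, domesticates
a CDS with planted internal sites, screens a duplicated-unit construct for
loop-out risk, and exercises the registry queries and timeline arithmetic,
writing its results as JSON to `--out`.

## Layout

| module | contents |
| --- | --- |
| `moclokit.seqcore` | records, FASTA/GenBank I/O, site scanning, fixture generation |
| `moclokit.gga_engine` | digestion/ligation simulation, fusion-site grammar, plans |
| `moclokit.domestication` | codon-usage-aware internal-site removal |
| `moclokit.loopout_checker` | maximal-repeat detection, risk verdicts, substitutions |
| `moclokit.parts_registry` | characterized parts table, selection, timelines |
| `moclokit.kozak` | start-codon context checks and position frequency matrices |

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
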