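# pepscreen

In silico protease digestion and bioactive-peptide screening.

Food by-products (tomato peel is the motivating case) are protein-rich
waste streams whose enzymatic hydrolysates can contain bioactive peptides
(BAPs): 5–30 residue fragments with predicted anticancer (ACP),
antidiabetic (ADP), antihypertensive (AHP), anti-inflammatory (AIP) or
antimicrobial (AMP) activity. Finding the protease — or ordered protease
pair — whose digest maximizes a given activity class is a combinatorial
search that is expensive at the bench but cheap in silico. `pepscreen` is
a toolkit for exactly that search, aimed at peptidomics and functional-food
researchers who want a reproducible, offline version of the workflow:

1. **Substrate selection** — average replicate expression values
   (triplicate by default), keep only manually annotated proteins, rank by
   mean abundance and take the top *N* (default 50) as substrates.
2. **Rule-based digestion** — each protease is a declarative
   Schechter–Berger position pattern (P4…P1 / P1′…P4′ with exceptions;
   cleavage at the P1–P1′ bond). Digestion is exhaustive, so fragments
   tile the parent exactly. Sequential mode applies enzymes one after
   another, each acting on the previous round's fragments.
3. **Combination screening** — over a library of *n* enzymes there are
   *n·(n−1)^(k−1)* ordered depth-*k* combinations with distinct consecutive
   entries: 1,560 pairs and 60,840 triples for the bundled 40-enzyme
   library. Every combination digests every substrate; 5–30 aa products
   are pooled, deduplicated by sequence, classified by a pluggable
   multi-label predictor, and counted per class (a peptide can increment
   several classes). The best combination per class is reported.
4. **Filter cascade** — candidates must be non-toxic, non-bitter
   (score ≤ 333), plasma-stable (half-life ≥ 800 s) and intestinally
   stable (half-life > 1.0 s); per-class confirmation uses an all-positive
   (or m-of-n) consensus across prediction platforms, and externally
   computed MM-PBSA pose energies are triaged at ≤ −30 kcal/mol.

External ML servers (toxicity, bitterness, half-life, per-class
bioactivity) are represented as predictor adapters over delimited score
tables — plus seeded-random and composition-heuristic baselines — so the
whole pipeline runs offline and deterministically.

## Worked example

Sequential digestion of the toy protein `MKRPADM` with trypsin (cleaves
after K/R, vetoed before P) followed by Asp-N endopeptidase (cleaves
before D):

```python
>>> import pepscreen as ps
>>> lib = ps.bundled_library()
>>> [f.sequence for f in ps.sequential_digest("MKRPADM",
...     ["Trypsin", "Asp-N Endopeptidase"], lib)]
['MK', 'RPA', 'DM']
```

Trypsin cuts after K (the R–P bond is protected), then Asp-N splits
`PADM` before its D. A full screen over a seeded synthetic proteome:

```python
>>> from pepscreen.synthetic import SyntheticConfig, generate_proteome, \
...     generate_expression_table
>>> from pepscreen.substrates import average_replicates, select_top_expressed
>>> cfg = SyntheticConfig(seed=1)
>>> prots = generate_proteome(cfg)
>>> recs = average_replicates(generate_expression_table(cfg, prots))
>>> subs = select_top_expressed(recs, {p.accession: p for p in prots}, 50)
>>> combos = ps.enumerate_combinations(lib, 2)
>>> len(combos)
1560
>>> res = ps.screen(subs, combos, ps.CompositionHeuristicPredictor(), library=lib)
>>> print(ps.format_best_combinations(ps.best_combination_per_class(res)))
ACP: Asp-N Endopeptidase + N-terminal Glu_Pancreatic Elastase (n = 111)
ADP: Chymotrypsin (low specificity)_Trypsin (n = 676)
AHP: Lys-C_Pancreatic Elastase (n = 199)
AIP: Pepsin (pH >= 2)_Trypsin (n = 32)
AMP: Asp-N Endopeptidase + N-terminal Glu_Pancreatic Elastase (n = 250)
```

Each line names the ordered enzyme pair whose digest of the 50 substrates
yields the most unique 5–30 aa peptides called positive for that class by
the (baseline) predictor, with the count in parentheses. The same
pipeline is available from the shell:

```sh
pepscreen simulate --seed 1 --out-dir fix
pepscreen select --expression fix/expression.tsv --fasta fix/proteome.fasta --out-dir sel
pepscreen digest --fasta sel/substrates.fasta --enzymes "Trypsin,Asp-N Endopeptidase" --out-dir dig
pepscreen screen --fasta sel/substrates.fasta --depth 2 --out-dir scr
pepscreen filter --peptides dig/peptides.tsv --safety-table fix/safety.tsv --out-dir flt
```

## Layout

- `src/pepscreen/cleavage.py` — rules, site finding, (sequential) digestion
- `src/pepscreen/substrates.py` — expression averaging, top-N selection
- `src/pepscreen/screening.py` — combination enumeration and the screen
- `src/pepscreen/predictors.py`, `filtering.py` — predictor contract and cascade
- `src/pepscreen/synthetic.py`, `fastaio.py`, `datasets.py`, `cli.py` — I/O,
  fixtures, bundled tables, command line
- `src/pepscreen/data/enzymes.yaml` — the 40-protease rule library
  (user-replaceable; schema documented in the file header)

See `docs/methods.md` for the model, parameter and design notes.
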