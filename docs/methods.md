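# Methods

## Scope and model

`motiftracks` treats a finished MEME 5.x run as its input: it does not run
motif discovery, align sequences or build trees. Its unit of data is the
**motif occurrence** — one motif hit on one training sequence with 1-based
inclusive coordinates, a strand (`+`/`-` for nucleotide runs, `none` for
protein), a site p-value and the site string. Everything downstream (tables,
filters, location maps, logos) is a function of the occurrence set plus the
per-motif models (width, nsites, E-value, Bayes threshold, probability
matrix).

## Coordinate conventions

The two MEME dialects disagree on coordinates: the XML stores 0-based site
offsets, the text report prints 1-based start positions. Internally
everything is 1-based inclusive `[start, end]` with `end − start + 1` equal
to the motif width; the XML parser converts (`start = offset + 1`), the text
parser keeps starts as printed. The fixture writers deliberately emit each
dialect's native convention so round-trip tests exercise the conversion, and
cross-dialect agreement is asserted on sibling files written from one
planted truth.

The XML carries two site lists: per-motif *contributing sites* (with
p-values and flanks) and an optional per-sequence *scanned-sites summary*.
Contributing sites are canonical; the summary is parsed into a separate
field and never merged, so occurrences are never double counted.

## Parsing policy

Only MEME major version 5 is accepted; 4.x files are rejected with the found
version rather than parsed best-effort. Scientific-notation numbers tolerate
the unicode minus some reports print. Background frequencies are
renormalized to sum to 1, since printed values are rounded. The Bayes
threshold is read from the XML motif attributes and, in the text dialect,
from the `log-odds matrix: ... bayes=` header; its filter direction is
"keep motifs with threshold ≤ cutoff" (the more permissive reading; the
comparison direction is a genuine design choice and is documented here
rather than guessed silently elsewhere).

## Occurrence table and filters

The table has one row per occurrence and a deterministic order —
`sequence_name` ascending, then `start`, then `motif_id` (lexicographic
tie-break) — so TSV outputs are byte-stable for golden-file comparisons.
Filters are a conjunction of optional predicates (motif ids, max site
p-value, max motif E-value, max Bayes threshold); absent predicates are
no-ops and row order is preserved, which makes tightening `max_p` provably
monotone in row count. E-value/Bayes filters operate on a table built with
`with_motif_stats=True`, which joins the per-motif fields onto the rows.

## Logos

Logos are always computed from the extracted site strings, not from the text
report's printed probability matrix — so XML inputs (which may lack a usable
matrix) still yield logos. When a printed matrix exists it is only used for
a consistency warning at 0.01 per-cell tolerance. The PPM uses
`p_ik = (count_ik + c)/(n + K·c)` with pseudocount `c = 0` by default, so
logos reflect the sites verbatim; `c = 1/K` is a documented alternative for
small site counts. Information content is
`R_i = log2(K) − H_i − e(n)`, `H_i = −Σ p·log2 p` with `0·log2 0 := 0`, and
`e(n) = (K−1)/(2·ln2·n)`. The correction defaults **off**, matching common
logo-package behavior, and negative corrected values are clipped to 0 rather
than drawn below the axis. Letter colors follow a conventional
chemistry-based palette (nucleotide ACGT; protein polar/basic/acidic/
hydrophobic classes). Letters are stacked tallest-on-top and each glyph
carries a stable `gid`, so SVG exports can be checked structurally.

## Trees and layout

Input is restricted to Newick (the one format the tool's workflow needs);
Nexus and other formats are out of scope. Trees are treated as rooted as
written and children keep file order — leaf order is depth-first in written
order, with ladderization (by clade size) available behind a flag because
figure row order depends on it. Absent branch lengths are stored as 0;
bare-number internal labels (support values) are retained as internal
labels. The rectangular layout puts tip *i* at integer row *i* and each
internal node at the midpoint of its first and last child's row; x is
cumulative branch length, so zero-length branches stack vertically.
Tip labels are matched to sequence names by exact string equality.

## Location maps

Tracks share one x-axis in residues/bases (no per-row normalization), so
shorter sequences visibly end earlier. Colors are a pure function of the
sorted motif-id set over a fixed 12-color categorical palette, cycling with
a warning beyond 12 motifs. Overlapping boxes draw the later-starting one on
top with translucency; minus-strand nucleotide occurrences get a small
directional glyph. When a tree is supplied the tracks are restricted to the
intersection of table sequences and tree tips, with one warning per name
present on only one side and an error on an empty intersection; the tree is
pruned to the kept tips (unary internals suppressed, branch lengths summed)
so both panels share row coordinates. The resolved geometry is exposed as a
JSON-serializable `TrackLayout`, which is what the geometry tests compare —
figures themselves are not required to be byte-identical across
environments, only their element counts and layout.

## Synthetic data

The fixture generator emulates the *output* of a ZOOPS-mode MEME run, not
MEME's statistics. Defaults are a protein run on 20 sequences of 100–400
residues with 10 motifs of widths 4–7 and a per-motif, per-sequence site
probability of 0.6 — the sequence count, motif count and width range mirror
a typical plant transcription-factor family analysis
(`-mod zoops -nmotifs 10 -minw 4 -maxw 7`), and 0.6 gives sequences a
realistic mix of present and absent motifs. Site strings come from a
degenerate-consensus model (consensus letter with probability 0.7, random
letter otherwise) so logos are non-trivial. Site p-values are sampled
log-uniformly over [1e-12, 1e-2] on the grid the text report's `%.2e`
format can print exactly, and per-motif E-values are nsites-scaled values on
the `%.1e` grid — format-realistic, not statistically faithful; likewise the
backgrounds are uniform so printed 5-decimal frequencies sum to exactly 1.
Trees are random-coalescent-like joins over the sequence names, with
optional dropped/added tips to exercise intersection handling.

What passing round-trip tests show is that the parsers invert the writers'
(MEME-conformant) dialect subset exactly; they do not show robustness to
every formatting variant real MEME emits (e.g. wrapped site tables in very
wide runs), and the synthetic p-values/E-values carry no statistical
meaning.

## Numerical and determinism notes

All randomness flows through `numpy.random.default_rng(seed)`; the same seed
reproduces files byte-for-byte. PPM columns must sum to 1 within 1e-9 and
stack heights sum to the column IC within 1e-9. Problem sizes in the test
suite and acceptance script (20 synthetic runs, 1000 random logo columns,
50–100 random trees, a 10,000-row filter table) were chosen as the smallest
sizes at which the checked properties are meaningfully exercised; all run in
seconds on one CPU.

## Known limitations

- MAST/FIMO/TOMTOM outputs and MEME's HTML report are not parsed.
- The fixture writers target the parsers' contract; they are not intended to
  be consumed by other MEME-ecosystem tools.
- No relative-entropy (background-weighted) logos or difference logos.
- No tree inference, rerooting or Nexus/PhyloXML support.
- Figure axis units are labeled generically "position" (residues for
  protein, bases for nucleotide runs).
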