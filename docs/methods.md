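# Methods

## Alignment model

The aligner implements a miRNA-specific model: target recognition is
dominated by the seed (mature nt 2–7), so a read that does not contain an
exact, uncorrupted copy of some reference seed at a position compatible with
miRNA structure is treated as non-miRNA and discarded before any extension
work. Alignment is strictly ungapped: a tag position `i` anchored with the
seed at tag position `s` pairs with mature position `i − s + seed_start`,
and end differences are modelled as unaligned additions/deletions at the
ends, never as gaps inside the alignment. This reflects the biology of
isomiR formation (imprecise end processing and untemplated tailing) rather
than generic sequence divergence.

Coordinates are 1-based and inclusive throughout, matching the field's
"nt 2–7" convention.

### Extension and mismatch rules

- The 5′ flank (mature positions before the seed that the tag reaches) is
  fully paired; a mismatch at mature position 1 is allowed and counted.
  Tag nucleotides 5′ of mature position 1 are unaligned 5′ additions
  (`offset_5p > 0`), not gaps or mismatches.
- The 3′ extension walks from `seed_end + 1` toward the mature 3′ end,
  recording mismatches, and stops immediately before the mismatch that
  would exceed the budget (`max_mismatches`, default 2). The unwalked tag
  tail becomes `overhang_3p`. Truncation, not rejection: the tag may still
  represent the miRNA with a divergent 3′ end.
- Two retained mismatches whose mature coordinates are within
  `mismatch_window` (default 10 nt) of each other reject the alignment.
  The source description gives both a pairwise-distance evaluation and a
  "two mismatches in the first 10 aligned nucleotides" phrasing; the
  pairwise-distance rule subsumes the positional one and is what is
  implemented, with the window exposed as a parameter. This is a deliberate
  disambiguation, flagged here rather than silently chosen.
- Rejections are typed (`mismatch_window`, `too_short`, `low_identity`,
  `no_seed`); when a tag fails on all anchors the reported aggregate reason
  is the highest-priority one in that fixed order, so reports are
  deterministic.

### Scores

Each accepted alignment carries

    align_score  = (miR_size − (align_size − #gaps)) / miR_size × 100
    miRtag_diff  = miR_size − tag_size

`align_score` is 0 for a full-length span and grows as the aligned span
shrinks relative to the mature; `#gaps` is identically 0 in the ungapped
mode but is kept in the formula so a future gapped mode can reuse it.
`miRtag_diff` separates candidates whose spans tie but whose overall
lengths do not.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `seed_start`, `seed_end` | 2, 7 | nt | seed span on the mature |
| `tag_search_min/max` | 1, 6 | nt | allowed seed start positions in the tag; admits a 1-nt 5′ deletion up to a 4-nt 5′ addition |
| `min_align_len` | 11 | nt | minimum accepted span |
| `mismatch_window` | 10 | nt | two mismatches closer than this reject |
| `max_mismatches` | 2 | count | retained mismatches before 3′ truncation |
| `identity_min` | 80 | % | minimum identity over the span; 80 keeps the 2-mismatch / 11-nt regime feasible (2/11 ≈ 18 % divergence) |
| `max_len_diff` | 4 | nt | reporting-stage \|miRtag_diff\| cap (d/u/f flag "f") |

Seed length 6 (nt 2–7) and minimum span 11 are the validated operating
point of the method; the rest are exposed because users legitimately tune
them per library chemistry.

## isomiR taxonomy and interaction sites

Labels are composed, in fixed order, from `iso_5p` (seed shifted in the
tag), `iso_snp`/`iso_multi_snp` (1 / ≥2 internal substitutions outside the
seed), and `iso_3p` (3′ length difference or overhang); `mirna_exact`
requires a full-span identity alignment. A pure 3′ variant is additionally
aliased `iso_3p-only` in reports. The taxonomy is exhaustive and exclusive
over accepted alignments.

Site conservation is evaluated from the recorded mismatch coordinates:
seed (exact by construction), offset = nt 8, central = nt 4–16, each
requiring every position aligned and matching; supplementary = nt 13–16
requires only the longest run of contiguous aligned matches to reach 3,
since contiguous Watson-Crick pairing — not completeness — is what
strengthens 3′-supplementary targeting. Mature positions outside the
aligned span cannot pair, so a truncated span breaks any site needing them.
Two documented disambiguations: the central span is 4–16 (the alternative
3–16 reading is accommodated by the `central_span` setting), and the
supplementary rule uses ≥3 contiguous matches (configurable) because the
biology is stated as a preference for 3–4 contiguous pairs, not a hard
predicate.

3′ additions are not split into templated vs untemplated: that distinction
needs genomic context, which is out of scope.

## Multi-mapping and multi-species resolution

Tags with one accepted alignment are *unique*; with several, the winner is
the minimum of `(align_score, |miRtag_diff|)`. An exact tie on both scores
across distinct mature ids is refused (`ambiguous_unresolved`) and the
tag's counts join no expression table — refusing fabricates no counts,
and no fractional (EM-style) allocation is attempted. A tie confined to a
single mature id (the same seed occurring at two tag positions) is broken
deterministically by position. Rescue is permutation-invariant: candidate
input order never changes the outcome.

With a reference spanning several species and a `focal_species` set, a tag
whose winner belongs to another species is excluded from the focal
expression tables (still present, labelled, in tag-level files). A tag
tied between the focal and a foreign species is *not* excluded — exclusion
requires the foreign alignment to actually win.

## Outputs and accounting

Nine TSVs with `#`-prefixed headers; column layouts are a documented
reconstruction (no published schema exists). Counts are integers,
percentages two decimals. The length filter (`|miRtag_diff| > 4` → flag
"f") acts only on reported flags and filtered views; flagged tags remain
in the expression tables, which is what makes the conservation identity

    input reads = unique + rescued + ambiguous_unresolved + discarded
                  + species-excluded

hold exactly on every input. Tag-level rows are sorted by descending count
then sequence, expression rows by descending total then id, so outputs are
byte-identical across runs and invariant to input order.

## Synthetic data

`isomirsea.synthetic` generates the entire test surface: references with
distinct seeds (sharing on request, to emulate families) and tags built by
applying a known variant class to a known source — 5′ shifts in [−1, +4],
3′ shifts in [−4, +4] constrained to `|miRtag_diff| ≤ 4` and span ≥ 11,
substitutions placed uniformly outside the seed respecting the mismatch
window, and two negative classes (`seed_corrupt`, `no_seed`) verified by
rejection sampling to contain no reference seed anywhere in the search
window. Truth labels (expected token and site flags) are computed at
generation time by independent span arithmetic, not by calling the
annotator, so label-recovery tests are not circular. Read counts per tag
are uniform on [1, 40] — a deliberately flat stand-in, since class recovery
and accounting, not abundance modelling, are what the corpus must exercise.

What the generator does **not** emulate: realistic (long-tailed) expression
distributions, sequencing error profiles beyond substitutions, adapter
artefacts, cross-mapping structure of real miRNA families, or genomic
context for templated tailing. Passing tests therefore demonstrate
correctness of the alignment/classification/accounting machinery under the
stated rules, not end-to-end accuracy on any particular biological library.

`synthetic.brute_force_align` is the independent oracle: a literal,
slice-based enumeration of every seed placement with the rules applied
verbatim, kept deliberately separate from the index-driven production path
and compared to it on randomized corpora (~1,200 pairs with random
substitutions/indels, lengths 16–30).

## Verification problem sizes

The standard checks run at: 1,200 randomized pairs for oracle equivalence;
a 50-reference corpus with 20 tags per class (≈280 tags) for truth
recovery; a 40-reference two-species corpus for conservation and
determinism; and a 1,000-reference / >10,000-tag corpus for the scale
smoke test. These sizes give full coverage of every rule path while
keeping the whole suite in the seconds range.

## Known limitations

- No gapped mode; internal insertions/deletions in a tag shift the 3′
  register and surface as mismatch clusters or truncation.
- A maximum 5′ deletion of one nucleotide: deeper 5′ trimming removes seed
  nt 2 and the tag is discarded, by design.
- No precursor (hairpin) re-mapping of discarded tags, no genome mapping,
  no normalization (RPM/TMM) or differential expression.
- Counts from refused ties are reported but never allocated; strongly
  homologous families with identical scores will under-count in expression
  tables, visibly (the ambiguous file carries them).
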