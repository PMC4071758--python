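# Methods

This note documents the models, conventions and parameter choices behind
splicefate, and what the synthetic substrate does and does not emulate.

## Coordinates and strand

GFF3 is 1-based inclusive on disk; everything in memory is 0-based
half-open, converted in `gene_model_io` and nowhere else. Minus-strand
genes are reverse-complemented at load, so every downstream module sees a
transcript-oriented model (genomic sequence reading 5′→3′ along the
transcript, exon intervals ascending); the original strand is retained
only for serialization. When a gene carries several mRNAs the canonical
transcript is the one with the longest summed CDS, ties broken by
lexicographic mRNA id — deterministic, and consistent with treating the
full-length cDNA as the reference isoform.

Structural validation fails closed: overlapping or unordered exons, a CDS
that is not a codon multiple or shorter than start+stop, and introns below
the minimum length are all load errors. The minimum intron length defaults
to 20 nt — below the effective minimum for plant U2 introns — so that
sub-minimum gaps are treated as annotation artifacts rather than real
introns.

## Event taxonomy

`diff_chains` explains every nucleotide of a variant chain relative to the
canonical model; `classify_form` maps the differences to events with a
fixed precedence:

* a variant segment covering a whole canonical intron is **IR**;
* partial inclusion at the intron's 5′ side is **Alt5SS**, at the 3′ side
  **Alt3SS**, and inclusion at both sides of one intron yields two AltSS
  events on that intron;
* **ES** is only called for a wholly absent exon; an exon trimmed at one
  edge is a negative-delta AltSS on the flanking intron (trimmed exons are
  a splice-site choice, not a skip);
* included sequence touching neither splice site of an intron, an
  internally split exon, or a trimmed outermost gene boundary is outside
  the taxonomy and rejected as a novel segment.

Deltas are signed changes to the mature transcript, so canonical spliced
length + Σδ = variant spliced length identically; the classifier asserts
this on every call. Retaining several introns in one form yields that many
IR events on the single form.

Greek names are assigned structurally: α is the annotation-canonical chain
(not the most abundant clone, which the package cannot know), and the
remaining forms sort by their full event-tuple sequence (anchor, type
code, delta). Duplicated event lists merge, unioning tissue provenance.
Naming is therefore a pure function of the set of event lists. Past ω the
names continue `aa25`, `aa26`, …

Because a combination form is ambiguous between "one form" and "two
events", `tally_events` reports both views (`per_form` and `per_event`)
alongside the total of non-canonical forms and the count of IR-only forms.

## cDNA-to-chain mapping

Spliced cDNA input is mapped to an exon chain by exact 20-mer anchoring
with greedy maximal extension — no fuzzy alignment; a cDNA that cannot be
explained exactly is rejected. Junction micro-homology (the intron's first
bases coinciding with the next exon's first bases) can make the greedy
extension overrun a donor site, so up to 15 nt may be handed back and
re-anchored; among the exact splits the mapper prefers the one whose
donor/acceptor coincide with canonical splice sites of the model, then the
smallest backtrack. Ambiguous anchors resolve to the leftmost genomic hit.

## Translation and the PTC definition

Translation uses the standard nuclear code. Codons containing ambiguity
characters translate to `X` and never terminate — deliberately including
codons such as `TAR` that would be a stop under every resolution, because
an uncertain base should not create a confident stop. A CDS that does not
start with ATG triggers a warning but is translated.

The PTC call is positional-by-identity: the variant's first in-frame stop
is premature iff its three genomic nucleotides differ from the canonical
stop codon's. This is the only definition under which a frame-preserving,
stop-free intron retention (protein +L/3 aa) or a frame-preserving exon
skip (protein shortened) is PTC-free and putatively functional while every
frameshifting variant is not. The mammalian-style 50-nt exon-junction rule
is implemented as an optional secondary flag (`ejc_rule=True`), off by
default, and never feeds the functional call. Variant translation runs
from the mapped canonical start through the transcript 3′ end, because a
frameshifted stop can lie downstream of the canonical stop inside the
3′UTR; loss of the start-containing region reports a zero-length protein
with an explicit flag.

NMD-candidate features are exactly that — features, never a claim of NMD
targeting: uORF count (ATG-initiated reading frames terminating inside the
5′UTR; frames running into the main CDS are tallied separately as
"overlapping"), variant 3′UTR length with a configurable "long" threshold
(default 350 nt — the literature says "long" without a number, so a fixed
documented default keeps runs reproducible), and presence of a
still-spliced intron entirely 3′ of the variant's stop codon.

## Intron projection, conservation, loss

An intron with `c` coding nucleotides upstream projects to residue
`⌈c/3⌉` with phase `c mod 3`, rendered `n.0` / `n.3` / `n.6`. The notation
is lossless (parse-back recovers residue and phase). Phase-0 introns sit
between codons n and n+1 and are keyed on the column of residue n — a
deterministic tie-break.

Conservation is exact (aligned column, phase) identity with no ±1-column
tolerance, matching how intron position tables are compared by eye; a
class is conserved when at least k of the n genes carry it (default
k = n; k is configurable because "somehow conserved" judgements in
practice use a majority reading). The MSA is an input artifact — alignment
construction is out of scope — and each row's ungapped sequence must equal
the gene's canonical protein, enforced with an error naming the offending
gene.

Loss inference is Dollo (single gain, no regain). The gain is placed at
the tree root by default — the supplied tree is usually a pruned
neighbourhood of a much larger phylogeny in which the intron is
demonstrably ancestral, and under root-presence an intron absent from two
sister taxa but present in the sole outgroup maps to one loss on the
sisters' common branch, which is the intended reading of such profiles.
`gain="mrca"` is available for the strict alternative in which absences
outside the intron-bearing clade need no event. Losses are the maximal
subtrees below the gain whose scored leaves all lack the intron; species
absent from the profile constrain nothing. On trees small enough to
enumerate, the event count equals the brute-force minimum number of loss
branches (verified in the tests).

## Synthetic substrate

The generator emulates the study conditions rather than arbitrary genes:
the two plant architectures (15 exons / 14 introns and 11 exons / 10
introns) are the default shapes; exon coding contributions are drawn from
45–150 nt (the 15-exon CDS then averages near the ~1.1–1.4 kb of real
SPO11 coding sequences), introns from 75–300 nt, GC fraction 0.42, 5′UTR
120 nt and 3′UTR 180 nt, with a literal GT…AG written at intron
boundaries and no further splice-site motif model. CDSs are built from
non-stop codons with an ATG start and a single terminal stop, so canonical
translations are clean by construction. All generation is a pure function
of (spec, seed); identical specs produce byte-identical artifacts.

`apply_events` realizes exactly a requested event list and refuses
infeasible or conflicting requests (AltSS deltas must leave ≥1 nt of exon
and a residual intron above the minimum; IR conflicts with AltSS on the
same intron and with skipping a flanking exon). Dataset manifests carry
expected PTC status and protein length computed by a deliberately naive
linear-scan oracle kept inside this module, so the classification and ORF
tests are not self-confirming.

Stop-free introns (the substrate for frame-preserving, PTC-free IR) are
forced to a codon-multiple length, capped at 90 nt — like the short
frame-preserving retentions seen in real surveys, and short enough that a
stop-free sequence is sampleable — and resampled until the retained
variant is stop-free; a phase-2 junction behind exon bases `TA` would
always read TAG across the GT donor, so that junction codon is swapped for
a safe one before sampling.

Planted alignments place n_planted introns at homologous backbone
positions across pseudo-species plus per-species extras inside
species-specific insertions (gapped in all other rows), so the planted
classes — and only they — can be conserved. The survey compositions
shipped in `SURVEY_COMPOSITIONS` re-encode the published per-species form
counts (8/6/5/11/1/1 with their type mixtures) on synthetic genes; the
anchors and deltas are stand-ins, the totals and type compositions are
the surveyed quantities.

What the synthetic data does not emulate: splice-site strength and branch
points, expression levels and clone abundances, sequencing error, real
codon usage, and paralog interference. Passing tests therefore demonstrate
the correctness of the coordinate arithmetic, classification, translation
and conservation logic on exactly specified structures — not robustness
to noisy annotation or to fuzzy transcript evidence, which the exact-match
design explicitly rejects.

## Determinism and sizes

Every random choice flows from an integer seed through `random.Random`;
reruns are byte-identical, TSV outputs carry no timestamps, and the
pipeline writes a config hash in its run log. The default test suite
classifies ~500 seeded forms and checks ~500 ORF outcomes against the
naive oracle (a few seconds in total); the acceptance script encodes one
eleven-form composition on a single synthetic gene. Problem sizes were
chosen to make each property check exhaustive over the event grid while
staying desk-scale.

## Known limitations

* Exact-junction matching only; transcripts from mis-annotated models or
  with novel (cryptic) exons are rejected rather than approximated.
* First/last-exon boundary changes (alternative transcription start or
  polyadenylation) are outside the event taxonomy.
* Dollo root-gain treats every intron class as potentially ancestral on
  the supplied tree; for classes genuinely gained inside the tree use
  `gain="mrca"`.
* uORF detection is ATG-only and does not score Kozak context.
* The 50-nt junction rule flag uses the variant's own last junction; it is
  informational and never enters the functional call.
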