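# Methods

## Scope and model of the analysis

`fesurvey` treats a genome survey of archaeal methanogens, methanotrophs,
and alkanotrophs as a deterministic annotation pipeline over predicted
proteomes. Per genome it produces (i) cofactor-binding-motif matches and
the [Fe-S]-motif proteome fraction, (ii) tiered homolog calls for a
configurable list of query gene families, (iii) pathway-level binary
features with biological flags, and per cohort (iv) per-taxon prevalence
tables and (v) a Jaccard/PCO ordination of genome feature profiles.
Nothing is statistically fitted; every output is a counting or linear-
algebra consequence of the inputs, which is why determinism (same inputs
and seed, byte-identical artifacts) is treated as a first-class contract.

## Motif grammar and scanner

Motifs are parsed from a compact grammar (fixed residues, `X` wildcards,
`(A/B)` alternations, bounded gaps `X{m}`/`X{m,n}`, and the literal open-gap
token `Xn`). Compiled patterns carry exact length bounds and scan via a
regular expression wrapped in a look-ahead, so overlapping matches at
distinct starts are all reported. Conventions, each chosen where the
source notations are silent:

- **Coordinates** are 1-based inclusive residue spans, matching protein
  numbering practice.
- **Open gaps.** The `Xn` token in siroheme-type motifs is unbounded in the
  literature notation; the scanner must terminate, so it compiles to a
  bounded gap with default (1, 50). Fifty residues comfortably spans known
  sulfite-reductase cysteine-cluster spacings; the bound is a configuration
  knob (`default_gap` / `--motif-gap-max`), not a constant.
- **One match per start.** Variable gaps expand to their shortest
  satisfying lengths (non-greedy quantifiers). Genome tables count
  motif-bearing proteins, not match multiplicity, so enumerating every gap
  assignment would add cost without information.
- **Ambiguity letters** (B, Z, J, U, O, X) in sequences satisfy wildcard
  and gap positions but never fixed or alternation positions: an ambiguous
  residue must not create a fixed-anchor hit.
- **Annotations.** CX{15}CH and CXXCK hits are flagged when the protein
  also carries a canonical CXXCH; CPV hits are flagged as CcmB-associated
  (the heme exporter subunit B characteristically carries this motif). The
  single-cysteine MsmS ligation pattern CXXXAH is available but off by
  default.

The [Fe-S] fraction of a proteome is the count of proteins with at least
one match from the [Fe-S] sub-library divided by the protein count. The
default [Fe-S] library is two sequence patterns — the [4Fe-4S] ferredoxin
spacing CX{2}CX{2}CX{3}C and the siroheme-type cluster CX{4,5}CXnCX{3}C.
This is an explicit approximation: production surveys use large curated
HMM/domain libraries for this quantity, so absolute fractions from the
motif library are not comparable to HMM-derived ones on real proteomes.
The pipeline exposes the library as configuration so a domain-based
provider can replace it.

## Tiered homolog classification

A hit record (E-value, bit score, percent identity, percent query coverage,
locus) is classified in strict tier order:

1. `E > e_max` → rejected (evalue); default `e_max = 1e-5`.
2. coverage `<= coverage_min` → rejected (coverage); the coverage screen is
   strict ("more than 30%").
3. identity `>= identity_min` (30%) and required motifs present → accepted.
4. identity in the half-open rescue band [20%, 30%) with domain evidence
   and motifs → rescued.
5. required motif absent → rejected (motif_failed).
6. otherwise rejected (identity or no_domain_evidence).

Boundary conventions (E passes at equality; identity accepts at equality;
coverage does not pass at equality) are stated because survey prose rarely
resolves them; only this reading makes a 20–30% rescue band meaningful
below a 30% acceptance cutoff. Siroheme-destination families (Dsr, Fsr)
use an override policy `E <= 1e-30`, identity and coverage `>= 50%`, no
rescue band, plus a required CX{4,5}CXnCX{3}C motif — sulfite/nitrite
reductase annotation warrants stringency because the fold family is large.

Domain evidence (the COG/Pfam assignment used to rescue 20–30% identity
hits) is abstracted as a pluggable boolean provider; bundling domain
databases is out of scope. The default desk-scale provider returns
required-motif satisfaction for families that declare required motifs and
False otherwise, so motif-less families get no free rescue evidence.

Bit-score filtering keeps the best hit per (family, subject) — ties broken
by lower E-value, then lexicographic subject id. With multiple seeds per
family, the best-scoring seed's hit represents the subject.

**Synteny rescue.** A rejected(coverage) or rejected(identity) call for an
operon-member family is upgraded to rescued iff at least `k = 2` other
families of the same operon have accepted/rescued calls within `w = 5` loci.
The neighbour count and window are exposed parameters: survey practice
("well-conserved operons") fixes neither. E-value rejections are never
upgraded — synteny compensates for truncation, not for absence of signal.

**Built-in backend.** `pairwise_search` runs Biopython's `PairwiseAligner`
(local, BLOSUM62, gap open 11 / extend 1). Identity is identical columns
over alignment columns (including internal gaps); coverage is the aligned
query span over query length. The approximate E-value uses gapped
Karlin–Altschul constants (lambda = 0.267, K = 0.041) with search space
m·n; it is documented as approximate, and no test or result depends on its
absolute value — only on the separation between planted homologs and random
background, which is orders of magnitude.

## Pathway rules, flags, ordination matrix

SufBC = SufB ∧ SufC. HemBCD = HemB ∨ HemC ∨ HemD (draft tolerance).
AhbABCD = all four subunits — the heme pathway is reasoned about as a
complete unit — with a companion `Ahb_partial` any-of feature so draft
genomes retain signal. The Feo state partitions genomes into
FeoAB/FeoA_only/FeoB_only/none; the ordination matrix encodes it as three
binary columns by default (switchable), since a categorical column has no
natural Jaccard contribution. Curated per-genome overrides (e.g. a known
homolog just outside the search thresholds) are applied through an explicit
override table and logged on the feature vector.

Flags: `heme_auxotroph_candidate` = some heme-user family present
(default set VhoC, HdrE, KatG, CydAB) and AhbABCD absent;
`siroheme_orphan` = SirA ∧ SirC ∧ ¬Dsr ∧ ¬Fsr. The ordination matrix
contains family bits plus pathway bits; raw motif-count columns are
excluded (motifs enter only through families that require them).
SirB/CbiX chelatases are not queryable: primary sequence cannot demarcate
them from paralogs, so the family list deliberately omits them.

## Summaries

Prevalences are integer percents with half-up rounding (95.4 → 95,
76.8 → 77, 12.5 → 13), matching how survey results print them. Group-mean
[Fe-S] fractions are unweighted means over genomes (the per-genome fraction
already normalizes by proteome size), rendered as percent at two decimals.
Denominators always derive from the matrix; a caller-supplied denominator
that disagrees is logged and ignored rather than silently adopted.

## Jaccard and PCO

Jaccard dissimilarity is computed by set arithmetic on binary rows; a pair
of feature-free genomes is defined as distance 0 (identical emptiness) and
triggers a warning, as such genomes are degenerate inputs. PCO is
classical scaling: Gower double-centering of −D∘D/2, symmetric
eigendecomposition, coordinates = eigenvectors × √λ for positive λ.
Numerical conventions:

- eigenvalues within 1e−9 (relative) of zero are treated as null axes;
- negative eigenvalues (non-Euclidean D) are reported but excluded from the
  variance-explained denominator, and no Cailliez/Lingoes correction is
  applied — variance explained is the share among positive eigenvalues;
- each axis's sign is fixed by making its largest-magnitude coordinate
  positive (first occurrence wins on exact ties), so output is
  deterministic under reruns and equivariant under genome permutation.

## Synthetic cohort generator

The generator emulates the structure of a survey cohort — not its biology:

- **Groups.** Each taxon group has a carriage probability per family.
  The default two-group configuration mirrors the observed contrast between
  deeply diverging lineages (FeoAB-rich, SufBC near-universal, no heme
  pathway, siroheme destinations rare, planted [Fe-S] fraction 6.8%) and
  the recently diverging heme-synthesizing lineage (AhbABCD, Dsr, heme-b
  users common, 5.5%), with carriage values set from the per-group
  prevalences the survey tables report.
- **Homologs** are substitution-only mutants of family seed sequences at a
  controlled target identity (default 60%): exactly round(L·(1−id/100))
  positions change, each to a different residue, so column identity is
  forced by construction and the classifier's identity bands are exercised
  analytically. An indel-free design keeps identity and coverage exact;
  families with required motifs have the seed's own motif region copied
  back at its original span, so the diagnostic motif survives mutation and
  identity can only move up.
- **Seeds** are deterministic synthetic stand-ins for real query proteins:
  240-residue cysteine-free random backbones (derived from the family name,
  independent of the cohort seed), with the family's diagnostic motif
  planted at a fixed offset where one exists.
- **Background** proteins are i.i.d. draws from a 20-letter or
  cysteine-free alphabet, lengths uniform in (120, 260). Because every
  default motif is C-anchored, the cysteine-free policy gives a provably
  zero false-positive regime for the scanner, separating scanner
  correctness from background-hit statistics.
- **Operons** (feo, suf, ahb) are planted as adjacent runs in an otherwise
  random gene order, so the synteny rule can be exercised with known truth.
- **Incompleteness** drops exactly round(N·completeness) whole proteins
  uniformly without replacement, preserving relative gene order. The
  default completeness 0.9 represents a cohort of mostly-good drafts (real
  surveys exclude MAGs under 50% complete but report no distribution above
  that floor; completeness is therefore a free parameter, chosen once).
- **Truth manifest** records planted families with their protein ids,
  planted motif spans and cofactor classes, dropped protein ids, and
  per-genome seeds — sufficient to recompute every expected downstream
  call, including the expected [Fe-S] fraction (siroheme plants count, as
  the siroheme cysteine cluster embeds a [4Fe-4S] center and is matched by
  the [Fe-S] library).

What the generator does **not** emulate: indel evolution (an optional
concern deliberately excluded from truth-exact tests), phylogenetic
correlation between genomes, realistic amino-acid composition, domain
architecture, or paralogy. Passing the planted-recovery suite therefore
demonstrates the pipeline's logical correctness under controlled
conditions, not field performance on real proteomes, where rescue bands,
domain evidence, and HMM-based [Fe-S] detection carry the weight.

## Problem sizes and verification

The test suite verifies the scanner against an independent brute-force
enumeration oracle exhaustively on every sequence of length ≤ 7 over
{A, C, G, H} and on 10,000 random length-200 sequences over the full
20-letter alphabet; the classifier against its decision table at every
threshold boundary; planted-cohort recovery end to end on a noise-free
2 × 20-genome cohort (sensitivity = specificity = 1.0); PCO against closed
forms (three equidistant points → eigenvalues ½, ½; variance 50%/50%),
distance reconstruction on Euclidean-embeddable inputs (≤ 1e−8), and an
independent reference PCoA implementation; group separation (axis-1
silhouette > 0.9) across ten seeds of two-group cohorts with disjoint
profiles; and byte-level determinism of the full artifact bundle.
`scripts/acceptance.py` recomputes the same quantities from scratch,
with the scanner check at 2,000 random sequences plus the exhaustive
sweep, and additionally re-derives the survey's printed prevalence
arithmetic through the summarizer from the published per-group counts.

## Known limitations

- The built-in aligner is a desk-scale stand-in: no composition-based
  statistics, no heuristic seeding; E-values are approximate.
- The motif-based [Fe-S] fraction undercounts relative to domain-library
  detection; it is a configurable stand-in.
- The CcmC/F tryptophan-rich periplasmic motif has no universal printed
  consensus; it is a per-family configurable required pattern with no
  hard-coded default.
- Negative-eigenvalue handling in PCO (exclude from denominator) is one of
  several published conventions; it is configurable only by
  post-processing the returned eigenvalues.
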