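# Methods

This note records the modelling choices behind cubkit's statistics, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that matter when comparing output
against other tools.

## Genetic codes and family structure

Translation tables 1, 6 and 10 are built from Biopython's NCBI tables; the
synonymous-family partition (grouping sense codons by amino acid) is derived
here. The degeneracy censuses are {1:2, 2:9, 3:1, 4:5, 6:3} (table 1, 61
sense codons), {1:2, 2:8, 3:1, 4:6, 6:3} (table 6, 63 — Gln becomes the
4-fold {CAA, CAG, UAA, UAG}) and {1:2, 2:8, 3:2, 4:5, 6:3} (table 10, 62 —
Cys becomes the 3-fold {UGU, UGC, UGA}). Six-fold amino acids (Leu, Ser,
Arg) are treated as single families, as in Wright's original ENC treatment.
Codons are stored in the DNA alphabet; reports may render them RNA-style.

Per-species defaults follow known ciliate usage: table 6 for hypotrich-type
MAC genomes, table 10 for euplotids; every entry point takes an explicit
table id, because the choice changes the stop set, the family structure, and
therefore every downstream index.

## CDS quality control

A record is kept when it is unambiguous (no N), a multiple of three, starts
with ATG, ends with a canonical terminator (TAA/TAG/TGA — deliberately
independent of the working code, since a table-6 gene still *ends* with its
genomic terminator even though UAA is Gln-sense internally), contains no
internal stop under the working code, is strictly longer than `min_len`
(default 300 nt) after any processing, and is not an exact duplicate or
exact reverse-complement duplicate of an earlier record (first occurrence
wins; the duplicate registry includes rejected records, so a raw
minus-strand copy preceding its plus-strand twin still marks the twin
redundant). Rejection reasons are assigned in a fixed order so reports are
deterministic. Two internal-stop policies are provided because both appear
in practice: `reject` (default, strict) and `delete_codon`, which excises
the offending codons and logs each excision. Near-duplicate clustering is
out of scope — duplicate detection is exact string matching only.

"Excluding Met and Trp" is implemented the CodonW way: one-fold families are
counted (the ATG start included) but excluded from all synonymous statistics
(GC3s, X3s, RSCU, ENC class averages), not removed from sequences.

## Index conventions

- The terminal stop codon is excluded from all counts.
- GC1/GC2/GC3 run over all counted codons; GC3s and X3s only over codons of
  degeneracy ≥ 2 families. The default X3s definition is the fraction of
  synonymous-family codons whose third base is X, so A3s+U3s+C3s+G3s = 1
  exactly; CodonW's historical per-base eligible-codon denominators are
  available via `x3s_mode="codonw"` (those four values need not sum to 1).
- ENC follows Wright's class-average estimator: families with n < 2 or
  F̂ ≤ 0 are dropped from their class; a missing 3-fold class mean is imputed
  as the mean of the 2- and 4-fold class means; if any other class cannot be
  estimated the gene's ENC is reported missing rather than guessed. The
  result is clipped to [2, sense-codon count]. Values are reported to two
  decimals in TSV output, full precision internally.
- PR2 coordinates default to all third positions of counted sense codons;
  `site_set="fourfold_third"` restricts to fully degenerate (NNN) boxes,
  including those inside 6-fold families. The fourfold restriction is the
  right instrument for strand-symmetry questions: with all third positions,
  the code's family structure itself (both one-fold codons ending in G; six
  U/C-ending two-fold families versus two or three A/G-ending ones) pushes
  the centroid off (0.5, 0.5) even under a perfectly strand-symmetric
  mutation process.
- The neutrality fit is ordinary least squares of GC12 on GC3s with the
  Pearson correlation and its two-sided p-value; correlations elsewhere are
  Pearson by default (Spearman by flag), computed pairwise-complete.
- Optimal codons: genes ranked by ENC ascending (low ENC = high bias; ties
  broken by gene id and logged); tail size ⌈0.10·n⌉ with a minimum of 2 and
  a minimum of 20 genes overall; ΔRSCU uses a strict `> 0.08` threshold; an
  optional stricter convention additionally requires RSCU_high > 1.

A caveat worth knowing when reading single-species ΔRSCU tables: because the
low-bias tail is *selected* for maximal ENC (i.e. maximally balanced usage),
its pooled RSCU is pulled toward 1, which inflates ΔRSCU by roughly one
standard deviation of the within-family sampling noise for every codon whose
genome-wide RSCU differs from 1. With tails of a few dozen genes this can
push unrelated codons past 0.08. The cross-species intersection is the
method's own correction for this — species-specific noise and composition
artefacts do not survive intersection across nine genomes — and is what the
recovery tests certify.

## RSCU comparison and trees

Per-species pooled RSCU rows span the union of synonymous codons across the
species' codes; a codon that is a stop (or one-fold) under some species'
code is missing for that species. Distances use pairwise-complete columns
rescaled by the total/shared column ratio (square root of the ratio for
euclidean) so pairs with different code-induced missingness stay comparable;
pairs sharing fewer than 10 columns are refused. UPGMA is the default
linkage (deterministic: among tied minimal pairs, the pair whose smallest
leaf labels sort first is merged) and produces an ultrametric Newick tree;
neighbour joining (scikit-bio) is available where ultrametricity is not
wanted. No bootstrap support is computed.

## CRISPR helpers

`scan_pam_sites` enumerates every 20-nt window immediately followed by NGG
on the plus strand and, by default, the reverse complement; windows
containing N are skipped and logged. Minus-strand sites report their
protospacer/PAM in minus-strand orientation with `start` being the
protospacer's leftmost plus-strand base. Guide *scoring* (GC content,
homopolymers, off-target search) is intentionally absent: site enumeration
and PAM counting only. `optimize_codons` rewrites every codon whose amino
acid has a designated target codon, never touches the start codon or the
terminal stop, and is translation-invariant and idempotent by construction;
when driven by an `OptimalCodonReport` that flags several codons in one
family, the largest-ΔRSCU codon is used.

## The synthetic generator

The generator emulates the statistical regime the analyses assume: hundreds
of start/stop-delimited genes (default 400 genes of 100–300 interior codons,
i.e. > 300 nt), an AT-rich synonymous composition (gene-level GC3s targets
drawn Normal(0.30, 0.05), clipped), a linear GC12 coupling
gc12 = a·gc3s + b + ε with defaults a = 0.4, b = 0.20, ε ~ N(0, 0.02) —
slopes and intercepts of that order are what AT-rich microbial genomes
show — and an optional within-family preference: designated codons receive
an extra log-weight s in the first `bias_fraction` (default 10%) of genes.
Amino-acid usage mixes a GC12-rich and a GC12-poor family pool, with the mix
chosen per gene so the expected first+second-position GC equals the gene's
target exactly given its actual within-family codon probabilities.

Two numerical choices matter:

- **Hierarchical multinomial sampling.** Each gene first draws its stratum
  totals (synonymous GC3-enders / synonymous AT3-enders / one-fold codons),
  then places codons within strata. The GC12 target is computed *between*
  the stages from the realized GC3s, so the neutrality regression recovers
  the configured slope without errors-in-variables attenuation, while
  within-family codon counts remain multinomial — which is what Wright's
  F̂ = (n·Σp̂² − 1)/(n − 1) estimator assumes. (A low-variance deterministic
  rounding scheme was evaluated and rejected: it deflates F̂ and drives ENC
  to the sense-codon cap.)
- **One global RNG stream per run**, seeded once; identical config + seed
  reproduces byte-identical FASTA.

The nine-species scenario draws GC3s means over 0.18–0.40 (all AT-rich),
puts eight species on table 6 and one on table 10, and injects a shared
8-codon optimal set — one AT-ending codon in each of eight distinct families
(UUU, UAU, CCU, GUU, GCA, AGA, AGU, ACU), so each family's RSCU shift
identifies exactly one codon — plus two private preferred codons per
species. Scenario conditions are 250 genes of 120–360 codons per species,
preference strength 2.0, GC3s spread 0.03: strong enough that the biased
10% occupy the low-ENC tail cleanly, with the composition-driven ENC spread
kept below the preference-driven separation.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: expression-correlated codon bias (bias flags
are assigned, not caused by an expression model), amino-acid composition
differences between genes beyond the GC12 pools, length–bias correlations,
isochore or chromosome-scale structure, sequencing or annotation error, and
evolutionary covariance between species (species are generated
independently; the RSCU tree on synthetic data reflects composition
distance, not descent).

## Desk-scale problem sizes

The validation suite and the acceptance script size their simulations to
what the recovery statistics need rather than to genome scale: 500-gene sets
for slope recovery (10 replicates), the nine-species scenario at 250 genes
per species (10 replicates), 1,000 genes for the PR2 centroid, 1,000 random
genes per code for RSCU normalization, and 60 random instances per oracle
comparison. At these sizes the whole suite runs in well under a minute of
simulation time while keeping recovery bands (slope ± 0.05, exact
shared-set recovery in ≥ 9/10 replicates, centroid within 0.02) comfortably
away from their statistical noise floors.

## Known limitations

- Correspondence analysis of RSCU (a common companion analysis) is not
  implemented; the correlation matrix covers the composition–bias
  relationships computed here.
- CAI, Fop and tRNA adaptation indices are out of scope.
- The ΔRSCU threshold 0.08 is a convention, not an inference; no multiple-
  testing control is applied to per-codon calls (see the single-species
  caveat above).
- ORF discovery, gene prediction and near-duplicate clustering are not
  provided; inputs are assumed to be annotated CDS collections.
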