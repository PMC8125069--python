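# Methods

This note documents the models and procedures implemented in
`effectornet`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that make the pipeline deterministic.

## Sequence comparison

All pairwise comparison is exact Smith–Waterman local alignment with
affine gaps (Gotoh recurrences), BLOSUM62, gap open 11 and gap extend 1 —
the classic protein-search defaults. A gap of length *k* costs
`11 + k`. The kernel is a numba-compiled dynamic program with fully
specified tie-breaking: the traceback starts at the first maximal cell in
row-major order; at each cell the preference is aligned pair, then gap in
the subject, then gap in the query; inside a gap, extension beats
re-opening. Fixing the ties matters because two downstream statistics —
identity and alignment length — are not invariant across co-optimal
alignments; with the ties pinned, both are reproducible and are verified
against an independent brute-force full-matrix oracle in the test suite.

Two identity conventions coexist deliberately, mirroring the two tools
they stand in for:

- **short-style** (clustering): identities / length of the shorter full
  sequence. A fragment that matches part of a long representative still
  clusters with it.
- **blast-style** (homolog search, network edges): identities / alignment
  columns, gap columns included.

## Clustering

Greedy incremental clustering: sequences sorted by decreasing length
(ties: lexicographic id); the longest founds the first cluster as its
representative; each subsequent sequence joins the *first* founded
representative it matches at ≥ 40 % short-style identity, else founds a
new cluster. The first-fit rule and the explicit sort make the partition
deterministic; a brute-force replay of the same rule serves as the test
oracle. 40 % is the field's customary family cutoff for polymorphic
toxins and is a config key (`cluster_identity`).

## Motif models

Domain detection uses gapless position-specific scoring matrices rather
than profile HMMs. Per retained column *c* and residue *r*,

    score(c, r) = log2( (count(c, r) + pc·bg(r)) / ((n_c + pc)·bg(r)) )

with pseudocount `pc = 1`, uniform background, and columns over 50 %
gapped dropped. Scanning sums column scores over every window (residue X
scores 0); overlapping above-threshold windows merge into one hit keeping
the maximal-scoring span. The motifs this package targets have ungapped
conserved cores, for which a gapless PSSM is an adequate detector; the
contract is simply protein → scored spans.

**Threshold calibration.** The scan threshold is set empirically, not
theoretically. Decoys are residue-shuffled seed sequences embedded in
background-composition sequence of typical protein length (1,000 aa by
default): a threshold must control the false-positive rate per *protein*,
and a protein exposes hundreds of windows, so bare-width decoys would
calibrate the wrong quantity. `calibrate_threshold` returns the smallest
threshold at which at most a `target_fpr` fraction (default 0.001) of
decoys fire — the noise floor. The working threshold of a library model
then sits one third of the way from that noise floor to the weakest
seed's self-score (the trusted ceiling), in the spirit of profile
noise/trusted cutoffs: with the synthetic families used here the gap
between the noise floor and true carriers exceeds 300 bits, so the
placement is uncritical across a wide band, and both the fraction
(`threshold_fraction`) and the decoy geometry are config keys. Sensitivity
on the training seeds is asserted as an invariant.

## Rhs core/toxin splitting

For each protein with an Rhs-core motif hit, the scan window
`[hit.start, hit.end + 100]` is searched for D-P-x-G; among occurrences
the one whose final G lies nearest the hit's end is the anchor (ties to
the earlier occurrence), and the first toxin residue is the position after
that G. Proteins with several candidate occurrences are flagged
(`ambiguous_split`) rather than silently resolved. Proteins without any
occurrence are excluded from the core/toxin analysis
(`excluded_no_dpxg`); toxin domains shorter than 30 aa are dropped
(`core_only`). Core domains shorter than 150 aa are left unassigned in
core clustering — orphan remnants rarely retain enough core to place.

Full-length status is *architectural* — core motif + DPxG split + toxin
domain — not a length cutoff; the familiar ~1,400-aa figure for intact
Rhs proteins is descriptive output, never a rule.

Orphan recovery searches every toxin-cluster representative against all
proteomes (≥ 40 % blast-style identity, ≥ 90 aligned columns — a
domain-sized floor); each matching protein joins the cluster of its
best-identity representative (ties: longer alignment, then smaller
cluster id) and is labelled `orphan_toxin` unless it has its own split.

## VgrG profiling

VgrG-motif proteins cluster at 40 %; representatives are searched with a
spike-sized alignment floor (≥ 300 columns). Matches longer than 500 aa
are counted members; shorter ones remain fragments. Length statistics
exclude gene copies at contig ends (partial by assembly, not biology);
truncation flags mark members shorter than half their cluster's maximum
among non-contig-end members (`truncation_fraction = 0.5` — the field
describes pseudogenes as "truncated relative to the cluster" without a
number, so this is an explicit, configurable operationalization). A
mobile-element context flag is set only when a neighbouring gene's
annotation matches a keyword list (transposase, insertion sequence,
integrase); there is no de-novo IS detection.

## T6SS completeness

Structural detection aligns every proteome protein to every reference
structural protein; a protein maps to at most one structural gene (highest
identity wins) at ≥ 40 % identity and ≥ 70 % reference coverage (a
permissive 0.20/0.20 mode exists for distant outgroups). Hits within
10 kb on one contig merge into loci; loci whose only structural gene is
tssI are satellites and never count toward completeness. Verdicts:

- `complete` — every required gene hit (subtype-iii's tssQ/tssR are
  reference proteins but never required);
- `complete_contig_end_exception` — exactly one required gene missing
  *and* a non-satellite locus terminating at a contig boundary
  (`contig_end_margin = 0`: the locus must truncate flush with the end,
  which prevents crediting genuinely deleted genes);
- `incomplete` — some structural evidence, neither rule met;
- `absent` — no non-satellite structural evidence.

A genome's overall verdict is the best across reference sets; a locus
belongs to the set that the majority of its genes match best.

## Immunity pairing and cooccurrence

Immunity genes sit immediately downstream of their toxin: the first
downstream neighbour on the same strand within 200 bp (both config keys;
the spacing is typical operonic distance). Pair representatives — by
default auto-derived, one per toxin cluster from largest down, taking the
first member with a pairable neighbour — are searched across all genomes
at ≥ 40 % identity over ≥ 90 % *of the reference's length*. When a toxin
is present without its immunity partner the cell carries a caveat:
`toxin_at_contig_end` if a counted toxin gene has nothing downstream on
its contig, else `low_homology`.

## Secretion-context classification

Similar toxin domains ride different secretion systems. Each Rhs-related
protein gets one label by fixed precedence: hemagglutinin repeats plus a
signal peptide in the first 100 aa → `t5ss_autotransporter`; an SpvB/TcdB
hit in the N-terminal half or a type-A sorting-domain gene within one
neighbour → `t9ss_associated`; a PAAR hit, or full-length architecture
with an Rhs core → `t6ss_effector`; orphan status → `orphan_domain`;
otherwise `unknown`. Missing motif models simply never fire, so a minimal
library degrades toward `unknown` rather than failing.

## Networks

Two edge rules: ≥ 40 % identity over ≥ 90 aligned columns (domain-scale)
or over ≥ 90 % of the shorter protein (full-protein scale; the shorter
protein is the permissive, symmetric choice of denominator and a config
key). The toxin homology network is built over *extracted toxin-domain
sequences* (whole proteins would connect across toxin families through
their shared cores — the very confounder that motivates splitting). The
core–toxin graph is bipartite by construction: cluster nodes sized by
membership, edges weighted by the number of full-length proteins pairing
them; its stars are C-terminal displacement signatures.

## The synthetic-data generator

The generator emulates a panel of draft isolate genomes the pipeline is
meant for: 1–3 contigs per genome; a T6SS structural locus planted as
complete, truncated flush at a contig end (one gene lost), subtype-iii
(no tssQ/tssR), partially deleted, or absent; full-length *rhs* genes
(PAAR-bearing stub + conserved core ending in DPxG + toxin, ~1,250–1,450
aa) each with an immunity gene 40–150 bp downstream on the same strand
(minus-strand cassettes included); downstream orphan arrays; satellite,
pseudogenized (< 50 % length) and contig-end *vgrG* copies; immunity-only
genes; and random decoys. Proteins are reverse-translated (table 11) into
gene sequences with random spacers, emitted as GFF3 + FASTA + protein
FASTA, and every planted gene is recorded in a ground-truth ledger.

Family structure is controlled positionally: family seeds are fixed-seed
random proteins; members are substitution-only mutants at 0.85 identity
to their seed, giving pairwise within-family identity ≈ 0.70 — above the
0.60 separation floor the defaults promise. Between-family identity of
seeds stays ≤ 0.25 and decoys are re-sampled until ≤ 0.30 against every
family representative; all three bounds are re-measured with the
alignment oracle at generation time, and violations abort. Conserved
motif blocks are shared across families at low divergence (0.90 for the
Rhs core — biologically the most conserved region — and 0.75 for the
VgrG spike head). The spike value is deliberately lower: a pseudogene
truncated down to little beyond the conserved head must still fall below
the 40 % clustering threshold against *other* families, which bounds how
similar family-level spike copies may be. Orphan core remnants (60 aa)
are drawn independently per orphan — decayed remnants diverge fast — so
remnants never create homology edges between unrelated orphans. The
structural tssI references carry no VgrG motif block, keeping the planted
satellite VgrG families the only motif carriers; in real annotation the
locus vgrG would also be motif-positive and would simply join the
inventory.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic nucleotide evolution (no indels, no
codon bias, no rearrangements), gapped domain architectures (real Rhs
cores contain repeats and indels a gapless PSSM would handle less
cleanly), annotation noise (mis-called gene boundaries, missed CDS),
contamination, and families near the 40 % boundary. The clean separation
band (within ≥ 0.60, between ≤ 0.25) makes exact recovery achievable by
design; on real genomes the same thresholds will produce boundary cases
the synthetic tests cannot exercise.

## Determinism and problem sizes

Every random draw flows from a single seed through named
`SeedSequence` streams; reruns produce byte-identical tables, FASTA,
networks and manifest (checksums of every file, relative paths). The
default validation community is 20 genomes (~550 proteins, 6 toxin
families, 3 VgrG families) — large enough that every planted verdict
class, displacement signature and pseudogene mode occurs, small enough
that a full pipeline run takes about a minute on one CPU; the
cooccurrence demonstration uses a 5-genome, 4-family community. These
sizes are the package's validation conditions, not limits: stages scale
quadratically in total protein count through the all-vs-all steps.

## Known limitations

- The PSSM scanner is gapless; a profile-HMM engine would be the natural
  upgrade for indel-rich motifs.
- Greedy first-fit clustering reproduces CD-HIT's semantics, not its
  exact output; representative choice differs from CD-HIT's heuristics.
- The one-missing-gene contig-end exception requires the locus to abut
  the contig boundary exactly (margin 0). Assemblies with trailing
  low-quality sequence may need a nonzero `contig_end_margin`.
- Pseudogene calls are length- and annotation-keyword-based only; no
  nonsense-mutation detection at the nucleotide level.
- The cooccurrence caveat distinguishes contig-end from low-homology
  cases but cannot recognize genuinely immunity-free toxins.
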