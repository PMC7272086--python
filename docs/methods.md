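# Methods

`hccpm` re-implements a two-axis prioritization scheme for phosphorylated
biomarkers of hepatocellular carcinoma (HCC): a *kinase-correlation* axis
that asks whether a candidate protein plausibly undergoes kinase-mediated
phosphorylation, and a *pathway-evidence* axis that asks whether the gene
plausibly marks HCC given the confirmed genes it shares pathways with.
Both axes produce a three-level call (strongly suggestive / suggestive /
not supported), and the combined phosphorylated-marker (HCCPM) call is the
conjunction of the two strong calls, the conjunction of the two negative
calls, and "suggestive" for every mixed case.

## Motif scanning and kinase nomination

Candidate kinases are nominated by sequence motifs written in Prosite
syntax: dash-separated elements that are literals, residue classes
`[RK]`, negated classes `{P}`, or the wildcard `x`, each with an optional
repeat count `(n)` or range `(n,m)`, plus optional terminal anchors `<`
and `>`. The scanner tests every window of the target sequence
(backtracking over variable-length elements, so *all* overlapping matches
and all lengths are reported) and discards matches whose phosphoacceptor
residue is not Ser, Thr, Tyr, or His. A motif that retains at least one
match nominates its associated kinases; the candidate set of a protein is
the union over matching motifs.

Conventions that the motif-table format leaves open were fixed as
follows and are part of the interface contract:

* **Site addressing.** `site_offset` counts 0-based residue slots of the
  matched window after repeat expansion (a repeat of length *k* occupies
  *k* slots), so the acceptor position is `start + site_offset`. This
  makes the acceptor well-defined for every match assignment and is
  validated against the pattern's minimal expanded length.
* **Skip flag.** Motifs with the skip flag set are excluded from
  scanning by default (an `--include-skipped` escape hatch exists).
* **Max repeat.** Stored and optionally enforced as a per-protein cap on
  the number of reported matches per motif (`enforce_max_repeat`); off by
  default because the cap changes no downstream score (kinase nomination
  only needs one surviving match).
* **Coordinates** are 1-based inclusive in every report.

The scanner is property-tested against an independently written
regex translation of the same syntax on >1000 random pattern/sequence
pairs per run.

## Kinase-correlation score Sk

For each (query, kinase) pair, three components are scored:

* **Tissue, St ∈ {0, 2, 6, 10}.** Both partners must be expressed in
  liver, blood, or the lymphatic system; the *weaker* evidence tier of
  the pair sets the score: both protein-level validated (T1) → 10,
  weakest mRNA-level (T2) → 6, weakest sequence-origin-only (T3) → 2,
  either absent → 0 (the pair cannot meet, so no reaction is possible).
* **Subcellular localization, Sl ∈ {0, 2, 4, 6, 8, 10}.** Two layers.
  Layer 1 scores each GO cellular-component term annotated on *both*
  records by the pair of evidence classes (both experimental L1 → 10,
  worst computational L2 → 8, worst curatorial L3 → 4, worst automatic
  L4 → 2) and keeps the maximum over shared terms; GO terms are compared
  as opaque identifiers (no ancestor propagation), and when a record
  carries several annotations of one term the most credible class is
  used. A layer-1 score ≥ 8 is final; otherwise sharing one of the six
  UniProt-style categories (Secreted, Cell Membrane, ER/Golgi,
  Mitochondrion, Cytoplasm, Nucleus) lifts the score to at least 6.
* **Cell-cycle phase, Sp ∈ {0, 10}.** 10 iff both genes have cycle
  profiles and are co-expressed (see below); a missing profile scores 0.

The combined score is the weighted mean

    Sk = (Wt·St + Wl·Sl + Wp·Sp) / (Wt + Wl + Wp),
    Wt = 5, Wl = 3, Wp = 2 (defaults; any positive weights accepted).

Tissue specificity carries half the total weight because expression in
the disease-relevant tissues is the binding constraint; phase data are
scarcer than localization data, hence Wp < Wl. Among all candidate
kinases the highest Sk is kept (ties broken by lexicographic kinase
accession for reproducibility); a query with no surviving motif match is
not supported.

**Classification modes.** The component-criteria mode (default) calls a
pair strongly suggestive when St ≥ 6 ∧ Sl ≥ 6 ∧ Sp = 10, suggestive when
St ≥ 6 ∧ Sl ≥ 6 (phase ignored because profile coverage is sparse), else
not supported. The threshold mode applies the Sk cutoffs ≥ 6.8 / ≥ 4.8
instead. With default weights the cutoffs are exactly the minima of Sk
over the respective criterion sets (asserted by brute force over the
4x6x2 component lattice), but the two rules are not logically
equivalent: (St, Sl, Sp) = (10, 10, 0) is suggestive by criteria yet
Sk = 8 ≥ 6.8. Both modes ship; the divergence is witnessed by a test
rather than hidden. Autophosphorylation pairs (query = kinase) are
scored normally and flagged.

## Cell-cycle profiles and co-expression

Profiles are log2(synchronous/asynchronous) ratios at arbitrary percent
positions of the division cycle (100% = cytokinesis). Every profile is
resampled by linear interpolation onto the integer grid 0–99; because
the cycle is periodic the segment from the last raw point wraps through
100% = 0% (a non-cyclic mode holding endpoints flat is available). Two
genes are co-expressed when both grids exceed a threshold at a shared
grid point; the default threshold 0 reads "enriched over the
asynchronous baseline". This positivity rule is one deliberate reading
of "expressed at the same time point"; peak-phase or correlation-based
readings are out of scope.

## Pathway-evidence marker score Scm

Within one pathway, a confirmed gene scores Sc = 10 (small-scale wet-lab
evidence, E1) or 8 (large-scale microarray/proteomic evidence, E2). An
unconfirmed gene is scored from the other genes of the same pathway
(OGSPs): with Ne E1-confirmed and Nm E2-confirmed OGSPs among Np total,

    Sc = W1·(Ne + 0.8·Nm)/Np + W2   if Ne ≥ 1      (range (3, 8])
    Sc = W2·Nm/Np                   if Ne = 0, Nm ≥ 1   (range (0, 3])
    Sc = 0                          otherwise,

with W1 = 5, W2 = 3, so an unconfirmed gene saturates at exactly 8 and
an all-E2 pathway yields exactly 3. **Counting basis:** Ne, Nm, Np are
computed over the members *excluding* the query. This choice makes both
identities exact — with a query-inclusive Np the all-E2 bound Sc = 3
would be unattainable — and is the only reading under which the stated
thresholds are attained.

Across the n pathways containing the gene, Scm = Σ Sc·W(Sc) / Σ W(Sc)
with the step weights W(10) = 10, W(8) = 8, W(Sc) = 5 for 5 ≤ Sc < 8,
else 3; the open interval (8, 10) cannot arise and is mapped to the
middle band. Classification: Scm ≥ 4.25 (the score of a pathway with a
quarter of its genes E1-confirmed) is strongly suggestive, Scm ≥ 3
suggestive, below that not supported. A gene outside every pathway is
not supported. Confirmed genes score 10/8 in every containing pathway
and therefore always classify strongly suggestive (when in ≥ 1 pathway).

## Drug joining and summaries

Drug–target rows (drug id, name, category ∈ {liver-cancer, cancer,
non-cancer}, target accession) are joined by accession equality and
tallied per category; categories are input data, never inferred. The
candidate set of a run is the union of pathway members present in the
corpus — confirmed markers included — and each per-system class triple
partitions it.

## Synthetic fixtures and what they show

The generator (`hccpm.fixtures`) emits complete corpora plus a
*constructive ledger*: every expected component score, Sk, Sc, Scm, and
classification is computed during planting from literal rule tables
local to the generator, never by calling the scoring engine, so the
engine-vs-ledger recovery test is a genuine dual-route comparison.
Three constructions make the ledger exact rather than probabilistic:

* background sequence is drawn from an alphabet disjoint from every
  non-wildcard residue of the fixture motifs, so a planted motif
  occurrence is provably the only one;
* GO sharing is planted through per-kinase signature terms, so the
  shared-term set of any pair is known at generation time;
* profiles are half-period square waves at phases {0, 25, 50, 75}, so
  co-expression reduces to "not exactly antiphase".

Defaults (seeded, mandatory seed): 1000 candidate genes; HCC evidence
fractions 7% E1 / 3% E2, mirroring the 421 + 190 confirmed genes among
the 5955 candidates of the reference corpus; tissue mix 45/30/15/10%
over T1/T2/T3/absent; 85% of queries carry a motif; 60% GO-sharing and
profile coverage; 1–3 dedicated pathways per query with 3–8 OGSPs each
(25% E1, 35% E2). Sequences are 60 residues. Where the reference corpus
does not pin a proportion these are round, plausible figures chosen once
for branch coverage, not fitted quantities.

What passing fixture tests does **not** show: real sequences contain
overlapping and repeated motif hits, real GO annotation is far denser
and hierarchical, real pathways overlap heavily, and real cycle profiles
are noisy and not square; the fixtures certify the scoring logic, not
performance on biological data.

## Numerical choices and limitations

* Scores are small rationals; comparisons use exact arithmetic where
  possible and 1e-9 tolerances at aggregation boundaries (`W(Sc)` band
  edges are matched with the same tolerance).
* Result tables print scores to 3 decimals; classification always uses
  full precision.
* Outputs are byte-deterministic for a fixed corpus and configuration;
  all iteration orders are explicit (sorted accessions, input order of
  pathways).
* The published corpus-scale counts (611 confirmed genes, 234 pathways,
  17 motifs, 255 kinases, and the per-gene scores of the original
  database) depend on 2018 snapshots of the upstream resources and are
  not reproducible from this package; the analytic identities and rule
  tables above are.
* Problem sizes in the shipped test suite: the scanner oracle runs on
  ~1200 random pairs, and the pipeline-recovery test uses a 1000-gene
  corpus (~12k records), which completes in a few seconds.
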