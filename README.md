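# hccpm

Phosphorylated-biomarker prediction for hepatocellular carcinoma (HCC).

Most HCC biomarker catalogues collect confirmed genes; few say anything
about *new* candidates, and none score whether a candidate is plausibly
regulated by phosphorylation — the modification that existing kinase
inhibitors act on. `hccpm` is a toolkit for researchers who have protein
sequences, evidence annotations, and pathway gene sets in hand and want a
reproducible two-axis prioritization:

1. **Kinase correlation (Sk).** Prosite-syntax motifs are scanned over
   each protein with a sliding window; matches whose phosphoacceptor is
   Ser/Thr/Tyr/His nominate candidate kinases. Each (protein, kinase)
   pair is then scored on tissue co-expression (St), shared subcellular
   localization (Sl), and cell-cycle co-expression (Sp), combined as

       Sk = (Wt·St + Wl·Sl + Wp·Sp) / (Wt + Wl + Wp),  Wt,Wl,Wp = 5,3,2

   and the best kinase's Sk is kept (strongly suggestive at St ≥ 6,
   Sl ≥ 6, Sp = 10, i.e. Sk ≥ 6.8 under default weights).

2. **Pathway-evidence marker score (Scm).** In each pathway containing
   the gene, the other members' HCC evidence (E1 wet-lab / E2
   large-scale) sets a score Sc = W1·(Ne + 0.8·Nm)/Np + W2 when E1
   evidence is present, Sc = W2·Nm/Np when only E2, with W1, W2 = 5, 3;
   pathway scores are averaged with confidence-step weights into Scm
   (strongly suggestive at Scm ≥ 4.25, suggestive at Scm ≥ 3).

A gene strong on both axes is a strongly suggestive phosphorylated
marker (HCCPM); drug–target rows (liver-cancer / cancer / non-cancer)
are joined per gene. A seeded synthetic-corpus generator with a
constructive ground-truth ledger makes the whole pipeline testable
without any external downloads. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from hccpm import (
    Corpus, CycleProfile, EvidenceClass, HccEvidence, Localization,
    MotifDefinition, PathwayGeneSet, ProteinRecord, Tissue,
    classify_hccpm, marker_score, score_protein,
)

def square(acc, phase):  # half-period cycle profile peaking at `phase`
    return CycleProfile.from_points(
        acc, [(t, 1.0 if (t - phase) % 100 < 50 else -1.0)
              for t in range(100)])

query = ProteinRecord(
    "Q00001", sequence="AAGGRKASGGLLVA", tissue_evidence=Tissue.T1,
    go_cc_annotations={("GO:0005634", EvidenceClass.L1)},
    localization_categories={Localization.NUCLEUS},
    cycle_profile=square("Q00001", 0))
kinase = ProteinRecord(
    "KIN01", tissue_evidence=Tissue.T2,
    go_cc_annotations={("GO:0005634", EvidenceClass.L1)},
    localization_categories={Localization.NUCLEUS},
    cycle_profile=square("KIN01", 25), is_kinase=True)
corpus = Corpus(
    proteins=[query, kinase],
    motifs=[MotifDefinition("PM001", "[RK](2)-x-[ST]", site_offset=3,
                            kinase_accessions={"KIN01"})],
    pathways=[PathwayGeneSet("PW1", "demo pathway",
                             {"Q00001", "G1", "G2", "G3", "G4"})])

ph = score_protein(query, corpus)
print(ph.best_kinase, ph.st, ph.sl, ph.sp, ph.sk, ph.classification.value)

tiers = {"G1": HccEvidence.E1}
mk = marker_score(query, corpus.pathways,
                  lambda a: tiers.get(a, HccEvidence.NONE))
print(mk.scm, mk.classification.value)
print(classify_hccpm(ph.classification, mk.classification).value)
```

prints

```
KIN01 6.0 10.0 10.0 8.0 STRONGLY_SUGGESTIVE
4.25 STRONGLY_SUGGESTIVE
STRONGLY_SUGGESTIVE
```

The query's `RKAS` window matches the motif (acceptor S), nominating
KIN01. The pair scores St = 6 (weaker tier is T2), Sl = 10 (shared GO
term, both experimental), Sp = 10 (overlapping cycle phases), giving
Sk = (5·6 + 3·10 + 2·10)/10 = 8.0 ≥ 6.8 — strongly suggestive. On the
marker axis, one of the four other pathway genes is E1-confirmed, so
Sc = 5·(1/4) + 3 = 4.25, exactly the strong cutoff. Strong on both axes,
the gene is a strongly suggestive HCCPM.

## Command line

```sh
hccpm simulate --out bundle/ --seed 42 --n 500   # synthetic input bundle + ledger
hccpm validate bundle/                           # cross-reference checks (exit 2 on errors)
hccpm scan bundle/ --out matches.tsv             # motif matches per protein
hccpm run bundle/ --out results/                 # full pipeline -> TSV tables
```

`results/` contains `phospho.tsv`, `marker.tsv`, `marker_pathways.tsv`,
`hccpm.tsv`, and `summary.tsv`. All outputs are deterministic for a
fixed bundle and configuration (`--config config.yaml` overrides
weights, thresholds, and classification mode).

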