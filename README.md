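# irapass

Immune-response alternative-polyadenylation (APA) analysis for bulk
transcriptomics: who responds to immune-checkpoint-inhibitor therapy, and
which 3′-UTR events and APA regulatory factors carry that signal.

Alternative polyadenylation shifts a transcript between proximal and distal
polyA sites, shortening or lengthening its 3′-UTR. DaPars2-style tools
summarise this per gene as the **PDUI** (Percentage of Distal polyA site
Usage Index, in [0, 1]: high = long 3′-UTR). Starting from PDUI tables,
expression tables (TPM) and clinical annotation, `irapass` implements:

* **Differential APA calling** — effect size
  ΔPDUI = Mean_PDUI(responders) − Mean_PDUI(non-responders); significance
  by a two-sided joint label-permutation test; an event is called when
  |ΔPDUI| ≥ 0.1 and p < 0.05 (BH q-values reported alongside). One-vs-rest
  calling over T-cell-state patient subgroups (TA/TS/TN) and monotone
  PDUI-gradient detection are included.
* **ATF network and master APA factors** — Spearman correlation edges
  between APA-factor expression and differential-event PDUI, merged with
  STRING-style PPI edges (combined score > 700); nodes ranked by the twelve
  cytoHubba topology measures (Betweenness, BottleNeck, Closeness,
  ClusteringCoefficient, Degree, DMNC, EcCentricity, EPC, MCC, MNC,
  Radiality, Stress) and aggregated by Borda count into master factors.
* **The IRAPAss scoring system** — for each (gene x, event y) pair within a
  response group, the correlation score
  `CS_xy = −log10(P_xy + 1e−20) · sign(Cor_xy)` (Pearson); preranked GSEA of
  each event's CS-ranked gene list against pathway collections; the
  association statistic `pathAPAscore = 1 − 2p` (ES > 0) or `2p − 1`
  (ES < 0), screened at > 0.995 with FDR < 0.05; candidate pairs must flip
  NES sign between responders and non-responders and replicate across both
  discovery cohorts; survival selection by univariate Cox (p < 0.05) then
  cross-validated LASSO Cox (1-SE rule); finally a linear scorer over raw
  PDUI features trained on a 70/30 split. The published 10-term formula
  ships with the package:

  ```
  IRAPAss = 0.785057366·AIM2|chr1|159062567 + 0.660980225·BAX|chr19|48960961
          − 0.564149737·COL27A1|chr9|114310700 − 0.060074512·CTTN|chr11|70422660
          − 0.037628233·ERH|chr14|69380489     − 1.267010808·GTF3C2-AS1|chr2|27337588
          + 0.819018066·NASP|chr1|45618212     + 0.974817872·RPL13|chr16|89563035
          − 0.624692976·TAF15|chr17|35847057   − 0.279070169·TMEM63A|chr1|225841036
  ```
* **Feature-based PPI module** — personalized PageRank (damping 0.85)
  seeded on the model's parental genes over the largest connected component
  of the score-filtered PPI network; the top 200 genes by impact score.
* **Synthetic cohorts** — a generator that plants differential events,
  factor→event regulation, immune-pathway coupling with opposite-sign group
  structure, and survival tied to a latent score, with a full ground-truth
  record; every recovery test in the suite runs against it.

## Worked example

Simulate a cohort of 23 responders vs 82 non-responders with 30 planted
ΔPDUI = 0.2 events among 500, then call differential APA:

```sh
irapass simulate --config sim.yaml --seed 7 --out-dir sim
# wrote synthetic cohort (500 events x 105 samples) to sim
irapass diff-apa --pdui sim/pdui.tsv --clinical sim/clinical.tsv -B 1000 --seed 7 --out-dir diff
# 38 events called differential
```

The strongest calls in `diff/differential_apa.tsv`:

```
event_id              delta_pdui  perm_p    fdr_q     direction
G00467|chr18|4242973   0.253998   0.000999  0.012488  shortened
G00180|chr5|700389     0.248033   0.000999  0.012488  shortened
G00407|chr21|145342   -0.246114   0.000999  0.012488  lengthened
```

`delta_pdui > 0` means the 3′-UTR is shortened in non-responders; `perm_p`
is the add-one permutation p over B = 1000 joint label shuffles. 38 calls
against 38 truly shifted events (30 planted differential + 8 immune-coupled)
in this cohort.

Scoring with the published model is a dot product over raw PDUI features:

```python
>>> import irapass as ir
>>> model = ir.published_model()
>>> vec = {f: 0.0 for f in model.features}
>>> vec.update({"AIM2|chr1|159062567": 0.62, "BAX|chr19|48960961": 0.40,
...             "GTF3C2-AS1|chr2|27337588": 0.55})
>>> float(model.score(vec).iloc[0])
0.05427157...
```

(0.785057366·0.62 + 0.660980225·0.40 − 1.267010808·0.55 ≈ 0.0543; higher
scores indicate likely responders with better prognosis.)

The remaining subcommands — `atf-network`, `irapass-build`,
`irapass-score`, `ppi-module` — follow the same pattern; each writes a
`manifest.json` with the resolved parameters. Library entry points carry
the same names (`run_differential`, `build_scoring_system`,
`extract_feature_module`, ...).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-cohort
generator and its limits, numerical conventions, and the design decisions
taken where the method left choices open.
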