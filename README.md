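# surfscreen

Screening tumor transcriptomes for over-expressed **cell-surface**
transcripts — candidate targets for CARs and therapeutic antibodies, which
can only engage proteins exposed on the extracellular plasma membrane.

The package is aimed at computational oncology groups mining bulk
expression compendia of (pediatric) tumor cohorts against a normal-tissue
panel.  It provides, as a tested library + CLI:

- per-disease, per-probe **pooled two-sample t screening** against a pooled
  15-tissue normal panel:

  `T = (x̄ − ȳ) / (s_p √(1/n₁ + 1/n₂))`, `df = n₁ + n₂ − 2`,
  with two-sided p computed through the incomplete beta function (exact to
  p ~ 1e−300, no 1 − CDF cancellation);
- **membrane-localization filtering** that merges annotation evidence (GO,
  protein databases, chip annotation, literature, curation overrides) and
  keeps only cell-surface calls — proteins restricted to mitochondria,
  nuclear envelope, Golgi, ER or vesicles are excluded, proteins on the
  surface *and* another compartment are kept;
- **threshold / rank / top-k selection** (hits at T > 10, top-25 surface
  targets per disease) and **cross-disease aggregation** (how many disease
  lists share each gene, box-whisker T summaries);
- a **seeded synthetic-data generator** with planted over-expressed surface
  targets, for calibration and recovery testing; and
- packaged, checksummed **reference top-25 tables** for 12 pediatric tumor
  cohorts (Pre-B ALL, ARMS, ASPS, GBM, NBL-MYCNA, STS, OS, HBL, EWS, ERMS,
  NBL, DSRCT) used by the offline consistency checks.

See `docs/methods.md` for the model, its assumptions, and design choices.

## Worked example

Fit the statsmodels-style model on a seeded synthetic dataset:

```python
import surfscreen as ss

config = ss.SimulationConfig(n_probes=5000, seed=42)   # 12 cohorts, 15 normals
ds = ss.generate_dataset(config)
model = ss.SurfaceTargetScreen(ds.matrix, ds.metadata, ds.evidence, ds.probe_to_gene)
results = model.fit()
print(results.summary())
```

```
Surface-target screen results
======================================================================
probes: 5000
normal panel size: 15
screenable tumor cohorts (12): Pre-B_ALL, ARMS, ASPS, GBM, NBL-MYCNA, STS, OS, HBL, EWS, ERMS, NBL, DSRCT
surface probes passing filter: 750
hit threshold: T > 10

disease          n      hits   top-k    T max    T min
----------------------------------------------------------------------
Pre-B_ALL        9         3      25    11.67     4.41
ARMS            12         2      25    12.06     5.89
...
NBL             15         6      25    12.92     5.24
DSRCT            8         2      25    10.45     4.35

genes in >=3 disease top-k lists: 8
```

Each row is one screenable tumor cohort: `n` its array count, `hits` the
probes with T > 10 (all 25 planted targets shift by 3σ, so a few clear
this extreme cutoff; at δ=0 every cohort shows 0), `top-k` the length of
its surface-filtered target list, and `T max`/`T min` that list's range.
The ranked list itself:

```python
print(results.target_tables["Pre-B_ALL"].table.head(3))
```

```
 rank     probe_id gene_symbol         T            p
    1 SYN004224_at  GENE004224 11.673723 6.737596e-11
    2 SYN003507_at  GENE003507 11.035718 1.951512e-10
    3 SYN002365_at  GENE002365 10.106963 9.943457e-10
```

`results.save_reports(outdir)` writes the full bundle (per-disease ranked
screens, top-25 tables, hit counts, T summaries, cross-disease frequency,
run log) as deterministic TSVs; `results.plot_t_ranges()` draws the
box-whisker T overview.

The same pipeline runs from the shell on your own TSVs:

```sh
surfscreen simulate --seed 1 --out data/
surfscreen screen --matrix data/matrix.tsv --metadata data/metadata.tsv \
    --annotation data/annotation.tsv --probe-to-gene data/probe_to_gene.tsv \
    --out reports/
surfscreen reference          # packaged reference tables at a glance
surfscreen aggregate --tables reports/ --out agg/
```

Working with the packaged reference tables:

```python
ref = ss.load_reference_tables()
freq = ss.cross_disease_frequency(list(ref.tables.values()), ss.load_packaged_aliases())
print(freq.head(3))
#   gene_symbol  count                                        diseases
# 0        GPC2      8  ARMS;DSRCT;ERMS;EWS;NBL;NBL-MYCNA;OS;Pre-B_ALL
# 1        MCAM      8    ARMS;ERMS;EWS;GBM;HBL;NBL-MYCNA;OS;Pre-B_ALL
# 2     CACNA1I      6                  ARMS;ERMS;EWS;GBM;OS;Pre-B_ALL
```

MCAM and GPC2 — the screen's broadest candidates — each appear in 8 of the
12 disease top-25 lists.

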