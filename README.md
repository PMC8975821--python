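# polkinetics

Analysis toolkit for RNA polymerase II transcription kinetics in a
knockout-versus-control design: elongation-rate estimation from
nascent-RNA (4sUDRB-style) coverage waves, traveling-ratio pausing
metrics, spike-in normalized transcriptional-output calls, and stranded
extragenic transcript (PROMPT/eRNA) detection and annotation — together
with a synthetic-data generator that produces every input with recorded
ground truth, so the whole pipeline is testable without any sequencing
download.

It is written for computational genomicists who work with binned coverage
tracks (bedGraph), gene annotations (BED12), stranded read intervals
(BED6) and gene × sample count tables (TSV).

## The quantities at the core

**Elongation rate.** After synchronized release from a DRB transcription
block, newly labeled RNA forms a wave advancing from the TSS. Per gene and
time point *t*, the front position *d(t)* is decoded from 50-bp binned
coverage with a three-state left-to-right HMM (WAVE → FRONT → BACKGROUND,
Gaussian emissions on log1p coverage) plus a local least-squares
changepoint refinement. Rates:

- 0–10 and 0–20 min: *v* = mean replicate distance (kb) / *t* (min), for
  genes > 30 kb (10 min) or > 60 kb (20 min), non-overlapping, with a
  clear 2-kb upstream window;
- 10–20 min: OLS slope of replicate-level (*t*, *d*) points, kept only if
  slope > 0, the 50% CI is narrower than 0.5 kb/min, and the time-axis
  intercept is > −10 min.

A gene elongates *faster* upon knockout iff every knockout replicate
distance exceeds every control replicate distance (strict reading of the
either-replicate rule), *slower* in the mirror case, else *unaffected*.

**Traveling ratio.** TR = promoter RPKM / gene-body RPKM of Pol II
occupancy (promoter [TSS−50, TSS+300), body [TSS+300, TES)); higher TR =
more pausing. TR fold changes ≥ 1.5 are called decreased/increased; genes
are placed on a 3×3 grid of TR status × output status (nine groups).

**Transcriptional output.** Per-sample scale factors are median-of-ratios
on spike-in features only, so genuine global output shifts survive
normalization. Differential calls need an abundance floor (CPM/TPM ≥ 1),
BH-adjusted p < 0.05 from a pooled-dispersion negative-binomial Wald test,
and fold change ≥ 1.2/1.5/2 by preset.

**Extragenic transcripts.** Stranded reads (genic reads excluded) are
tiled into 500-bp windows; Poisson-improbable windows with gaps ≤ 1 kb
form islands, score-thresholded by Monte-Carlo calibration to an expected
background island count (e-value 100). Regions merged across conditions
need ≥ 50 reads in every replicate of at least one condition and are
annotated by priority lncRNA > enhancer > antisense > PROMPT >
readthrough > promoter-convergent > other.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

Run the full pipeline on a seeded synthetic dataset (60 genes, two
conditions × two replicates, time points 0/10/20 min, control waves at the
human-typical 3.8 kb/min and knockout at 4.4 kb/min):

```python
from polkinetics.config import RunConfig, SimConfig
from polkinetics import pipeline

cfg = RunConfig(sim=SimConfig(n_genes=60), seed=1, out_dir="example_run")
res = pipeline.run(cfg)

early = res["rate_changes"]
early = early[early["interval"] == "r0_10"]["category"]
print(len(early), dict(early.value_counts()))

r = res["rates"]
fit = r[(r["interval"] == "r10_20") & r["passes_filters"]]
for cond in ("control", "ko"):
    print(cond, round(fit[fit["condition"] == cond]["rate"].median(), 2))

print(dict(res["traveling_ratio"]["tr_status"].value_counts()))
print(dict(res["extragenic"]["class"].value_counts()))
```

prints

```
26 {'faster': 26}
control 3.67
ko 4.32
{'unaffected': 47, 'decreased': 18, 'increased': 1}
{'PROMPT': 4, 'readthrough': 3, 'lncRNA': 3, 'enhancer': 3, 'other': 3,
 'promoter_convergent': 2}
```

Reading this: all 26 eligible genes with clear wave fronts in every
replicate elongate faster in the knockout over 0–10 min — the simulated
knockout releases an elongation restraint, and the strict either-replicate
rule picks that up. The fitted 10–20 min rates (3.67 and 4.32 kb/min)
recover the configured condition speeds to within the 50-bp boundary
resolution. 18 of 66 genes show a ≥1.5-fold TR decrease, matching the
configured 40%-of-genes × 2-fold pausing loss after the evaluability
floor. All 18 detectable extragenic truth islands are found and correctly
classed (the two antisense islands overlap gene bodies and are removed by
genic-read exclusion, by construction of that filter).

Every stage's table is also written under `out_dir` together with a
`manifest.json` of SHA-256 digests; rerunning the same config reproduces
the digests bit for bit.

The same stages are available from the shell:

```bash
polkinetics simulate --seed 1 --out simdata/
polkinetics run --seed 1 --out example_run/
polkinetics init-config cfg.yaml && polkinetics validate --config cfg.yaml
```

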