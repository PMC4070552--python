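# mitocovbias

Coverage-bias and sequencing-error profiling for ultra-deep sequencing of
circular mitochondrial genomes.

When a whole-genome library is sequenced deeply, the mtDNA fraction reaches
extreme coverage (10⁴–10⁵X). At that depth, counting noise is negligible and
the remaining site-to-site variation in coverage — and the low background of
non-reference read bases — reflect properties of the sequence itself:
GC-dependent amplification bias, sequence-specific error (SSE) motifs such
as `CCNGCC`/`GGCNGG`, and genuine heteroplasmy. `mitocovbias` turns per-site
pileups of a circular mtDNA reference into those signals:

* **Coverage profiles** — fold the circular-mapping overlap, trim unreliable
  ends, scale individuals to a common mean, and window coverage with GC
  content.
* **GC bias** — OLS of window coverage on GC (`cov ~ gc` and
  `cov ~ gc + gc²`), compared by Gaussian AIC; Welch *t*-test of per-site
  coverage at A/T vs G/C bases; site-level ANCOVA
  `cov ~ base + gene_type + gc₅₀` with Type II sums of squares.
* **Error profile** — per-site error rate `e = (depth − n_consensus)/depth`,
  the 4×4 substitution spectrum and ti/tv ratio, IUPAC motif scanning
  (forward + reverse complement, circular-aware), coverage vs distance to
  error-prone motifs, and the error/coverage rank correlation.
* **Heteroplasmy** — sites where exactly one individual carries one specific
  non-consensus allele at intermediate frequency (≥1%) while the rest of the
  cohort shows only baseline error; multi-carrier sites are reported as
  shared variants instead.
* **k-mer spectrum** — exact k-mer counting of reads (k = 25 by default,
  canonical), valley detection in the bimodal multiplicity histogram,
  per-base error `= error-instance fraction / k`, and base coverage from the
  spectrum peak via `N = M·L/(L−k+1)`.
* **Concordance** — Spearman correlation of coverage profiles across
  individuals and, through a pairwise alignment column map, across species.
* **Synthetic cohorts** — a seeded generator producing references, pileups,
  reads and ground-truth tables with all of the structure above planted, so
  every stage is testable without external data.

## Worked example

```python
from mitocovbias import (SimulationConfig, generate_reference,
                         simulate_site_profiles, window_profile,
                         fit_gc_regression, call_heteroplasmy,
                         consensus_from_counts)
import numpy as np

cfg = SimulationConfig(seed=1)            # 16.5 kb, 11 individuals, ~4,000X
ref, motifs = generate_reference(cfg)
profiles, truth = simulate_site_profiles(ref, cfg, motifs)

cov = profiles[0].depth.astype(float)
table = window_profile(ref.sequence, cov, 50, 50)
fit = fit_gc_regression(table, degree=1)
print(f"slope={fit.coefficients[1]:.0f}  R2={fit.R2:.2f}  df={fit.df}")

cons = consensus_from_counts(profiles, np.array(list(ref.sequence)))
calls, shared = call_heteroplasmy(profiles, cons)
print(f"heteroplasmic sites called: {len(calls)} (planted: {len(truth.heteroplasmies)})")
```

prints

```
slope=-6248  R2=0.72  df=328
heteroplasmic sites called: 6 (planted: 6)
```

The negative slope is the GC bias (coverage falls with window GC), and all
six planted intermediate-frequency variants are recovered, none spuriously.

The same stages are scriptable from the shell:

```bash
mitocovbias simulate --seed 1 --out simdir/
mitocovbias coverage --pileup simdir/ind00.pileup --ref simdir/reference.fa \
    --window 50 --out windows.tsv
mitocovbias gcfit --windows windows.tsv
mitocovbias run --config run.toml --out outdir/   # everything end to end
```

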