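# landhab

Land-use change statistics, landscape pattern metrics, an InVEST-style
habitat-quality model, variance-decomposition (geodetector-style)
attribution, and a Markov + patch-seeding cellular-automaton land-use
simulator — one tested package operating on categorical rasters.

## What it does

| Module | Purpose |
| --- | --- |
| `landhab.grid` | Grid data model and I/O (ESRI ASCII grid, TIFF), class areas, Euclidean distance surfaces |
| `landhab.change` | Per-class dynamic degree K, comprehensive dynamic degree LC, class-area tables, class×class transfer matrices and transition probabilities |
| `landhab.metrics` | NP, PD, LPI, LSI, AI at class level; NP, PD, LSI, SPLIT, SHDI, AI, CONTAG at landscape level, all computed from first principles |
| `landhab.quality` | Distance-decayed threat degradation D and habitat quality Q = H·(1 − Dᶻ/(Dᶻ + kᶻ)), 5-level classing and change classing |
| `landhab.detector` | q-statistic of a stratification (1 − within/total variance), interaction detector, Jenks natural-breaks discretization, permutation significance |
| `landhab.simulate` | Markov area demand, per-class expansion-probability learning from two dates + driver stack, demand-driven CA allocation with stochastic patch seeding, Cohen's kappa and three-map figure of merit |
| `landhab.synth` | Seeded synthetic driver stacks and multi-date land-use series with known Markov structure; transcribed summary-table fixtures |
| `landhab.pipeline` / `landhab.cli` | Config-driven orchestration of the full stage sequence |

## CLI

```bash
landhab synth --size 120 --seed 7 --out scenario/
landhab change --t1 scenario/landuse_1991.asc --t2 scenario/landuse_2000.asc --years 9
landhab metrics --input scenario/landuse_2019.asc --level landscape
landhab hq --landuse scenario/landuse_2019.asc --threats threats.csv \
           --sensitivity sens.csv --k 0.5 --z 2.5
landhab geodetect --y quality.asc --factors scenario/ --classes 7
landhab simulate --t1 scenario/landuse_2000.asc --t2 scenario/landuse_2010.asc \
                 --drivers scenario/ --steps 2 --seed 42
landhab run --synthetic --seed 0 --out pipeline_out/
```

Threat tables are CSV with columns `code,name,weight,d_max_km,decay`;
sensitivity tables with `code,name,suitability,s_<threat code>…`.
`landhab.synth.default_threats()` / `default_sensitivity()` provide the
standard six-class desert parameterization.

## Conventions

- Row-major grids, origin at the upper-left, 0-based indices; distances
  between cell centers; areas always reported in km².
- Nodata cells are excluded from every statistic, metric and model.
- Patches are 8-connected by default; adjacency tallies are rook
  (single-count for AI, double-count for CONTAG); the landscape boundary
  counts toward perimeter but never toward adjacencies.
- Exponential threat decay is `exp(−2.99·d/d_max)`; both decay modes are
  truncated at `d_max`, so the production kernel equals the brute-force
  definition exactly.
- All randomness flows from explicit integer seeds; same seed ⇒
  identical output.
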