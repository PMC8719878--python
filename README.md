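# allofit

Two-state allosteric ensemble models and global/local least-squares fitting
for histidine-kinase dose–response panels.

A homodimeric transmembrane sensor kinase is modeled as one, two, or three
coupled two-state domains (periplasmic sensor, HAMP, cytoplasmic autokinase)
with divalent-cation binding to the sensor (one site per monomer, so the
binding polynomial is `(1 + [Mg2+]/Kd)^2`).  The package provides the full
inference stack used to fit such models to panels of mutant dose–response
curves measured with two simultaneous observables (sensor crosslink fraction
and reporter activity in Miller units):

- **`allofit.ensemble`** — closed-form on-fractions for the concerted,
  two-domain, and three-domain ensembles, plus a brute-force 8-state
  enumeration oracle.
- **`allofit.panel`** — tidy CSV/TSV panel I/O, Miller-unit and crosslink
  arithmetic, and *q*-rescaling (activity divided by
  `q = mean(activity)/mean(crosslink)` so both observables weigh equally).
- **`allofit.ledger`** — global/local/fixed parameter-sharing ledgers built
  from construct annotations (domain map, heptad-of-junction rules,
  Gly-insertion decoupling fixed to 1, documented exceptions).
- **`allofit.fitting`** — bounded trust-region least squares in log10
  coordinates, seeded log-uniform multistart, and model-family comparison.
- **`allofit.uncertainty`** — bootstrap-of-residuals confidence intervals
  and single-parameter residual-sweep identifiability curves.
- **`allofit.synthetic`** — seeded synthetic panel generator and
  parameter-recovery experiments.
- **`allofit.reference`** — the published 36-construct panel encoded as
  data: annotations, published fit values, replicate structure.

## Command line

```bash
# synthetic reference panel (56 datasets, 36 constructs) as tidy CSV
allofit simulate --seed 1 --noise-crosslink 0.05 --noise-activity-rel 0.10 \
    --out panel.csv

# three-domain global/local multistart fit (62-slot reference ledger)
allofit fit --data panel.csv --seed 1 --n-starts 2000 --out-dir runs/fit \
    --allow-out-of-range

# uncertainty diagnostics for the completed fit
allofit bootstrap --data panel.csv --fit-json runs/fit/fit.json \
    --n-boot 200 --seed 2 --out-dir runs/boot --allow-out-of-range
allofit sweep --data panel.csv --fit-json runs/fit/fit.json \
    --slots kd_off:global,kd_on:global --out-dir runs/sweep --allow-out-of-range

# rank concerted / two-domain / three-domain families by best SSR
allofit compare --data panel.csv --seed 3 --out runs/compare.json \
    --allow-out-of-range
```

Fits report the seed, restart count, boundary-pinned slots, and all local
minima within 1% of the best SSR.  The default restart count is desk-scale;
production fits should raise `--n-starts` (the published analysis used
125,000 restarts).

## Data dialect

Long-format CSV/TSV with columns
`mutant_id, replicate, mg_mM, crosslink_fraction, activity_miller`, five
Mg²⁺ concentrations per (mutant, replicate) group (0.1, 0.4, 1.6, 6.4,
25.6 mM by default).  Groups with missing doses are rejected with a report;
Mg²⁺ is converted to molar internally.
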