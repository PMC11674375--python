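# glycosim

Proteomics-constrained kinetic modeling of renal glucose metabolism.

`glycosim` builds an ODE model of glycolysis, gluconeogenesis, the
2,3-bisphosphoglycerate (2,3-BPG) shunt and the polyol pathway, integrates it
to steady state over a grid of external glucose concentrations, scales each
enzyme's maximal activity by measured protein abundance
(`vmax_sample = vmax_control_mean * E_sample / E_control_mean`), and compares
control-vs-knockout ensembles of exchange-flux curves (glucose uptake,
lactate release). A synthetic proteomics generator provides group-structured,
lognormal-noise intensity tables with a configurable Bpgm knockdown, so the
whole pipeline runs without any external data.

## Layout

| module | contents |
|---|---|
| `glycosim.model` | metabolites, rate laws, reactions, stoichiometry, ODE right-hand side, carbon bookkeeping, YAML parameter files |
| `glycosim.steady_state` | stiff integration to steady state (BDF + Newton polish), glucose sweeps, flux curves |
| `glycosim.proteomics` | intensity tables, enzyme maps, per-sample Vmax scaling factors, sample-model instantiation |
| `glycosim.ensemble` | per-sample sweeps, group mean/SD statistics, KO-vs-control direction report |
| `glycosim.synthetic` | synthetic proteomics tables, analytic toy-chain oracle, packaged KO scenario |
| `glycosim.io` / `glycosim.cli` | CSV/YAML round-tripping and the `glycosim` command-line tool |

The reference network (21 dynamic metabolites, 31 reactions, clamped
NAD/NADH/ATP/ADP cofactors) ships as
`src/glycosim/data/reference_model.yaml`. All kinetic constants there are
curated order-of-magnitude defaults, not fitted values; every constant
carries an explicit unit and files without units are rejected. The 2,3-BPG
feedback couplings (competitive inhibition of hexokinase, modifier of
phosphoglycerate mutase) are tagged `bpg_hk` / `bpg_pgam` and can be toggled
at build time.

## CLI

```bash
# one steady state of the reference model at 5 mM external glucose
glycosim simulate --glucose 5

# exchange-flux curve over the default 2-12 mM grid
glycosim sweep --out curve.csv

# generate a synthetic KO fixture (6 samples per group, Bpgm x0.05)
glycosim synth --n-per-group 6 --seed 0 --outdir fixture/

# proteomics -> per-sample Vmax factors
glycosim scale --table fixture/proteomics.csv --groups fixture/groups.csv \
    --out factors.csv

# full control-vs-KO ensemble comparison (plus optional --plot)
glycosim ensemble --table fixture/proteomics.csv --groups fixture/groups.csv \
    --enzyme-map fixture/enzyme_map.yaml --outdir run/
```

`ensemble` writes a tidy per-sample CSV, a per-group mean/SD summary, a
per-grid-point direction report and a `config.json` echoing every effective
setting. Sign convention throughout: positive glucose flux = uptake,
positive lactate flux = release.

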